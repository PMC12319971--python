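"""End-to-end orchestration: simulate/load -> HR -> similarity -> substates
-> activation maps -> associations.

`run_pipeline` wires the stage modules together under a single explicit
seed, producing a report bundle (plain dict, JSON-serializable) plus
standard-format artifacts (affiliation TSV, sweep CSV, summary JSON,
contrast and heart-rate CSVs) when an output directory is given. Every
random draw flows from the config seed, so a fixed config reproduces the
report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activation_maps import paired_contrast, roi_average, stack_beta_maps
from .association_stats import (
    median_split,
    order_effect_regression,
    paired_ttest,
    pearson_with_df,
    pls2,
    vas_change_and_tests,
)
from .ekg_hr import HeartRateSeries, hr_qc_report, mean_hr_in_state, process_ekg
from .similarity import ParcelTimeSeries, group_mean_matrix, subtraction_matrix, time_similarity_matrix
from .substates import kmeans_control, retained_substates, threshold_sweep
from .synthetic_data import (
    CONDITIONS,
    Cohort,
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    generate_ekg,
    generate_vas,
)

__all__ = ["RunConfig", "run_pipeline", "read_cohort", "write_cohort"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``manifest`` points at a cohort on disk, or a synthetic cohort
    is generated (``cohort_spec``, defaulting to the planted design of
    :func:`brainstates.synthetic_data.default_cohort_spec` with ``seed``).
    """

    seed: int = 0
    manifest: str | None = None
    cohort_spec: CohortSpec | None = None
    # threshold sweep
    threshold_min: float = 0.20
    threshold_max: float = 0.30
    threshold_step: float = 0.01
    gamma: float = 1.0
    n_restarts: int = 100
    neg_treatment: str = "symmetric"
    # statistics
    alpha: float = 0.05
    min_occupancy: float = 0.10
    pls_components: int = 2
    kmeans_k: int = 3
    # synthetic EKG / VAS noise
    ekg_noise_sd: float = 200.0
    vas_noise_sd: float = 0.05
    out_dir: str | None = None

    def thresholds(self) -> np.ndarray:
        n = int(round((self.threshold_max - self.threshold_min) / self.threshold_step)) + 1
        return np.round(self.threshold_min + self.threshold_step * np.arange(n), 10)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write nodal series as per-participant CSVs plus a manifest.

    Each CSV has one row per volume and one column per node; floats are
    written with full precision so read(write(x)) == x exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, cond), ts in sorted(cohort.series.items()):
        fname = f"{pid}_{cond}_timeseries.csv"
        pd.DataFrame(ts.values.T, columns=ts.node_labels).to_csv(
            out / fname, index=False, float_format="%.17g"
        )
        rows.append(
            {
                "participant": pid,
                "condition": cond,
                "path": fname,
                "tr_seconds": ts.tr_seconds,
                "injection_volume": ts.injection_volume,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> dict[tuple[str, str], ParcelTimeSeries]:
    """Load a cohort from a manifest CSV (participant, condition, path).

    Every participant must appear in both conditions; violations are
    rejected naming the participant.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    required = {"participant", "condition", "path"}
    if not required <= set(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    series: dict[tuple[str, str], ParcelTimeSeries] = {}
    for _, row in man.iterrows():
        path = manifest_path.parent / row["path"]
        try:
            df = pd.read_csv(path, float_precision="round_trip")
            values = df.to_numpy(dtype=float).T
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"{path}: malformed time-series CSV ({exc})") from exc
        series[(row["participant"], row["condition"])] = ParcelTimeSeries(
            values=values,
            tr_seconds=float(row.get("tr_seconds", 2.0)),
            injection_volume=int(row.get("injection_volume", 240)),
            participant_id=str(row["participant"]),
            condition=str(row["condition"]),
            node_labels=list(df.columns),
        )
    participants = {pid for pid, _ in series}
    for pid in sorted(participants):
        missing = [c for c in CONDITIONS if (pid, c) not in series]
        if missing:
            raise ValueError(f"participant {pid} lacks condition(s) {missing}")
    return series


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulated_hr(
    cohort: Cohort, rng: np.random.Generator, noise_sd: float
) -> tuple[dict[tuple[str, str], HeartRateSeries], dict]:
    """Synthesize EKG traces from planted RR plans and run the HR chain."""
    hr: dict[tuple[str, str], HeartRateSeries] = {}
    qc: dict[str, dict] = {}
    for key in sorted(cohort.truth.rr_plans):
        trace, _ = generate_ekg(
            cohort.truth.rr_plans[key],
            fs=250.0,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        series, peaks = process_ekg(
            trace,
            tr_seconds=cohort.spec.tr_seconds,
            n_volumes=cohort.spec.n_volumes,
        )
        hr[key] = series
        qc["/".join(key)] = hr_qc_report(series, peaks)
    return hr, qc


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report bundle (JSON-ready dict).

    Stages: cohort simulation/ingest, EKG-to-heart-rate, similarity and
    subtraction matrices, threshold-swept Louvain substate detection with
    k-means control, substate beta/z maps with paired contrasts, ROI and
    heart-rate summaries, VAS change tests and PLS associations.
    """
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
        }
    }

    # ------------------------------------------------------------------ data
    simulated = config.manifest is None
    if simulated:
        spec = config.cohort_spec or default_cohort_spec(seed=config.seed)
        cohort = generate_cohort(spec)
        series = cohort.series
    else:
        series = read_cohort(config.manifest)
        cohort = None
        spec = None
    some = next(iter(series.values()))
    tr, inj, n_volumes = some.tr_seconds, some.injection_volume, some.n_volumes
    participants = sorted({pid for pid, _ in series})
    report["cohort"] = {
        "n_participants": len(participants),
        "n_nodes": some.n_nodes,
        "n_volumes": n_volumes,
        "tr_seconds": tr,
        "injection_volume": inj,
        "simulated": simulated,
    }

    # ---------------------------------------------------------------- heart rate
    hr_series: dict[tuple[str, str], HeartRateSeries] = {}
    if simulated:
        hr_series, hr_qc = _simulated_hr(cohort, rng, config.ekg_noise_sd)
        report["hr_qc"] = hr_qc

    # ---------------------------------------------------------------- similarity
    sims = {
        cond: [time_similarity_matrix(series[(pid, cond)]) for pid in participants]
        for cond in CONDITIONS
    }
    mean_dmt = group_mean_matrix(sims["DMT"])
    mean_pcb = group_mean_matrix(sims["PCB"])
    sub = subtraction_matrix(mean_dmt, mean_pcb)

    # ---------------------------------------------------------------- substates
    try:
        sweep = threshold_sweep(
            sub,
            thresholds=config.thresholds(),
            gamma=config.gamma,
            seed=int(rng.integers(2**31 - 1)),
            n_restarts=config.n_restarts,
            min_occupancy=config.min_occupancy,
            alpha=config.alpha,
            neg_treatment=config.neg_treatment,
        )
    except ValueError:
        # conditions indistinguishable: every threshold empties the graph
        report["substates"] = {"selected_threshold": None, "k": 0, "retained": []}
        report["sweep"] = []
        return _finalize(report, config, None, None)
    sel = sweep.selected
    affil = sel.affiliation
    retained = [s.label for s in sel.summaries if s.retained]
    report["sweep"] = sweep.to_frame().to_dict(orient="records")
    report["substates"] = {
        "selected_threshold": sel.threshold,
        "k": sel.k,
        "modularity_q": affil.q,
        "omnibus_chi2": sel.omnibus_chi2,
        "retained": retained,
        "summaries": [
            {
                "label": s.label,
                "pre_occupancy": s.pre_occupancy,
                "post_occupancy": s.post_occupancy,
                "pre_minutes": s.pre_minutes,
                "post_minutes": s.post_minutes,
                "chi2": s.chi2,
                "p_value": s.p_value,
                "retained": s.retained,
            }
            for s in sel.summaries
        ],
    }
    km_affil, km_inertias = kmeans_control(
        sub, k=config.kmeans_k, seed=int(rng.integers(2**31 - 1))
    )
    report["kmeans_control"] = {
        "k": config.kmeans_k,
        "best_inertia": float(np.min(km_inertias)),
        "labels_first10": km_affil.labels[:10].tolist(),
    }

    if not retained:
        return _finalize(report, config, sweep, None)

    # ---------------------------------------------------------------- maps
    beta = {
        cond: stack_beta_maps(
            [series[(pid, cond)] for pid in participants], affil, retained
        )
        for cond in CONDITIONS
    }
    contrasts = {
        s: paired_contrast(beta["DMT"], beta["PCB"], s, alpha=config.alpha)
        for s in retained
    }
    report["contrasts"] = {
        str(s): {
            "n_hyper": int(c.hyper_mask.size),
            "n_hypo": int(c.hypo_mask.size),
            "hyper_nodes": c.hyper_mask.tolist(),
            "hypo_nodes": c.hypo_mask.tolist(),
        }
        for s, c in contrasts.items()
    }
    # focus on the post-injection-dominant retained substate with the
    # strongest contrast (downstream HR/behavior analyses target the state
    # emerging after the injection)
    def _contrast_size(s):
        c = contrasts[s]
        return c.hyper_mask.size + c.hypo_mask.size

    by_label = {s.label: s for s in sel.summaries}
    post_dominant = [s for s in retained if by_label[s].post_occupancy > by_label[s].pre_occupancy]
    focus = max(post_dominant or retained, key=_contrast_size)
    report["focus_state"] = int(focus)
    fc = contrasts[focus]
    j = retained.index(focus)

    roi_changes: dict[str, np.ndarray] = {}
    diff_beta = beta["DMT"].betas[:, :, j] - beta["PCB"].betas[:, :, j]
    for name, mask in (("hyper", fc.hyper_mask), ("hypo", fc.hypo_mask)):
        if mask.size:
            roi_changes[name] = roi_average(diff_beta, mask, axis=1)

    # ---------------------------------------------------------------- heart rate in state
    assoc: dict = {}
    hr_change = None
    if hr_series:
        means = {
            cond: np.array(
                [
                    mean_hr_in_state(hr_series[(pid, cond)], affil.labels, focus)
                    for pid in participants
                ]
            )
            for cond in CONDITIONS
        }
        t, df, p = paired_ttest(means["DMT"], means["PCB"])
        hr_change = means["DMT"] - means["PCB"]
        low, high = median_split(hr_change)
        assoc["hr"] = {
            "state": int(focus),
            "mean_dmt_bpm": float(means["DMT"].mean()),
            "mean_pcb_bpm": float(means["PCB"].mean()),
            "paired_t": t,
            "df": df,
            "p": p,
            "median_split_low": low.tolist(),
            "median_split_high": high.tolist(),
        }
        if "hypo" in roi_changes:
            r, rdf, rp = pearson_with_df(hr_change, roi_changes["hypo"])
            assoc["hr_vs_hypo"] = {"r": r, "df": rdf, "p": rp}

    # ---------------------------------------------------------------- VAS + PLS
    if simulated:
        vas_dmt, vas_pcb = generate_vas(
            cohort.truth,
            coupling=spec.vas_coupling,
            noise_sd=config.vas_noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            shifts=spec.vas_shifts,
        )
        vas = vas_change_and_tests(vas_dmt, vas_pcb, alpha=config.alpha)
        assoc["vas"] = {
            "rejected_items": vas.rejected[vas.rejected].index.tolist(),
        }
        X = vas.change.to_numpy(float)
        if roi_changes:
            Y = np.column_stack([roi_changes[k] for k in sorted(roi_changes)])
            m = pls2(Y, X, n_components=config.pls_components)
            assoc["pls_brain"] = {
                "score_r": m.score_r.tolist(),
                "score_p": m.score_p.tolist(),
                "top_items": [
                    vas.change.columns[int(np.argmax(np.abs(m.x_loadings[:, a])))]
                    for a in range(m.n_components)
                ],
            }
        if hr_change is not None and np.std(hr_change) > 0:
            m = pls2(hr_change, X, n_components=config.pls_components)
            assoc["pls_hr"] = {
                "score_r": m.score_r.tolist(),
                "score_p": m.score_p.tolist(),
            }
        order = (np.arange(len(participants)) < len(participants) // 2).astype(int)
        order_tests = {}
        for name, y in list(roi_changes.items()) + (
            [("hr_change", hr_change)] if hr_change is not None else []
        ):
            slope, pval = order_effect_regression(y, order)
            order_tests[name] = {"beta": slope, "p": pval}
        assoc["order_effects"] = order_tests

    report["associations"] = assoc
    return _finalize(report, config, sweep, affil)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _finalize(report: dict, config: RunConfig, sweep, affil) -> dict:
    report = _jsonify(report)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if sweep is not None:
            sweep.to_frame().to_csv(out / "sweep.csv", index=False)
        if affil is not None:
            pd.DataFrame(
                {"volume": np.arange(1, affil.n_volumes + 1), "label": affil.labels}
            ).to_csv(out / "affiliation.tsv", sep="\t", index=False)
    return report
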