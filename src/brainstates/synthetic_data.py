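"""Synthetic paired-condition cohorts with planted ground truth.

Emulates the three data streams of a paired pharmaco-fMRI resting-state
study (drug vs placebo, within participant):

* parcellated nodal BOLD time series with planted contiguous temporal
  substates and condition-specific regional effects,
* EKG voltage traces with known R-peak times and condition-specific RR
  dynamics (a post-injection heart-rate increase under the drug),
* 25-item visual-analogue-scale ratings coupled to the planted effects.

Default dimensions follow the emulated study design: 14 participants,
112 nodes (100 cortical + 12 subcortical parcels), 840 volumes at TR 2 s,
injection at the end of minute 8 (volume 240).

Planted temporal structure
--------------------------
The drug condition carries five pattern-states tiling the scan (two before
the injection, three after), each a distinct spatial activity pattern held
constant over its windows. The placebo condition carries a fast-alternating
two-pattern baseline whose block boundaries are misaligned with the drug
windows. Consequently the drug-minus-placebo subtraction matrix contains
positive entries only within the planted drug-state blocks — at zero noise
and at moderate noise alike — which is exactly the structure the substate
detector is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ekg_hr import EKGTrace
from .similarity import ParcelTimeSeries

__all__ = [
    "SubstateTruth",
    "ConditionEffect",
    "HREffect",
    "CohortSpec",
    "CohortTruth",
    "Cohort",
    "default_cohort_spec",
    "generate_cohort",
    "generate_ekg",
    "generate_vas",
    "VAS_COUPLING_SCALE",
]

CONDITIONS = ("DMT", "PCB")

#: rating-unit scale of the VAS coupling model (see generate_vas)
VAS_COUPLING_SCALE = 0.2


@dataclass
class SubstateTruth:
    """A planted temporal substate: label, per-condition windows, pattern.

    ``windows[condition]`` is a list of 1-based inclusive volume intervals
    during which every node expresses ``amplitude * spatial_pattern``.
    """

    label: int
    windows: dict[str, list[tuple[int, int]]]
    spatial_pattern: np.ndarray
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float)


@dataclass
class ConditionEffect:
    """Additive regional activity shift applied in one condition only.

    The per-participant amplitude is drawn as N(amplitude, amplitude_sd^2);
    by default the shift is applied to post-injection volumes only.
    """

    nodes: list[int]  # 0-based node indices
    condition: str = "DMT"
    amplitude: float = 1.0
    amplitude_sd: float = 0.0
    name: str = ""
    post_only: bool = True


@dataclass
class HREffect:
    """Planted heart-rate dynamics (bpm).

    Placebo heart rate is constant at the participant baseline; under the
    drug, heart rate rises by a per-participant amount N(dmt_increase_bpm,
    increase_sd^2) for the post-injection period.
    """

    baseline_bpm: float = 70.0
    baseline_sd: float = 5.0
    dmt_increase_bpm: float = 12.0
    increase_sd: float = 3.0


@dataclass
class CohortSpec:
    n_participants: int = 14
    n_nodes: int = 112
    n_volumes: int = 840
    tr_seconds: float = 2.0
    injection_volume: int = 240
    seed: int = 0
    noise_sd: float = 0.5
    substate_plan: list[SubstateTruth] = field(default_factory=list)
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    hr_effects: HREffect = field(default_factory=HREffect)
    vas_coupling: dict[str, tuple[str, float]] = field(default_factory=dict)
    vas_shifts: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.injection_volume < self.n_volumes:
            raise ValueError("need n_volumes > injection_volume > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        patterns = []
        for cond in CONDITIONS:
            occupied = np.zeros(self.n_volumes, dtype=bool)
            for st in self.substate_plan:
                for a, b in st.windows.get(cond, []):
                    if not (1 <= a <= b <= self.n_volumes):
                        raise ValueError(
                            f"state {st.label}: window ({a},{b}) outside "
                            f"[1, {self.n_volumes}]"
                        )
                    if occupied[a - 1 : b].any():
                        raise ValueError(
                            f"state {st.label}: window ({a},{b}) overlaps another "
                            f"window in condition {cond}"
                        )
                    occupied[a - 1 : b] = True
        for st in self.substate_plan:
            if st.spatial_pattern.size != self.n_nodes:
                raise ValueError(
                    f"state {st.label}: pattern length {st.spatial_pattern.size} "
                    f"!= n_nodes {self.n_nodes}"
                )
            patterns.append(st.spatial_pattern)
        if len(patterns) >= 2:
            if np.linalg.matrix_rank(np.column_stack(patterns)) < 2:
                raise ValueError("substate patterns are mutually collinear")
        for eff in self.condition_effects:
            if eff.condition not in CONDITIONS:
                raise ValueError(f"unknown condition {eff.condition!r}")
            if any(not 0 <= n < self.n_nodes for n in eff.nodes):
                raise ValueError("condition effect references nodes out of range")


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    affiliation: dict[str, np.ndarray]  # condition -> per-volume labels (0 = none)
    state_labels: list[int]
    sources: dict[str, np.ndarray]  # couplable per-participant quantities
    rr_plans: dict[tuple[str, str], np.ndarray]  # (participant, cond) -> RR (s)
    hr_volume_bpm: dict[tuple[str, str], np.ndarray]
    participants: list[str]


@dataclass
class Cohort:
    series: dict[tuple[str, str], ParcelTimeSeries]
    truth: CohortTruth
    spec: CohortSpec

    @property
    def participants(self) -> list[str]:
        return self.truth.participants


def _split_period(start: int, end: int, n_parts: int) -> list[tuple[int, int]]:
    edges = np.linspace(start - 1, end, n_parts + 1).round().astype(int)
    return [(int(edges[i] + 1), int(edges[i + 1])) for i in range(n_parts)]


def default_cohort_spec(
    seed: int = 0,
    n_participants: int = 14,
    n_nodes: int = 112,
    n_volumes: int = 840,
    injection_volume: int = 240,
    noise_sd: float = 0.5,
    n_pre_states: int = 2,
    n_post_states: int = 3,
    pcb_block: int = 10,
    effect_amplitude: float = 1.0,
) -> CohortSpec:
    """Build the default planted design (see module docstring).

    Patterns are orthonormal directions scaled to unit per-node variance,
    drawn deterministically from ``seed``. Two regional condition effects
    ("hyper" and "hypo", 5 nodes each, drug condition, post-injection only)
    and a default VAS coupling to the hyperactivity effect and the planted
    heart-rate change are included.
    """
    rng = np.random.default_rng(seed)
    n_states = n_pre_states + n_post_states
    q, _ = np.linalg.qr(rng.standard_normal((n_nodes, n_states + 2)))
    patterns = q * np.sqrt(n_nodes)  # per-node sd ~ 1

    plan: list[SubstateTruth] = []
    windows = _split_period(1, injection_volume, n_pre_states) + _split_period(
        injection_volume + 1, n_volumes, n_post_states
    )
    for s, win in enumerate(windows):
        plan.append(
            SubstateTruth(label=s + 1, windows={"DMT": [win]}, spatial_pattern=patterns[:, s])
        )
    # placebo baseline: two patterns alternating every `pcb_block` volumes,
    # misaligned with the drug-state windows
    base_windows: list[list[tuple[int, int]]] = [[], []]
    for i, a in enumerate(range(1, n_volumes + 1, pcb_block)):
        base_windows[i % 2].append((a, min(a + pcb_block - 1, n_volumes)))
    for j in range(2):
        plan.append(
            SubstateTruth(
                label=n_states + 1 + j,
                windows={"PCB": base_windows[j]},
                spatial_pattern=patterns[:, n_states + j],
            )
        )

    node_pool = rng.permutation(n_nodes)
    effects = [
        ConditionEffect(
            nodes=node_pool[:5].tolist(),
            condition="DMT",
            amplitude=effect_amplitude,
            amplitude_sd=0.3 * effect_amplitude,
            name="hyper",
        ),
        ConditionEffect(
            nodes=node_pool[5:10].tolist(),
            condition="DMT",
            amplitude=-effect_amplitude,
            amplitude_sd=0.3 * effect_amplitude,
            name="hypo",
        ),
    ]
    coupling = {
        "item_05": ("region_effect_hyper", 0.6),
        "item_12": ("hr_change", 0.6),
    }
    shifts = {"item_01": 0.35}  # a drug-intensity-like item, shifted under drug
    return CohortSpec(
        n_participants=n_participants,
        n_nodes=n_nodes,
        n_volumes=n_volumes,
        injection_volume=injection_volume,
        seed=seed,
        noise_sd=noise_sd,
        substate_plan=plan,
        condition_effects=effects,
        vas_coupling=coupling,
        vas_shifts=shifts,
    )


def _affiliation_from_plan(spec: CohortSpec, condition: str) -> np.ndarray:
    labels = np.zeros(spec.n_volumes, dtype=int)
    for st in spec.substate_plan:
        for a, b in st.windows.get(condition, []):
            labels[a - 1 : b] = st.label
    return labels


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the paired cohort: nodal series + heart-rate ground truth.

    For every participant and condition the nodal series is the planted
    state pattern over its windows, plus condition-specific regional
    effects, plus i.i.d. Gaussian noise of sd ``spec.noise_sd``. Windows are
    identical across participants. Bit-identical for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    participants = [f"sub-{i + 1:02d}" for i in range(spec.n_participants)]

    # per-participant effect amplitudes and heart-rate parameters (drawn
    # before the big noise arrays so that draw order is stable)
    eff_amps: dict[str, np.ndarray] = {}
    for i, eff in enumerate(spec.condition_effects):
        name = eff.name or str(i)
        eff_amps[f"region_effect_{name}"] = eff.amplitude + eff.amplitude_sd * rng.standard_normal(
            spec.n_participants
        )
    hre = spec.hr_effects
    baselines = hre.baseline_bpm + hre.baseline_sd * rng.standard_normal(spec.n_participants)
    baselines = np.clip(baselines, 40.0, 140.0)
    hr_change = hre.dmt_increase_bpm + hre.increase_sd * rng.standard_normal(spec.n_participants)

    scan_s = spec.n_volumes * spec.tr_seconds
    injection_s = spec.injection_volume * spec.tr_seconds

    series: dict[tuple[str, str], ParcelTimeSeries] = {}
    rr_plans: dict[tuple[str, str], np.ndarray] = {}
    hr_vol: dict[tuple[str, str], np.ndarray] = {}
    affil = {c: _affiliation_from_plan(spec, c) for c in CONDITIONS}

    for p, pid in enumerate(participants):
        for cond in CONDITIONS:
            base = np.zeros((spec.n_nodes, spec.n_volumes))
            for st in spec.substate_plan:
                for a, b in st.windows.get(cond, []):
                    base[:, a - 1 : b] += st.amplitude * st.spatial_pattern[:, None]
            for i, eff in enumerate(spec.condition_effects):
                if eff.condition != cond:
                    continue
                name = eff.name or str(i)
                amp = eff_amps[f"region_effect_{name}"][p]
                sl = slice(spec.injection_volume, None) if eff.post_only else slice(None)
                base[np.asarray(eff.nodes)[:, None], sl] += amp
            noise = rng.standard_normal(base.shape) * spec.noise_sd
            series[(pid, cond)] = ParcelTimeSeries(
                values=base + noise,
                tr_seconds=spec.tr_seconds,
                injection_volume=spec.injection_volume,
                participant_id=pid,
                condition=cond,
            )

            # planted RR plan: constant baseline; drug adds the planted
            # post-injection increase
            bpm_pre = baselines[p]
            bpm_post = baselines[p] + (hr_change[p] if cond == "DMT" else 0.0)
            rr: list[float] = []
            t = 0.0
            while t < scan_s + 2.0:
                bpm = bpm_pre if t < injection_s else bpm_post
                rr.append(60.0 / bpm)
                t += rr[-1]
            rr_plans[(pid, cond)] = np.asarray(rr)
            vols = np.arange(spec.n_volumes) * spec.tr_seconds
            hr_vol[(pid, cond)] = np.where(vols < injection_s, bpm_pre, bpm_post)

    truth = CohortTruth(
        affiliation=affil,
        state_labels=sorted({st.label for st in spec.substate_plan if "DMT" in st.windows}),
        sources={**eff_amps, "hr_change": hr_change, "hr_baseline": baselines},
        rr_plans=rr_plans,
        hr_volume_bpm=hr_vol,
        participants=participants,
    )
    return Cohort(series=series, truth=truth, spec=spec)


def generate_ekg(
    rr_plan: np.ndarray,
    fs: float = 250.0,
    peak_amplitude: float = 15000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    qrs_width_s: float = 0.08,
) -> tuple[EKGTrace, np.ndarray]:
    """Synthesize an EKG-like trace from a planned RR sequence.

    One biphasic QRS surrogate (Mexican-hat pulse, main lobe ~``qrs_width_s``)
    is placed at each cumulative RR time; Gaussian noise of sd ``noise_sd``
    (microvolts) is added. Returns the trace and the true peak sample
    indices.
    """
    rr = np.asarray(rr_plan, dtype=float)
    if rr.ndim != 1 or rr.size == 0:
        raise ValueError("rr_plan must be a non-empty 1-D sequence")
    if np.any(rr <= 0):
        raise ValueError("all RR intervals must be positive")
    # crude QRS bandwidth ~ 2 / width; require fs above twice that
    if fs <= 4.0 / qrs_width_s:
        raise ValueError(f"fs={fs} too low for a {qrs_width_s * 1000:.0f} ms QRS pulse")

    beat_times = np.cumsum(rr)
    peak_idx = np.round(beat_times * fs).astype(int)
    n = peak_idx[-1] + int(round(0.5 * fs))

    a = (qrs_width_s / 2) * fs  # Ricker scale in samples; zero-crossings at +-a
    half = int(np.ceil(4 * a))
    t = np.arange(-half, half + 1)
    template = (1 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    template *= peak_amplitude

    x = np.zeros(n)
    for k in peak_idx:
        lo, hi = k - half, k + half + 1
        tl, th = max(0, -lo), len(t) - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += template[tl:th]
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return EKGTrace(x, fs=fs), peak_idx


def _vas_grid(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 100.0) / 100.0, 0.0, 1.0)


def generate_vas(
    truth: CohortTruth | dict[str, np.ndarray],
    coupling: dict[str, tuple[str, float]] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_items: int = 25,
    shifts: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired 25-item VAS ratings coupled to planted effects.

    ``coupling`` maps an item name to ``(source, coefficient)``, where
    ``source`` names a per-participant ground-truth quantity (e.g.
    ``"region_effect_hyper"``, ``"hr_change"``). The drug-minus-placebo
    change score of a coupled item is ``0.2 * c * z(source)`` plus coupling
    noise of sd ``noise_sd``; each rating additionally carries independent
    N(0, noise_sd^2) rating noise. At ``noise_sd = 0`` the
    change score is an exact linear map of the source (so the sample
    correlation equals the coefficient sign-for-sign, up to 0.01-grid
    quantization), and the scaling is calibrated so that the observed
    change-vs-source correlation is close to ``c`` at the default noise
    level. ``shifts`` adds a fixed drug-minus-placebo mean shift to named
    items (an intensity-like main effect). Ratings are clipped to [0, 1]
    on the 0.01 grid.

    Returns ``(vas_dmt, vas_pcb)`` DataFrames (participants × items).
    """
    sources = truth.sources if isinstance(truth, CohortTruth) else dict(truth)
    if not sources:
        raise ValueError("truth provides no couplable sources")
    n_part = len(next(iter(sources.values())))
    if isinstance(truth, CohortTruth):
        index = truth.participants
    else:
        index = [f"sub-{i + 1:02d}" for i in range(n_part)]
    coupling = coupling or {}
    for item, (src, _c) in coupling.items():
        if src not in sources:
            raise ValueError(f"unknown coupling source {src!r} for item {item!r}")

    rng = np.random.default_rng(seed)
    items = [f"item_{i + 1:02d}" for i in range(n_items)]
    base = rng.uniform(0.40, 0.60, size=n_items)  # headroom against clipping

    change = np.zeros((n_part, n_items))
    for j, item in enumerate(items):
        if shifts and item in shifts:
            change[:, j] += shifts[item]
        if item in coupling:
            src, c = coupling[item]
            v = np.asarray(sources[src], dtype=float)
            sdv = v.std()
            z = (v - v.mean()) / sdv if sdv > 0 else np.zeros_like(v)
            change[:, j] = VAS_COUPLING_SCALE * c * z + noise_sd * rng.standard_normal(n_part)

    shape = (n_part, n_items)
    noise_p = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    noise_d = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
    pcb = _vas_grid(base[None, :] + noise_p)
    dmt = _vas_grid(base[None, :] + change + noise_d)
    return (
        pd.DataFrame(dmt, index=index, columns=items),
        pd.DataFrame(pcb, index=index, columns=items),
    )
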