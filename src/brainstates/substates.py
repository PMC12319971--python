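"""Temporal substate detection on the subtraction matrix.

The drug-minus-placebo subtraction matrix is swept over Pearson-difference
thresholds (default 0.20-0.30 in steps of 0.01, positive entries only).
Each thresholded matrix is treated as a weighted graph over fMRI volumes
and partitioned with a Louvain modularity optimization; the resulting
community affiliation vector assigns every volume to a temporal substate.
Per-substate occupancy before vs after the injection is compared with
Pearson chi-square tests, and the operating threshold is the one maximizing
the number of substates that are both substantially occupied (>= 10% of a
period) and significantly pre/post separable. A k-means clustering of the
matrix rows is provided as a control path.

Louvain here optimizes the signed-weight modularity of Rubinov & Sporns:
with W+ / W- the positive and negative parts of the weight matrix and
s+/s- their total weights, the "symmetric" treatment uses

    B = (B+ - B-) / (s+ + s-),      B+- = W+- - gamma * k k^T / s+-

(positive and negative contributions weighted equally), while the
"asymmetric" treatment down-weights the negative term,

    B = B+/s+ - B-/(s+ + s-).

After positive-only thresholding the two coincide with standard Newman
modularity. Optimization is a locally greedy node-move pass with community
aggregation, restarted ``n_restarts`` times from random node orders; the
best-quality partition is kept, making results reproducible for a fixed
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .similarity import SubtractionMatrix

__all__ = [
    "AffiliationVector",
    "SubstateSummary",
    "SeparabilityResult",
    "ThresholdSweepResult",
    "threshold_matrix",
    "modularity_matrix",
    "modularity",
    "louvain_communities",
    "occupancy",
    "occupancy_minutes",
    "separability_chi2",
    "retained_substates",
    "threshold_sweep",
    "kmeans_control",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = np.round(np.arange(0.20, 0.301, 0.01), 2)
#: resolution parameter of the modularity quality function
DEFAULT_GAMMA = 1.0
DEFAULT_RESTARTS = 100
MIN_OCCUPANCY = 0.10
ALPHA = 0.05


@dataclass
class AffiliationVector:
    """Per-volume substate labels (1..k contiguous; 0 = unassigned)."""

    labels: np.ndarray
    k: int
    threshold: float | None = None
    q: float | None = None
    singleton_volumes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels[self.labels > 0])
        if present.size and (present[0] != 1 or present[-1] != present.size):
            raise ValueError("labels must be contiguous integers starting at 1")
        if self.k != present.size:
            raise ValueError(f"k={self.k} does not match {present.size} labels present")

    @property
    def n_volumes(self) -> int:
        return self.labels.size


@dataclass
class SubstateSummary:
    """Occupancy and separability statistics for one substate."""

    label: int
    pre_occupancy: float
    post_occupancy: float
    pre_minutes: float
    post_minutes: float
    chi2: float = np.nan
    p_value: float = np.nan
    retained: bool = False


@dataclass
class SeparabilityResult:
    omnibus_chi2: float
    df: int
    p_value: float
    per_state: dict[int, tuple[float, float]]  # label -> (chi2, p)
    method: str = "omnibus"


def threshold_matrix(
    S: SubtractionMatrix, r: float, use_absolute: bool = False
) -> np.ndarray:
    """Keep entries >= r at their value, zero the rest (and the diagonal).

    Positive-only by default, which targets periods of higher similarity
    under the drug; ``use_absolute`` keeps entries with ``|value| >= r``
    (at their signed value) instead.
    """
    if not 0.20 <= r <= 0.30:
        warnings.warn(
            f"threshold {r} outside the calibrated sweep range [0.20, 0.30]",
            stacklevel=2,
        )
    vals = S.values
    keep = np.abs(vals) >= r if use_absolute else vals >= r
    W = np.where(keep, vals, 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def modularity_matrix(
    W: np.ndarray, gamma: float = DEFAULT_GAMMA, neg_treatment: str = "symmetric"
) -> np.ndarray:
    """Signed-weight modularity matrix (see module docstring)."""
    if neg_treatment not in ("symmetric", "asymmetric"):
        raise ValueError("neg_treatment must be 'symmetric' or 'asymmetric'")
    W = np.asarray(W, dtype=float)
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    sp, sn = Wp.sum(), Wn.sum()
    n = W.shape[0]
    Bp = Wp - gamma * np.outer(Wp.sum(1), Wp.sum(1)) / sp if sp > 0 else np.zeros((n, n))
    Bn = Wn - gamma * np.outer(Wn.sum(1), Wn.sum(1)) / sn if sn > 0 else np.zeros((n, n))
    if sp + sn == 0:
        raise ValueError("empty graph: all weights are zero (over-thresholded)")
    if neg_treatment == "symmetric":
        return (Bp - Bn) / (sp + sn)
    return Bp / sp - (Bn / (sp + sn) if sn > 0 else 0.0)


def modularity(
    W: np.ndarray,
    labels: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    neg_treatment: str = "symmetric",
) -> float:
    """Quality Q of a partition under the signed modularity."""
    B = modularity_matrix(W, gamma, neg_treatment)
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += B[np.ix_(idx, idx)].sum()
    return float(q)


def _louvain_once(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain run on a dense (signed) modularity matrix."""
    n0 = B.shape[0]
    assign = np.arange(n0)
    Bcur = B
    while True:
        n = Bcur.shape[0]
        comm = np.arange(n)
        moved_any = False
        for _ in range(1000):  # convergence guard
            moved = False
            for u in rng.permutation(n):
                row = Bcur[u]
                gains = np.bincount(comm, weights=row, minlength=n)
                gains[comm[u]] -= row[u]  # self-term moves with u
                best = int(np.argmax(gains))
                if gains[best] - gains[comm[u]] > 1e-12:
                    comm[u] = best
                    moved = moved_any = True
            if not moved:
                break
        if not moved_any:
            return assign
        _, comm = np.unique(comm, return_inverse=True)
        k = comm.max() + 1
        H = np.zeros((n, k))
        H[np.arange(n), comm] = 1.0
        Bcur = H.T @ Bcur @ H
        assign = comm[assign]
        if k == n:
            return assign


def louvain_communities(
    W: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    neg_treatment: str = "symmetric",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> tuple[AffiliationVector, float]:
    """Best-of-``n_restarts`` Louvain partition of a weighted volume graph.

    Volumes with zero total (absolute) weight are removed before
    optimization and returned as singleton substates, recorded in
    ``AffiliationVector.singleton_volumes``. Raises if the graph is empty.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    n = W.shape[0]
    strength = np.abs(W).sum(1)
    active = strength > 0
    if not active.any():
        raise ValueError("empty graph: all weights are zero (over-thresholded)")
    idx = np.flatnonzero(active)
    Wa = W[np.ix_(idx, idx)]
    B = modularity_matrix(Wa, gamma, neg_treatment)

    rng = np.random.default_rng(seed)
    best_q, best_part = -np.inf, None
    for _ in range(max(1, n_restarts)):
        part = _louvain_once(B, rng)
        H = np.zeros((part.size, part.max() + 1))
        H[np.arange(part.size), part] = 1.0
        q = float(np.trace(H.T @ B @ H))
        if q > best_q + 1e-15:
            best_q, best_part = q, part

    # relabel communities 1..k in order of first occurrence in time
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for pos, orig in zip(idx, best_part):
        if orig not in mapping:
            mapping[orig] = len(mapping) + 1
        labels[pos] = mapping[orig]
    k = len(mapping)
    singletons = np.flatnonzero(~active)
    for v in singletons:
        k += 1
        labels[v] = k
    return (
        AffiliationVector(
            labels=labels,
            k=k,
            q=best_q,
            singleton_volumes=(singletons + 1).tolist(),
        ),
        best_q,
    )


def occupancy_minutes(fraction: float, period_minutes: float) -> float:
    """Occupancy fraction -> minutes of the period, 1-decimal rounding."""
    return round(fraction * period_minutes, 1)


def occupancy(
    affil: AffiliationVector,
    injection_volume: int,
    tr_seconds: float = 2.0,
) -> list[SubstateSummary]:
    """Per-substate occupancy of the pre- and post-injection periods.

    Occupancy is the state's volume count in a period divided by the
    period's (assigned) volume count; minutes are occupancy times the
    period duration. Unassigned volumes (label 0) are excluded from the
    denominators.
    """
    labels = affil.labels
    vol = np.arange(1, labels.size + 1)
    pre = (vol <= injection_volume) & (labels > 0)
    post = (vol > injection_volume) & (labels > 0)
    n_pre, n_post = int(pre.sum()), int(post.sum())
    if n_pre == 0 or n_post == 0:
        raise ValueError("a period contains no assigned volumes")
    pre_min = injection_volume * tr_seconds / 60.0
    post_min = (labels.size - injection_volume) * tr_seconds / 60.0
    out = []
    for s in range(1, affil.k + 1):
        po = float(np.sum(pre & (labels == s)) / n_pre)
        qo = float(np.sum(post & (labels == s)) / n_post)
        out.append(
            SubstateSummary(
                label=s,
                pre_occupancy=po,
                post_occupancy=qo,
                pre_minutes=po * pre_min,
                post_minutes=qo * post_min,
            )
        )
    return out


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    # Pearson chi-square without continuity correction
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def separability_chi2(
    affil: AffiliationVector,
    injection_volume: int,
    method: str = "omnibus",
) -> SeparabilityResult:
    """Chi-square separability of substate occupancy, pre vs post injection.

    The omnibus statistic is the Pearson chi-square of the k×2 contingency
    table of volume counts (state × period); per-state statistics come from
    2×2 tables (state vs rest × period), without continuity correction.
    ``method="sum"`` reports the sum of the per-state statistics as the
    separability index instead.
    """
    if method not in ("omnibus", "sum"):
        raise ValueError("method must be 'omnibus' or 'sum'")
    if affil.k < 2:
        raise ValueError("need at least 2 substates for a separability test")
    labels = affil.labels
    vol = np.arange(1, labels.size + 1)
    pre = (vol <= injection_volume) & (labels > 0)
    post = (vol > injection_volume) & (labels > 0)
    if pre.sum() == 0 or post.sum() == 0:
        raise ValueError("a period contains no assigned volumes")

    counts = np.array(
        [
            [np.sum(pre & (labels == s)), np.sum(post & (labels == s))]
            for s in range(1, affil.k + 1)
        ],
        dtype=float,
    )
    per_state: dict[int, tuple[float, float]] = {}
    for s in range(1, affil.k + 1):
        row = counts[s - 1]
        rest = counts.sum(axis=0) - row
        per_state[s] = _chi2_2x2(np.array([row, rest]))

    nz = counts[counts.sum(axis=1) > 0]
    if np.allclose(counts.sum(axis=0), 0) or nz.shape[0] < 2:
        omni, p, df = 0.0, 1.0, 0
    else:
        omni, p, df, _ = stats.chi2_contingency(nz, correction=False)
    if method == "sum":
        omni = float(sum(c for c, _ in per_state.values()))
        df = affil.k
        p = float(stats.chi2.sf(omni, df))
    return SeparabilityResult(float(omni), int(df), float(p), per_state, method)


def retained_substates(
    summaries: list[SubstateSummary],
    min_occupancy: float = MIN_OCCUPANCY,
    alpha: float = ALPHA,
) -> list[int]:
    """Substates that are significantly pre/post separable (p < alpha) and
    substantially occupied (>= ``min_occupancy`` of either period).

    Sets the ``retained`` flag on the summaries and returns the labels.
    """
    kept = []
    for s in summaries:
        s.retained = bool(
            np.isfinite(s.p_value)
            and s.p_value < alpha
            and (s.pre_occupancy >= min_occupancy or s.post_occupancy >= min_occupancy)
        )
        if s.retained:
            kept.append(s.label)
    return kept


@dataclass
class SweepRow:
    threshold: float
    k: int
    n_retained: int
    omnibus_chi2: float
    selected: bool = False
    affiliation: AffiliationVector | None = None
    summaries: list[SubstateSummary] = field(default_factory=list)


@dataclass
class ThresholdSweepResult:
    rows: list[SweepRow]

    @property
    def selected(self) -> SweepRow:
        return next(r for r in self.rows if r.selected)

    @property
    def selected_threshold(self) -> float:
        return self.selected.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": r.threshold,
                    "k": r.k,
                    "n_retained": r.n_retained,
                    "omnibus_chi2": r.omnibus_chi2,
                    "selected": r.selected,
                }
                for r in self.rows
            ]
        )


def threshold_sweep(
    S: SubtractionMatrix,
    thresholds: np.ndarray | None = None,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    min_occupancy: float = MIN_OCCUPANCY,
    alpha: float = ALPHA,
    neg_treatment: str = "symmetric",
    chi2_method: str = "omnibus",
) -> ThresholdSweepResult:
    """Threshold sweep with data-driven operating-point selection.

    For each threshold: threshold the subtraction matrix, partition with
    Louvain, compute occupancy and pre/post chi-square separability, and
    count retained substates. The selected threshold maximizes the retained
    count; ties go to the larger omnibus chi-square, then to the smaller
    threshold. Thresholds that empty the graph are recorded with k = 0.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    rng = np.random.default_rng(seed)
    rows: list[SweepRow] = []
    for r in np.asarray(thresholds, dtype=float):
        sub_seed = int(rng.integers(2**31 - 1))
        W = threshold_matrix(S, float(r))
        if not np.any(W != 0):
            rows.append(SweepRow(float(r), 0, 0, np.nan))
            continue
        affil, _q = louvain_communities(
            W, gamma=gamma, neg_treatment=neg_treatment, seed=sub_seed, n_restarts=n_restarts
        )
        affil.threshold = float(r)
        summaries = occupancy(affil, S.injection_volume, S.tr_seconds)
        if affil.k >= 2:
            sep = separability_chi2(affil, S.injection_volume, method=chi2_method)
            for s in summaries:
                s.chi2, s.p_value = sep.per_state[s.label]
            omni = sep.omnibus_chi2
        else:
            omni = 0.0
        kept = retained_substates(summaries, min_occupancy, alpha)
        rows.append(
            SweepRow(float(r), affil.k, len(kept), float(omni), False, affil, summaries)
        )
    if all(row.k == 0 for row in rows):
        raise ValueError("all thresholds yield an empty graph")

    def key(row: SweepRow):
        chi2 = row.omnibus_chi2 if np.isfinite(row.omnibus_chi2) else -np.inf
        return (row.n_retained, chi2, -row.threshold)

    best = max(rows, key=key)
    best.selected = True
    return ThresholdSweepResult(rows)


def kmeans_control(
    S: SubtractionMatrix,
    k: int = 3,
    max_iter: int = 10000,
    replicates: int = 10,
    seed: int = 0,
) -> tuple[AffiliationVector, np.ndarray]:
    """k-means control clustering of subtraction-matrix rows.

    Runs ``replicates`` independent initializations and keeps the partition
    with the lowest within-cluster sum of squares. Returns the affiliation
    vector (labels renumbered by first occurrence in time) and the
    per-replicate inertias.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    T = S.n_volumes
    if k > T:
        raise ValueError(f"k={k} exceeds the number of volumes {T}")
    rng = np.random.default_rng(seed)
    best_labels, inertias = None, []
    for _ in range(replicates):
        km = KMeans(
            n_clusters=k,
            n_init=1,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(S.values)
        inertias.append(km.inertia_)
        if best_labels is None or km.inertia_ < min(inertias[:-1]):
            best_labels = km.labels_
    _, inv = np.unique(best_labels, return_inverse=True)
    # renumber by first occurrence in time
    order = {c: i + 1 for i, c in enumerate(pd.unique(inv))}
    labels = np.array([order[c] for c in inv])
    return AffiliationVector(labels=labels, k=k), np.asarray(inertias)
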