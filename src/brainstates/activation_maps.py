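"""Substate activation maps and condition contrasts.

Given a participant's nodal time series and the group affiliation vector,
per-substate activity is summarized two ways: z-maps (state mean relative
to whole-scan mean, in units of the node's temporal SD) and GLM beta-maps.
The beta GLM regresses each node's time series on one indicator regressor
per substate with no intercept, so beta(node, state) is exactly the node's
mean activity during that state. Beta-maps are contrasted across
conditions with paired t-tests, Benjamini-Hochberg FDR corrected across
nodes, yielding hyper-/hypoactivity node masks used for ROI averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .similarity import ParcelTimeSeries
from .substates import AffiliationVector

__all__ = [
    "BetaMap",
    "ContrastResult",
    "state_mean_zmaps",
    "beta_maps_glm",
    "stack_beta_maps",
    "paired_contrast",
    "fdr_bh",
    "roi_average",
]


@dataclass
class BetaMap:
    """GLM state-activity estimates: participants × nodes × substates."""

    betas: np.ndarray
    state_labels: list[int]
    condition: str = ""
    participants: list[str] = field(default_factory=list)
    design: str = "per-substate indicator regressors, no intercept"

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be participants x nodes x substates")
        if self.betas.shape[2] != len(self.state_labels):
            raise ValueError("substate axis does not match state_labels")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")


@dataclass
class ContrastResult:
    """Per-node paired-contrast statistics for one substate."""

    state: int
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    hyper_mask: np.ndarray  # node indices, q < alpha and t > 0
    hypo_mask: np.ndarray
    alpha: float
    degenerate_nodes: np.ndarray  # zero-variance difference, flagged


def state_mean_zmaps(
    ts: ParcelTimeSeries,
    affil: AffiliationVector,
    state_labels: list[int] | None = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Per-node, per-substate z-scored mean activity (nodes × substates).

    z(node, state) = (mean within state - reference mean) / reference SD,
    where the reference is the whole scan by default, or the scan excluding
    the state's own volumes with ``exclude_self``.
    """
    if affil.n_volumes != ts.n_volumes:
        raise ValueError("affiliation and time series differ in volume count")
    labels = affil.labels
    if state_labels is None:
        state_labels = list(range(1, affil.k + 1))
    out = np.empty((ts.n_nodes, len(state_labels)))
    for j, s in enumerate(state_labels):
        in_state = labels == s
        if not in_state.any():
            raise ValueError(f"substate {s} occupies no volumes")
        ref = ~in_state if exclude_self else np.ones_like(in_state)
        mu = ts.values[:, ref].mean(axis=1)
        sd = ts.values[:, ref].std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero temporal SD at node(s) {bad.tolist()[:5]}")
        out[:, j] = (ts.values[:, in_state].mean(axis=1) - mu) / sd
    return out


def beta_maps_glm(
    ts: ParcelTimeSeries,
    affil: AffiliationVector,
    state_labels: list[int] | None = None,
) -> np.ndarray:
    """OLS beta estimates (nodes × substates) from the indicator GLM.

    The design has one column per substate (1 when the volume belongs to
    the substate, else 0) and no intercept; with this design the OLS
    solution equals the within-state mean of each node. States occupying
    fewer than 2 volumes make the design unusable and are rejected.
    """
    if affil.n_volumes != ts.n_volumes:
        raise ValueError("affiliation and time series differ in volume count")
    if state_labels is None:
        state_labels = list(range(1, affil.k + 1))
    X = np.column_stack([(affil.labels == s).astype(float) for s in state_labels])
    counts = X.sum(axis=0)
    empty = [state_labels[j] for j in np.flatnonzero(counts < 2)]
    if empty:
        raise ValueError(f"substate(s) {empty} occupy < 2 volumes; design is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    return beta.T  # nodes x substates


def stack_beta_maps(
    series: list[ParcelTimeSeries],
    affil: AffiliationVector,
    state_labels: list[int] | None = None,
) -> BetaMap:
    """Stack per-participant GLM beta maps into one BetaMap."""
    if not series:
        raise ValueError("no time series given")
    if state_labels is None:
        state_labels = list(range(1, affil.k + 1))
    betas = np.stack([beta_maps_glm(ts, affil, state_labels) for ts in series])
    return BetaMap(
        betas=betas,
        state_labels=list(state_labels),
        condition=series[0].condition,
        participants=[ts.participant_id for ts in series],
    )


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q values, rejection mask)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def paired_contrast(
    beta_dmt: BetaMap,
    beta_pcb: BetaMap,
    state: int,
    alpha: float = 0.05,
) -> ContrastResult:
    """Node-wise paired t contrast of one substate's betas across conditions.

    Differences are drug minus placebo; p-values are BH-FDR corrected
    across nodes within the substate. Nodes with zero-variance differences
    are flagged: t = 0, p = 1 when the mean difference is also zero,
    otherwise t = ±inf, p = 0.
    """
    if beta_dmt.betas.shape != beta_pcb.betas.shape:
        raise ValueError("beta maps differ in shape")
    if beta_dmt.participants != beta_pcb.participants:
        raise ValueError("beta maps cover different participants")
    n = beta_dmt.betas.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired participants")
    j = beta_dmt.state_labels.index(state)
    d = beta_dmt.betas[:, :, j] - beta_pcb.betas[:, :, j]  # participants x nodes
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    t[degenerate] = np.where(mean[degenerate] == 0, 0.0, np.sign(mean[degenerate]) * np.inf)
    p[degenerate] = np.where(mean[degenerate] == 0, 1.0, 0.0)
    q, reject = fdr_bh(p, alpha)
    return ContrastResult(
        state=state,
        t=t,
        p=p,
        q=q,
        hyper_mask=np.flatnonzero(reject & (t > 0)),
        hypo_mask=np.flatnonzero(reject & (t < 0)),
        alpha=alpha,
        degenerate_nodes=degenerate,
    )


def roi_average(values: np.ndarray, mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unweighted mean over a node mask.

    ``axis`` selects the node axis: 0 for (nodes,) or (nodes × volumes)
    arrays, 1 for (participants × nodes) beta slices.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("empty ROI mask")
    values = np.asarray(values, dtype=float)
    return np.take(values, mask, axis=axis).mean(axis=axis)
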