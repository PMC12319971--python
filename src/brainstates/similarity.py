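"""Time-resolved brain-activity similarity matrices.

Each fMRI volume is a spatial pattern: one activity value per parcellated
node (default 112 = 100 cortical + 12 subcortical parcels). Correlating the
pattern at volume *i* with the pattern at volume *j*, for every pair of
volumes, yields a symmetric T×T matrix describing how homogeneous brain
activity is across time. Subtracting the group-mean matrix of one condition
from the other isolates periods in which brain activity is more similar in
time under the drug than under placebo; that subtraction matrix is the input
to community-based substate detection (:mod:`brainstates.substates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "TimeSimilarityMatrix",
    "SubtractionMatrix",
    "time_similarity_matrix",
    "group_mean_matrix",
    "subtraction_matrix",
]


@dataclass
class ParcelTimeSeries:
    """Nodal activity for one participant in one condition.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_volumes)
        Parcel-averaged BOLD activity (arbitrary units).
    tr_seconds : float
        Repetition time between volumes.
    injection_volume : int
        1-based index of the last pre-injection volume (240 for the default
        timing: injection at the end of minute 8 with TR = 2 s).
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    injection_volume: int = 240
    participant_id: str = ""
    condition: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (nodes x volumes)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if not 0 < self.injection_volume < self.n_volumes:
            raise ValueError(
                f"injection_volume={self.injection_volume} must lie strictly "
                f"inside the scan (1..{self.n_volumes - 1})"
            )
        if not self.node_labels:
            self.node_labels = [f"node_{i + 1:03d}" for i in range(self.n_nodes)]
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class TimeSimilarityMatrix:
    """T×T Pearson correlations between spatial patterns of volume pairs."""

    values: np.ndarray
    tr_seconds: float = 2.0
    injection_volume: int = 240

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        T = self.values.shape[0]
        if self.values.shape != (T, T):
            raise ValueError("similarity matrix must be square")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class SubtractionMatrix:
    """Condition difference (drug minus placebo) of similarity matrices."""

    values: np.ndarray
    tr_seconds: float = 2.0
    injection_volume: int = 240

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        T = self.values.shape[0]
        if self.values.shape != (T, T):
            raise ValueError("subtraction matrix must be square")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


def time_similarity_matrix(ts: ParcelTimeSeries) -> TimeSimilarityMatrix:
    """Correlate the whole-brain spatial pattern of every volume pair.

    Entry (i, j) is the Pearson correlation, across nodes, between the
    activity vectors at volumes i and j.  Requires at least 3 nodes and
    non-zero spatial variance at every volume.
    """
    if ts.n_nodes < 3:
        raise ValueError("need at least 3 nodes for spatial correlation")
    sd = ts.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero spatial variance at volume(s) {(bad + 1).tolist()[:5]}"
        )
    corr = np.corrcoef(ts.values.T)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return TimeSimilarityMatrix(
        values=corr,
        tr_seconds=ts.tr_seconds,
        injection_volume=ts.injection_volume,
    )


def group_mean_matrix(matrices: list[TimeSimilarityMatrix]) -> TimeSimilarityMatrix:
    """Elementwise mean of same-shape similarity matrices (group average)."""
    if not matrices:
        raise ValueError("no matrices given")
    T = matrices[0].n_volumes
    inj = matrices[0].injection_volume
    for m in matrices:
        if m.n_volumes != T:
            raise ValueError(f"shape mismatch: {m.n_volumes} vs {T} volumes")
        if m.injection_volume != inj:
            raise ValueError("injection_volume differs across matrices")
    mean = np.mean([m.values for m in matrices], axis=0)
    return TimeSimilarityMatrix(
        values=mean,
        tr_seconds=matrices[0].tr_seconds,
        injection_volume=inj,
    )


def subtraction_matrix(
    dmt: TimeSimilarityMatrix, pcb: TimeSimilarityMatrix
) -> SubtractionMatrix:
    """Drug-minus-placebo similarity difference; diagonal forced to zero."""
    if dmt.n_volumes != pcb.n_volumes:
        raise ValueError("matrices differ in volume count")
    if dmt.injection_volume != pcb.injection_volume:
        raise ValueError("matrices differ in injection_volume")
    diff = dmt.values - pcb.values
    np.fill_diagonal(diff, 0.0)
    return SubtractionMatrix(
        values=diff,
        tr_seconds=dmt.tr_seconds,
        injection_volume=dmt.injection_volume,
    )
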