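"""Continuous heart rate from EKG traces.

The processing chain mirrors a standard MR-compatible EKG workflow:

1. rectify (negative voltages to zero, sharpening R-peak prominence),
2. wavelet band-pass enhancement around the QRS band (~5-32 Hz),
3. constrained peak detection (minimum height 7,500 uV, minimum inter-beat
   distance 0.45 s),
4. instantaneous heart rate HR_t = 60 / RR between successive R-peaks,
   sampled at 250 Hz,
5. down-sampling to the fMRI volume grid (0.5 Hz for TR = 2 s) by averaging
   within each non-overlapping TR window.

Traces recorded at higher rates (e.g. 5 kHz) are decimated to 250 Hz with an
anti-aliasing polyphase filter before detection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import pywt
from scipy import signal

__all__ = [
    "EKGTrace",
    "RPeakSeries",
    "HeartRateSeries",
    "rectify_trace",
    "decimate_trace",
    "wavelet_enhance",
    "detect_r_peaks",
    "instantaneous_hr",
    "resample_hr",
    "mean_hr_in_state",
    "process_ekg",
    "read_ekg_csv",
    "write_hr_csv",
    "hr_qc_report",
]

#: sampling rate (Hz) of the instantaneous heart-rate signal
HR_FS = 250.0
#: default QRS enhancement band (Hz)
QRS_BAND = (5.0, 32.0)
#: default peak-detection constraints
MIN_HEIGHT_UV = 7500.0
MIN_DISTANCE_S = 0.45


@dataclass
class EKGTrace:
    """Raw or processed EKG voltage trace.

    samples are in microvolts; ``t0`` is the trace start time in seconds
    relative to the start of the fMRI scan.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace must be a 1-D array of length >= 2")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class RPeakSeries:
    """Detected R-peaks: sample indices (strictly increasing) and times."""

    peak_indices: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.peak_indices.size and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def peak_times(self) -> np.ndarray:
        return self.t0 + self.peak_indices / self.fs

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size

    def rr_intervals(self) -> np.ndarray:
        """Inter-beat intervals in seconds."""
        return np.diff(self.peak_times)


@dataclass
class HRSignal:
    """Piecewise-constant instantaneous heart rate at a fixed sampling rate."""

    bpm: np.ndarray
    fs: float = HR_FS
    t0: float = 0.0


@dataclass
class HeartRateSeries:
    """Heart rate on the fMRI volume grid (one bpm value per volume).

    Volumes whose TR window contained no HR samples are NaN ("missing").
    """

    bpm: np.ndarray
    tr_seconds: float = 2.0
    volume_alignment: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.volume_alignment is None:
            self.volume_alignment = np.arange(1, self.bpm.size + 1)
        self.volume_alignment = np.asarray(self.volume_alignment, dtype=int)

    @property
    def n_volumes(self) -> int:
        return self.bpm.size


def rectify_trace(trace: EKGTrace) -> EKGTrace:
    """Set negative voltages to zero (improves R-peak detectability)."""
    return EKGTrace(np.maximum(trace.samples, 0.0), fs=trace.fs, t0=trace.t0)


def decimate_trace(trace: EKGTrace, target_fs: float = HR_FS) -> EKGTrace:
    """Anti-aliased resampling of a trace to ``target_fs`` (polyphase)."""
    if trace.fs == target_fs:
        return trace
    frac = Fraction(target_fs / trace.fs).limit_denominator(10000)
    out = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return EKGTrace(out, fs=target_fs, t0=trace.t0)


def _swt_level_band(fs: float, level: int) -> tuple[float, float]:
    # detail level j of a dyadic wavelet transform passes ~[fs/2^(j+1), fs/2^j]
    return fs / 2 ** (level + 1), fs / 2**level


def wavelet_enhance(
    trace: EKGTrace,
    band: tuple[float, float] = QRS_BAND,
    wavelet: str = "db4",
) -> EKGTrace:
    """Band-limited reconstruction via a stationary (undecimated) wavelet
    transform.

    Detail levels whose dyadic pass-band intersects ``band`` are retained;
    the approximation is retained only if ``band`` extends below the lowest
    detail level. The reconstruction has the same length as the input and
    preserves the location of an isolated QRS pulse to within one sample.
    """
    lo, hi = band
    nyq = trace.fs / 2
    if not (0 < lo < hi <= nyq):
        raise ValueError(f"band {band} must lie within (0, {nyq}] Hz")

    # deepest level whose pass-band reaches down to `lo`
    n_levels = max(1, int(np.ceil(np.log2(trace.fs / lo) - 1)))
    n = trace.samples.size
    max_possible = pywt.swt_max_level(int(2 ** np.ceil(np.log2(max(n, 2)))))
    n_levels = min(n_levels, max_possible, 12)

    pad_to = int(np.ceil(n / 2**n_levels)) * 2**n_levels
    x = np.pad(trace.samples, (0, pad_to - n), mode="edge")

    coeffs = pywt.swt(x, wavelet, level=n_levels, norm=True)
    # coeffs[0] is the deepest level: (cA_J, cD_J), ..., coeffs[-1] = (cA_1, cD_1)
    new = []
    for i, (ca, cd) in enumerate(coeffs):
        level = n_levels - i
        d_lo, d_hi = _swt_level_band(trace.fs, level)
        keep_d = (lo < d_hi) and (hi > d_lo)
        keep_a = level == n_levels and lo < trace.fs / 2 ** (n_levels + 1)
        new.append(
            (ca if keep_a else np.zeros_like(ca), cd if keep_d else np.zeros_like(cd))
        )
    rec = pywt.iswt(new, wavelet, norm=True)
    return EKGTrace(np.asarray(rec[:n]), fs=trace.fs, t0=trace.t0)


def detect_r_peaks(
    trace: EKGTrace,
    min_height: float = MIN_HEIGHT_UV,
    min_distance: float = MIN_DISTANCE_S,
) -> RPeakSeries:
    """Constrained local-maximum R-peak detection.

    Local maxima of height >= ``min_height`` are found first; peaks closer
    than ``min_distance`` seconds are then resolved by keeping the larger
    peak (ties: the earlier one). An empty result is returned (with a
    warning) rather than raising.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    idx, _ = signal.find_peaks(trace.samples, height=min_height)
    if idx.size == 0:
        warnings.warn("no R-peaks detected", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs=trace.fs, t0=trace.t0)

    heights = trace.samples[idx]
    min_gap = min_distance * trace.fs
    # priority: larger amplitude first, earlier index on ties
    order = np.lexsort((idx, -heights))
    kept: list[int] = []
    for j in order:
        cand = idx[j]
        if all(abs(cand - k) >= min_gap for k in kept):
            kept.append(cand)
    kept_arr = np.sort(np.asarray(kept, dtype=int))
    return RPeakSeries(kept_arr, fs=trace.fs, t0=trace.t0)


def instantaneous_hr(
    peaks: RPeakSeries,
    fs_out: float = HR_FS,
    t_start: float | None = None,
    t_end: float | None = None,
) -> HRSignal:
    """Piecewise-constant instantaneous heart rate, HR_t = 60 / RR_ij.

    Between R-peaks i and j the rate is 60 divided by their interval in
    seconds. Before the first peak and after the last, the nearest RR value
    is extended so the signal covers the full requested span.
    """
    if peaks.n_peaks < 2:
        raise ValueError("need at least 2 R-peaks to form an RR interval")
    pt = peaks.peak_times
    rr = np.diff(pt)
    if np.any(rr <= 0):
        raise ValueError("non-positive RR interval")
    if t_start is None:
        t_start = peaks.t0
    if t_end is None:
        t_end = pt[-1]
    n = int(np.round((t_end - t_start) * fs_out))
    t = t_start + np.arange(n) / fs_out
    # interval index: samples in [pt[i], pt[i+1]) get rr[i]; edges extended
    which = np.clip(np.searchsorted(pt, t, side="right") - 1, 0, rr.size - 1)
    return HRSignal(60.0 / rr[which], fs=fs_out, t0=t_start)


def resample_hr(
    hr: HRSignal, tr_seconds: float = 2.0, n_volumes: int | None = None
) -> HeartRateSeries:
    """Average instantaneous HR within non-overlapping TR windows.

    Volume v (1-based) covers [(v-1)*TR, v*TR) relative to the HR signal
    start. Windows with no samples yield NaN.
    """
    samples_per_vol = tr_seconds * hr.fs
    if hr.bpm.size < 1:
        raise ValueError("empty HR signal")
    if n_volumes is None:
        n_volumes = int(np.floor(hr.bpm.size / samples_per_vol))
        if n_volumes == 0:
            raise ValueError("HR signal shorter than one TR window")
    bpm = np.full(n_volumes, np.nan)
    for v in range(n_volumes):
        a = int(np.round(v * samples_per_vol))
        b = int(np.round((v + 1) * samples_per_vol))
        chunk = hr.bpm[a : min(b, hr.bpm.size)]
        if chunk.size:
            bpm[v] = chunk.mean()
    return HeartRateSeries(bpm, tr_seconds=tr_seconds)


def mean_hr_in_state(
    hr: HeartRateSeries,
    labels: np.ndarray,
    state: int,
    period: str = "all",
    injection_volume: int | None = None,
) -> float:
    """Mean bpm over the volumes a substate occupies in a given period.

    ``period`` is ``"pre"``, ``"post"`` or ``"all"``; pre/post require
    ``injection_volume`` (the last pre-injection volume, 1-based). Missing
    (NaN) volumes are excluded; an empty selection raises.
    """
    labels = np.asarray(labels)
    if labels.size != hr.n_volumes:
        raise ValueError("labels and heart-rate series differ in length")
    sel = labels == state
    if period != "all":
        if injection_volume is None:
            raise ValueError("injection_volume required for pre/post periods")
        vol = np.arange(1, labels.size + 1)
        sel &= (vol <= injection_volume) if period == "pre" else (vol > injection_volume)
    vals = hr.bpm[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"state {state} has no (non-missing) volumes in period {period!r}")
    return float(vals.mean())


def process_ekg(
    trace: EKGTrace,
    band: tuple[float, float] = QRS_BAND,
    min_height: float = MIN_HEIGHT_UV,
    min_distance: float = MIN_DISTANCE_S,
    tr_seconds: float = 2.0,
    n_volumes: int | None = None,
) -> tuple[HeartRateSeries, RPeakSeries]:
    """Full chain: decimate -> rectify -> wavelet enhance -> detect ->
    instantaneous HR -> TR-grid heart rate."""
    dec = decimate_trace(trace, HR_FS)
    enh = wavelet_enhance(rectify_trace(dec), band=band)
    peaks = detect_r_peaks(enh, min_height=min_height, min_distance=min_distance)
    hr = instantaneous_hr(peaks, fs_out=HR_FS, t_start=dec.t0, t_end=dec.t0 + dec.duration)
    return resample_hr(hr, tr_seconds=tr_seconds, n_volumes=n_volumes), peaks


# ---------------------------------------------------------------------------
# I/O helpers

def read_ekg_csv(path, fs: float | None = None) -> EKGTrace:
    """Read a trace from CSV with columns (time_s, voltage_uV) or a single
    voltage_uV column plus an explicit ``fs``."""
    df = pd.read_csv(path)
    if "voltage_uV" not in df.columns:
        raise ValueError("EKG CSV needs a 'voltage_uV' column")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError("need at least two samples")
        fs_est = 1.0 / np.median(np.diff(t))
        return EKGTrace(df["voltage_uV"].to_numpy(float), fs=fs_est, t0=float(t[0]))
    if fs is None:
        raise ValueError("fs must be given when the CSV has no time_s column")
    return EKGTrace(df["voltage_uV"].to_numpy(float), fs=fs)


def write_hr_csv(hr: HeartRateSeries, path) -> None:
    pd.DataFrame(
        {"volume_index": hr.volume_alignment, "bpm": hr.bpm}
    ).to_csv(path, index=False)


def hr_qc_report(hr: HeartRateSeries, peaks: RPeakSeries, path=None) -> dict:
    report = {
        "n_peaks": int(peaks.n_peaks),
        "n_volumes": int(hr.n_volumes),
        "pct_windows_missing": float(100.0 * np.mean(~np.isfinite(hr.bpm))),
        "mean_bpm": float(np.nanmean(hr.bpm)) if np.isfinite(hr.bpm).any() else None,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
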