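"""Brain/heart-behavior association statistics.

Links substate-related brain and heart-rate changes to subjective-experience
change scores: per-item paired t-tests with BH-FDR over the 25 VAS items,
two-component partial least squares regression (SIMPLS), Pearson
correlations reported with their degrees of freedom, a median split of
participants, and order-of-dosing regressions.

The PLS follows the SIMPLS algorithm (de Jong 1993): X and Y are column
centered (no variance scaling); each component's weight vector is the
dominant left singular vector of the running cross-product matrix
S = X0' Y0, which is then deflated by the orthonormalized X-loading basis.
Components are sign-fixed so that the largest-|loading| X entry is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activation_maps import fdr_bh

__all__ = [
    "VASChange",
    "PLSModel",
    "vas_change_and_tests",
    "pls2",
    "pearson_with_df",
    "median_split",
    "order_effect_regression",
    "paired_ttest",
]


@dataclass
class VASChange:
    """Per-item drug-minus-placebo change scores and paired tests."""

    change: pd.DataFrame  # participants x items, in [-1, 1]
    t: pd.Series
    p: pd.Series
    q: pd.Series
    rejected: pd.Series
    alpha: float


@dataclass
class PLSModel:
    """Two-component (by default) SIMPLS partial least squares regression."""

    n_components: int
    x_weights: np.ndarray  # p x A
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # q x A
    x_scores: np.ndarray  # n x A
    y_scores: np.ndarray  # n x A
    score_r: np.ndarray  # per-component Pearson r between y- and x-scores
    score_p: np.ndarray
    x_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict Y from X using the first ``n_components`` components."""
        A = self.n_components if n_components is None else n_components
        X0 = np.asarray(X, dtype=float) - self.x_mean
        # regression coefficients from weights/loadings of the first A comps
        B = self.x_weights[:, :A] @ self.y_loadings[:, :A].T
        return X0 @ B + self.y_mean


def vas_change_and_tests(
    vas_dmt: pd.DataFrame, vas_pcb: pd.DataFrame, alpha: float = 0.05
) -> VASChange:
    """Item-wise paired t-tests of VAS ratings, BH-FDR across items."""
    missing = set(vas_dmt.columns) ^ set(vas_pcb.columns)
    if missing:
        raise ValueError(f"items missing in one condition: {sorted(missing)}")
    if not vas_dmt.index.equals(vas_pcb.index):
        raise ValueError("participant sets differ across conditions")
    pcb = vas_pcb[vas_dmt.columns]
    change = vas_dmt - pcb
    n = len(change)
    t_vals, p_vals = [], []
    for item in change.columns:
        d = change[item].to_numpy(float)
        if d.std(ddof=1) == 0:
            t_vals.append(0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf)
            p_vals.append(1.0 if d.mean() == 0 else 0.0)
        else:
            t, p = stats.ttest_rel(vas_dmt[item], pcb[item])
            t_vals.append(float(t))
            p_vals.append(float(p))
    q, reject = fdr_bh(np.asarray(p_vals), alpha)
    items = change.columns
    return VASChange(
        change=change,
        t=pd.Series(t_vals, index=items),
        p=pd.Series(p_vals, index=items),
        q=pd.Series(q, index=items),
        rejected=pd.Series(reject, index=items),
        alpha=alpha,
        )


def pls2(Y: np.ndarray, X: np.ndarray, n_components: int = 2) -> PLSModel:
    """SIMPLS partial least squares regression of Y on X.

    ``X`` is n × p (predictors, e.g. the 25 VAS change scores), ``Y`` is
    n × q or a length-n vector (outcomes, e.g. regional activity or heart
    rate change). Returns loadings, scores and the per-component Pearson
    correlation (with p-value) between dependent and independent scores.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y disagree on the number of participants")
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("constant outcome column")
    A = n_components
    if A > min(n - 1, p):
        raise ValueError(f"n_components={A} exceeds the rank bound min(n-1, p)")

    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - x_mean, Y - y_mean
    S = X0.T @ Y0

    R = np.zeros((p, A))  # weights
    P = np.zeros((p, A))  # x-loadings
    Q = np.zeros((Y.shape[1], A))  # y-loadings
    T = np.zeros((n, A))  # x-scores
    U = np.zeros((n, A))  # y-scores
    V = np.zeros((p, A))  # orthonormal deflation basis

    for a in range(A):
        if Y.shape[1] == 1:
            r = S[:, 0].copy()
        else:
            uu, _, _ = np.linalg.svd(S, full_matrices=False)
            r = uu[:, 0]
        t = X0 @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt < 1e-12:
            raise ValueError(f"component {a + 1} has degenerate scores")
        t /= normt
        r /= normt
        p_load = X0.T @ t
        q_load = Y0.T @ t
        u = Y0 @ q_load
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
            u -= T[:, :a] @ (T[:, :a].T @ u)
        v /= np.linalg.norm(v)
        S = S - v[:, None] @ (v[None, :] @ S)

        # deterministic sign: largest-|x-loading| entry positive
        sign = np.sign(p_load[np.argmax(np.abs(p_load))]) or 1.0
        R[:, a], P[:, a], Q[:, a] = sign * r, sign * p_load, sign * q_load
        T[:, a], U[:, a] = sign * t, sign * u
        V[:, a] = v

    score_r = np.empty(A)
    score_p = np.empty(A)
    for a in range(A):
        score_r[a], _, score_p[a] = pearson_with_df(T[:, a], U[:, a])
    return PLSModel(
        n_components=A,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        y_scores=U,
        score_r=score_r,
        score_p=score_p,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def pearson_with_df(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pearson correlation reported as (r, df, p) with df = n - 2.

    The two-sided p-value comes from the t transform t = r sqrt(df/(1-r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return r, df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


def median_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split participants at the sample median of ``values``.

    Returns (low indices, high indices); values equal to the median go to
    the low group, so with even n and distinct values the groups are
    equal-sized.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participants")
    med = np.median(values)
    high = np.flatnonzero(values > med)
    low = np.flatnonzero(values <= med)
    return low, high


def order_effect_regression(
    outcome: np.ndarray, dosing_order: np.ndarray
) -> tuple[float, float]:
    """OLS of an outcome on the binary order-of-dosing indicator.

    ``dosing_order`` is 1 for participants dosed with the drug at the first
    visit, 0 otherwise. Returns (slope, two-sided p for the slope).
    """
    outcome = np.asarray(outcome, dtype=float)
    order = np.asarray(dosing_order, dtype=float)
    if set(np.unique(order)) != {0.0, 1.0}:
        raise ValueError("both dosing orders must be present")
    res = stats.linregress(order, outcome)
    return float(res.slope), float(res.pvalue)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired t-test, returned as (t, df = n-1, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)
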