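"""Shared statistical kernels.

Vectorized two-sample / paired t statistics and the Pearson correlation
kernel used by both the cross-study concordance and the regulator-correlation
analyses (the two must agree exactly, so they share this code path).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t_rows",
    "paired_t_rows",
    "pearson_r_p",
    "pearson_rows_r_p",
    "bh_qvalues",
]


def welch_t_rows(x_case: np.ndarray, x_ctrl: np.ndarray):
    """Row-wise Welch t test (case − control orientation).

    Parameters
    ----------
    x_case, x_ctrl : 2-D arrays, rows = features, columns = samples.

    Returns
    -------
    (t, df, p) arrays. Rows where both groups have zero variance get
    t = 0, p = 1 (df set to n1 + n2 − 2 by convention).
    """
    x_case = np.atleast_2d(np.asarray(x_case, dtype=float))
    x_ctrl = np.atleast_2d(np.asarray(x_ctrl, dtype=float))
    n1, n2 = x_case.shape[1], x_ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")
    m1 = x_case.mean(axis=1)
    m2 = x_ctrl.mean(axis=1)
    v1 = x_case.var(axis=1, ddof=1)
    v2 = x_ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 <= 0.0
    se2_safe = np.where(degenerate, 1.0, se2)
    t = (m1 - m2) / np.sqrt(se2_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2_safe**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, df, p


def paired_t_rows(diffs: np.ndarray):
    """Row-wise one-sample t on paired differences (late − early).

    Rows with zero-variance differences get t = 0, p = 1 per the
    degenerate-input contract.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[1]
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs (got {n})")
    m = diffs.mean(axis=1)
    v = diffs.var(axis=1, ddof=1)
    degenerate = v <= 0.0
    se = np.sqrt(np.where(degenerate, 1.0, v) / n)
    t = np.where(degenerate, 0.0, m / se)
    df = float(n - 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, np.full_like(t, df), p


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r via the exact t transform, df = n − 2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and its analytic two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 observations for a correlation (got {n})")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(_r_to_p(np.array(r), n))


def pearson_rows_r_p(X: np.ndarray, y: np.ndarray):
    """Pearson correlation of each row of ``X`` with the vector ``y``.

    Uses the same estimator and p-value transform as :func:`pearson_r_p`,
    vectorized. Zero-variance rows yield r = nan, p = nan.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError(f"need >= 3 observations for a correlation (got {n})")
    if np.std(y) == 0.0:
        raise ValueError("zero-variance reference vector: correlation undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.where(sx == 0.0, np.nan, np.clip(r, -1.0, 1.0))
    p = np.where(np.isnan(r), np.nan, _r_to_p(r, n))
    return r, p


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
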