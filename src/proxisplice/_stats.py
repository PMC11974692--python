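"""Shared statistical primitives: downshifted-normal imputation and the
pooled two-sample t machinery used by both the intron-retention and the
proteomics enrichment engines."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["impute_downshifted_normal", "pooled_t", "two_sample_t_test"]


def impute_downshifted_normal(
    values: np.ndarray,
    downshift: float = 1.8,
    width: float = 0.3,
    rng: np.random.Generator | None = None,
    min_finite: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise imputation of non-finite entries from a downshifted normal.

    For each column, the mean ``m`` and SD ``s`` of the finite entries are
    estimated and every non-finite entry is replaced by an independent draw
    from ``Normal(m - downshift*s, (width*s)^2)`` — the proteomics
    left-censoring convention that treats missing values as below the
    detection limit.

    Returns ``(imputed, flags)`` where ``flags`` is True exactly where a
    value was imputed.  Raises ``ValueError`` if a column has fewer than
    ``min_finite`` finite entries (the moments would be meaningless).
    """
    if rng is None:
        rng = np.random.default_rng()
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    mat = values[:, None].copy() if squeeze else values.copy()
    flags = ~np.isfinite(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        finite = np.isfinite(col)
        if not flags[:, j].any():
            continue
        if finite.sum() < min_finite:
            raise ValueError(
                f"column {j}: only {int(finite.sum())} finite values "
                f"(< {min_finite}); widen the prefilter before imputing"
            )
        m = col[finite].mean()
        s = col[finite].std(ddof=1)
        n_miss = int(flags[:, j].sum())
        col[flags[:, j]] = rng.normal(m - downshift * s, width * s, size=n_miss)
    if squeeze:
        return mat[:, 0], flags[:, 0]
    return mat, flags


def pooled_t(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t pieces: (mean difference, pooled SE, df)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return g1.mean() - g2.mean(), float(se), float(df)


def two_sample_t_test(
    g1: np.ndarray, g2: np.ndarray, equal_var: bool = True
) -> float:
    """Two-tailed two-sample t-test p-value with degenerate-variance rules.

    Zero within-group variance in both groups: p = 1 if the means are
    equal (no evidence either way, by convention) else p = 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        return 1.0 if g1.mean() == g2.mean() else 0.0
    res = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(res.pvalue)
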