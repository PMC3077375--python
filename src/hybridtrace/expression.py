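"""Expression-matrix statistics: quantile normalization, fold changes, PMCC."""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) to a common distribution.

    Every sample's sorted values are replaced by the across-sample means
    of the sorted columns; ties within a sample receive the average of
    the target values at their tied ranks. All output columns share an
    identical value distribution, and the operation is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains non-numeric or missing entries")
    target = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def pmcc(x, y) -> float:
    """Pearson product-moment correlation via standard scores.

    r = sum(z_x * z_y) / (n - 1) with sample standard deviations, which
    equals cov(x, y) / (sd_x * sd_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance profile")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    return float(np.sum(zx * zy) / (n - 1))


def pairwise_pmcc(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise PMCCs between sample columns."""
    cols = list(matrix.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = pmcc(matrix[a].to_numpy(), matrix[b].to_numpy())
            out.loc[a, b] = out.loc[b, a] = r
    return out


def log2_fold_change(
    expr_a: Union[pd.Series, np.ndarray],
    expr_b: Union[pd.Series, np.ndarray],
    pseudocount: float = 1.0,
) -> Union[pd.Series, np.ndarray]:
    """Per-gene log2((a + c) / (b + c)) on linear-scale inputs.

    Antisymmetric under swapping a and b; the pseudocount floors genes
    with zero expression.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("linear expression values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    lfc = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    if isinstance(expr_a, pd.Series):
        return pd.Series(lfc, index=expr_a.index)
    return lfc
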