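"""Vectorised rank-correlation kernels shared by the screening and window modules.

Everything here computes Spearman coefficients as the Pearson correlation of
average ranks (ties receive the mean of the ranks they span), which is the
definition used throughout the package.  Degenerate inputs (constant vectors)
yield NaN rather than 0 so callers can distinguish "undefined" from
"uncorrelated".
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def rowwise_rank_corr(x_rows: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Spearman coefficient of each row pair of two equally shaped 2-D arrays.

    Parameters
    ----------
    x_rows, y_rows : ndarray of shape (m, w)
        ``m`` paired observation vectors of length ``w``.

    Returns
    -------
    ndarray of shape (m,)
        Row-wise Spearman coefficients in [-1, 1]; NaN where either row is
        constant (zero rank variance).
    """
    x_rows = np.asarray(x_rows, dtype=float)
    y_rows = np.asarray(y_rows, dtype=float)
    if x_rows.shape != y_rows.shape or x_rows.ndim != 2:
        raise ValueError("x_rows and y_rows must be 2-D arrays of equal shape")
    rx = rankdata(x_rows, axis=1, method="average")
    ry = rankdata(y_rows, axis=1, method="average")
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    sx = np.einsum("ij,ij->i", rx, rx)
    sy = np.einsum("ij,ij->i", ry, ry)
    num = np.einsum("ij,ij->i", rx, ry)
    den = np.sqrt(sx * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / den, np.nan)
    return np.clip(out, -1.0, 1.0, out=out)


def normalized_ranks(values: np.ndarray) -> np.ndarray:
    """Centre and unit-normalise the per-row average ranks of a matrix.

    The dot product of two normalised rank rows is their Spearman
    coefficient, which makes whole-pool pair screening a gather + einsum.
    Constant rows come back as all-NaN so downstream dot products propagate
    the undefinedness.
    """
    values = np.asarray(values, dtype=float)
    r = rankdata(values, axis=1, method="average")
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.einsum("ij,ij->i", r, r))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(norm[:, None] > 0.0, r / norm[:, None], np.nan)
    return r
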