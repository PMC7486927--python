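"""Mutual-information ranking of observed variables against a target.

When many observed variables carry little information about the target,
restricting the reservoir input to the D most informative ones improves the
signal-to-noise of the readout fit.  Relevance is scored with a plug-in
mutual-information estimate from a 2-D equal-width histogram: deterministic,
symmetric, and adequate for ranking.  Selection is optional in the pipeline.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import SelectionError


def default_bins(m: int) -> int:
    """Histogram bins per axis: ceil(sqrt(m / 5)), at least 2."""
    return max(2, math.ceil(math.sqrt(m / 5)))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Plug-in MI estimate (nats) between two series under equal-width binning.

    Nonnegative and symmetric in its arguments; invariant to any common
    reordering of the samples.  A constant input has a degenerate marginal:
    the estimate is 0 and a warning is emitted.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise SelectionError("x and y must have equal length")
    m = x.shape[0]
    if m < 8:
        raise SelectionError("need at least 8 samples for the histogram estimate")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if n_bins is None:
        n_bins = default_bins(m)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: mutual information set to 0")
        return 0.0
    counts, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = counts / m
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def mi_ranking(X: np.ndarray, target_row: int, n_bins: int | None = None) -> list[tuple[int, float]]:
    """All rows of X ranked by MI with the target row, descending.

    Ties are broken in favour of the target row itself, then by ascending
    row index, giving a single deterministic total order (so the top-D set
    is monotone in D and always contains the target: under a common binning
    no row can exceed the target's self-information).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (0 <= target_row < n):
        raise SelectionError("target_row out of range")
    y = X[target_row]
    scores = [mutual_information(X[i], y, n_bins=n_bins) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-scores[i], i != target_row, i))
    return [(i, scores[i]) for i in order]


def select_variables(
    X: np.ndarray, target_row: int, D: int, n_bins: int | None = None
) -> list[int]:
    """Indices of the D variables most informative about the target.

    Returned in descending MI order; the target row is always included.
    """
    n = X.shape[0]
    if not (1 <= D <= n):
        raise SelectionError(f"D must be in [1, {n}], got {D}")
    return [i for i, _ in mi_ranking(X, target_row, n_bins=n_bins)[:D]]
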