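"""Delay-coordinate (Hankel) structure of the target variable.

The delay map sends the scalar series ``y^1 ... y^{m+L-1}`` to the L x m
matrix whose column t is the delay vector ``(y^t, ..., y^{t+L-1})``.  The
lower-right anti-diagonal triangle of that matrix holds the L-1 future values
the solver estimates.  The matrix is exposed as a strided *view* of the
underlying series, so every cell sharing a future value is one and the same
number by construction and cannot drift during solver updates.

Indexing note: the scientific description above is 1-based (y^t); all arrays
in code are 0-based, so series position ``m + j`` (j = 0..L-2) holds the
(j+1)-step-ahead future value.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DimensionError


class DelayHankel:
    """L x m delay matrix of a target series with an unknown future tail.

    Attributes
    ----------
    series : ndarray, shape (m + L - 1,)
        Backing storage; the first m entries are observed, the trailing
        L - 1 entries are the future values (0.0 until filled).
    known_mask : ndarray of bool, shape (m + L - 1,)
        True where the entry is known/filled.
    """

    def __init__(self, series: np.ndarray, L: int, m: int, known_mask: np.ndarray):
        self.series = np.asarray(series, dtype=float)
        self.L = int(L)
        self.m = int(m)
        self.known_mask = np.asarray(known_mask, dtype=bool)
        if self.series.shape != (self.m + self.L - 1,):
            raise DimensionError("series must have length m + L - 1")
        if self.known_mask.shape != self.series.shape:
            raise DimensionError("known_mask must match series length")

    @property
    def matrix(self) -> np.ndarray:
        """The L x m Hankel matrix as a read-through view of ``series``."""
        return sliding_window_view(self.series, self.L).T

    @property
    def n_unknown(self) -> int:
        return int((~self.known_mask).sum())

    def unknown_cells(self) -> int:
        """Number of matrix cells (i, t) that read an unknown series entry."""
        mat_idx = np.add.outer(np.arange(self.L), np.arange(self.m))
        return int((~self.known_mask[mat_idx]).sum())

    def fill(self, tail: np.ndarray) -> "DelayHankel":
        """Set the L - 1 future values (last write wins) and return self."""
        tail = np.asarray(tail, dtype=float)
        if tail.shape != (self.L - 1,):
            raise DimensionError(f"tail must have length L - 1 = {self.L - 1}")
        if not np.all(np.isfinite(tail)):
            raise ValueError("tail must be finite")
        self.series[self.m:] = tail
        self.known_mask[self.m:] = True
        return self

    def extract_tail(self) -> np.ndarray:
        return self.series[self.m:].copy()

    def copy(self) -> "DelayHankel":
        return DelayHankel(self.series.copy(), self.L, self.m, self.known_mask.copy())


def build_hankel(y_known: np.ndarray, L: int) -> DelayHankel:
    """Embed the observed series in L delay coordinates with an open tail.

    Requires ``2 <= L <= m``.  The returned structure has exactly L - 1
    trailing unknown positions, which appear in L(L-1)/2 cells of the matrix.
    """
    y_known = np.asarray(y_known, dtype=float)
    if y_known.ndim != 1:
        raise DimensionError("y_known must be a vector")
    m = y_known.shape[0]
    if L < 2:
        raise DimensionError("L must be >= 2 (L - 1 >= 1 steps to predict)")
    if L > m:
        raise DimensionError(f"embedding dimension L={L} exceeds series length m={m}")
    if not np.all(np.isfinite(y_known)):
        raise ValueError("y_known must be finite")
    series = np.concatenate([y_known, np.zeros(L - 1)])
    mask = np.concatenate([np.ones(m, dtype=bool), np.zeros(L - 1, dtype=bool)])
    return DelayHankel(series, L, m, mask)


def fill_unknowns(h: DelayHankel, tail: np.ndarray) -> DelayHankel:
    """Functional wrapper around :meth:`DelayHankel.fill`."""
    return h.fill(tail)
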