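"""Joint estimation of the readout matrices and the future tail.

The primary/conjugate information-transformation equations

    A F(X^t) = Y^t        (encode: spatial features -> delay vector)
    F(X^t)   = B Y^t      (decode: delay vector -> spatial features)

with the consistency constraint AB = I are fitted simultaneously for the
readout pair (A, B) *and* the L - 1 unknown future values of the target that
sit in the lower-right tail of the delay matrix Y.  The fitted functional is
penalized least squares,

    J(A, B, tail) = w_p sum_t ||A FX_t - Y_t||^2
                  + w_c sum_t ||FX_t - B Y_t||^2
                  + gamma ||AB - I||_F^2
                  + lambda (||A||_F^2 + ||B||_F^2),

minimized by block-coordinate descent.  Each block has an exact closed-form
minimizer: A solves a ridge system, B a Sylvester equation (the AB-penalty
couples it to A), and the tail a small (L-1)-dimensional least-squares
problem collecting every Hankel cell in which a future value appears.  With
dropout disabled every step is an exact block minimization, so the objective
is provably non-increasing.

Dropout regularizes the readout fits: each outer iteration a random fraction
of reservoir features (rows of FX) is zeroed during the A/B fits only;
the tail update and all reported quantities use the full features scaled by
(1 - dropout_rate), the usual inverted-dropout convention.

Two fitting scopes are available per readout block.  Fitting a block on
"all" m columns lets the current tail estimates participate in the fit (the
semi-supervised coupling: training and predicting happen together), and with
both blocks on "all" and dropout off the procedure is exact block-coordinate
descent on J, so the objective is provably non-increasing.  Fitting a block
on the "complete" columns only (the m - L + 1 delay vectors made entirely of
observations) anchors it to data the solver cannot influence.  The default -
encoder A on all columns, decoder B on complete columns - keeps the
semi-supervised coupling where it helps while preventing the decoder, whose
back-projection drives the tail estimate, from confirming its own guesses;
in that configuration the iteration is a fixed-point scheme rather than
descent on a single functional.

The linearized variant (F = identity) is the same code path with FX = X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DimensionError, SolvabilityError
from .hankel import DelayHankel, build_hankel

__all__ = [
    "SolverOptions",
    "SolverDiagnostics",
    "STISolution",
    "solve_arnn",
    "solve_linear_sti",
    "update_readout",
    "update_tail",
    "sti_objective",
]


@dataclass(frozen=True)
class SolverOptions:
    """Tunables of the block-coordinate solver.

    tol is the relative l2-change of the predicted tail below which the
    iteration stops; ridge is the Tikhonov weight lambda on A and B;
    consistency_weight is gamma, the soft AB = I penalty; dropout_rate is
    the per-iteration fraction of reservoir features masked during the
    readout fits.  primary_weight / conjugate_weight rescale the two
    residual blocks (equal by default; set one to 0 for an ablation).

    tail_smoothing is the weight mu of a second-difference penalty
    mu * sum_k (s[k-1] - 2 s[k] + s[k+1])^2 over the predicted tail (the
    window starts at the last observed value, so a noisy junction slope is
    not extrapolated) - a smoothness prior for densely sampled continuous
    dynamics, where true second differences are O(dt^2) and therefore
    essentially free, while oscillatory blow-ups of the weakly-constrained
    far tail are heavily penalized.  Set it to 0 for coarsely sampled or
    discontinuous series.  The term does not involve A or B, so exact
    block-coordinate descent is preserved.
    """

    max_iter: int = 60
    tol: float = 1e-4
    ridge: float = 1e-4
    dropout_rate: float = 0.05
    consistency_weight: float = 1.0
    init_strategy: str = "hold_last"  # hold_last | linear_extrapolate | zero
    seed: int = 0
    primary_weight: float = 1.0
    conjugate_weight: float = 1.0
    a_fit_columns: str = "all"  # all | complete
    b_fit_columns: str = "complete"  # all | complete
    tail_smoothing: float = 100.0

    def __post_init__(self):
        if self.a_fit_columns not in ("all", "complete") or self.b_fit_columns not in (
            "all",
            "complete",
        ):
            raise ValueError("fit column scopes must be 'all' or 'complete'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.ridge < 0 or self.consistency_weight < 0:
            raise ValueError("ridge and consistency_weight must be >= 0")
        if self.tail_smoothing < 0:
            raise ValueError("tail_smoothing must be >= 0")
        if self.init_strategy not in ("hold_last", "linear_extrapolate", "zero"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class SolverDiagnostics:
    objective: list[float] = field(default_factory=list)
    ab_identity_gap: float = float("nan")
    iterations: int = 0
    converged: bool = False


@dataclass
class STISolution:
    """Result of a solve: readout pair, completed series and diagnostics."""

    A: np.ndarray
    B: np.ndarray
    completed_series: np.ndarray
    forecast: np.ndarray
    diagnostics: SolverDiagnostics


def _init_tail(y_known: np.ndarray, L: int, strategy: str) -> np.ndarray:
    if strategy == "zero":
        return np.zeros(L - 1)
    if strategy == "hold_last":
        return np.full(L - 1, y_known[-1])
    # linear extrapolation from the last two observed points
    slope = y_known[-1] - y_known[-2] if y_known.shape[0] >= 2 else 0.0
    return y_known[-1] + slope * np.arange(1, L)


def update_readout(
    FX: np.ndarray,
    Y: np.ndarray,
    ridge: float,
    consistency_weight: float,
    dropout_mask: np.ndarray | None = None,
    B_prev: np.ndarray | None = None,
    primary_weight: float = 1.0,
    conjugate_weight: float = 1.0,
    a_columns: slice | np.ndarray | None = None,
    b_columns: slice | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge updates of the readout pair (A, B) given the delay matrix Y.

    A solves  A (w_p FX FX' + gamma B B' + lambda I) = w_p Y FX' + gamma B'
    (a ridge system; B is the previous iterate, or 0 when absent), then B
    solves the Sylvester equation
    gamma A'A B + B (w_c Y Y' + lambda I) = w_c FX Y' + gamma A'.
    When each block uses all columns these are the exact per-block minimizers
    of J; ``a_columns`` / ``b_columns`` restrict a block's fit to a subset of
    time columns (e.g. the fully-observed ones).

    ``dropout_mask`` (boolean over features) zeroes the dropped rows of FX
    for both fits; a masked feature's column of A / row of B then has no
    effect on the fitted residuals.
    """
    FX = np.asarray(FX, dtype=float)
    Y = np.asarray(Y, dtype=float)
    d_feat, m = FX.shape
    L = Y.shape[0]
    if Y.shape[1] != m:
        raise DimensionError("FX and Y must share the time dimension")
    if dropout_mask is not None:
        FX = FX * np.asarray(dropout_mask, dtype=float)[:, None]
    w_p, w_c, lam, gam = primary_weight, conjugate_weight, ridge, consistency_weight
    B0 = np.zeros((d_feat, L)) if B_prev is None else B_prev
    FXa = FX if a_columns is None else FX[:, a_columns]
    Ya = Y if a_columns is None else Y[:, a_columns]
    FXb = FX if b_columns is None else FX[:, b_columns]
    Yb = Y if b_columns is None else Y[:, b_columns]

    # --- A step (ridge, closed form) ---
    lhs = w_p * (FXa @ FXa.T) + gam * (B0 @ B0.T) + lam * np.eye(d_feat)
    rhs = w_p * (Ya @ FXa.T) + gam * B0.T
    if lam == 0 and np.linalg.matrix_rank(lhs) < d_feat:
        raise np.linalg.LinAlgError(
            "singular normal equations; retry with ridge > 0"
        )
    try:
        A = np.linalg.solve(lhs, rhs.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular normal equations; retry with ridge > 0"
        ) from exc

    # --- B step (Sylvester when the AB penalty couples, ridge otherwise) ---
    rhs_b = w_c * (FXb @ Yb.T) + gam * A.T
    lhs_b = w_c * (Yb @ Yb.T) + lam * np.eye(L)
    if gam > 0:
        B = scipy.linalg.solve_sylvester(gam * (A.T @ A), lhs_b, rhs_b)
    else:
        try:
            B = np.linalg.solve(lhs_b.T, rhs_b.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal equations; retry with ridge > 0"
            ) from exc
    return A, B


def update_tail(
    FX: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    hankel: DelayHankel,
    primary_weight: float = 1.0,
    conjugate_weight: float = 1.0,
    tail_smoothing: float = 0.0,
) -> np.ndarray:
    """Jointly optimal future values given fixed (A, B).

    Every unknown appears in several primary residual rows and conjugate
    residual columns of the delay matrix; stacking all of them (plus the
    optional second-difference smoothness rows across the observed/predicted
    junction) gives one small linear least-squares problem in the L - 1
    unknowns, solved exactly.  A tail that is already optimal is a fixed
    point of this update.
    """
    L, m = hankel.L, hankel.m
    w_p, w_c = np.sqrt(primary_weight), np.sqrt(conjugate_weight)
    w_s = np.sqrt(tail_smoothing)
    t0 = m - L + 1  # first (0-based) column whose delay vector reaches the tail
    cols = slice(t0, m)
    FXc = FX[:, cols]
    P = A @ FXc  # primary predictions for the affected columns

    series = hankel.series.copy()

    def residual(tail: np.ndarray) -> np.ndarray:
        series[m:] = tail
        Yc = np.lib.stride_tricks.sliding_window_view(series, L).T[:, cols]
        r1 = w_p * (P - Yc)
        r2 = w_c * (FXc - B @ Yc)
        parts = [r1.ravel(), r2.ravel()]
        if w_s > 0 and L >= 3:
            # roughness of the tail itself; touches only the last observed
            # value, so a noisy junction slope is not extrapolated
            parts.append(w_s * np.diff(series[m - 1 :], n=2))
        return np.concatenate(parts)

    r0 = residual(np.zeros(L - 1))
    C = np.empty((r0.shape[0], L - 1))
    eye = np.eye(L - 1)
    for j in range(L - 1):
        C[:, j] = residual(eye[j]) - r0
    tail, *_ = np.linalg.lstsq(C, -r0, rcond=None)
    return tail


def sti_objective(
    FX: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    options: SolverOptions,
) -> float:
    """Evaluate the penalized least-squares objective J."""
    L = Y.shape[0]
    j = options.primary_weight * float(np.sum((A @ FX - Y) ** 2))
    j += options.conjugate_weight * float(np.sum((FX - B @ Y) ** 2))
    j += options.consistency_weight * float(np.sum((A @ B - np.eye(L)) ** 2))
    j += options.ridge * (float(np.sum(A**2)) + float(np.sum(B**2)))
    if options.tail_smoothing > 0 and L >= 3:
        # Y row 0 is the series at positions 0..m-1; row L-1 ends the tail
        series = np.concatenate([Y[0], Y[1:, -1]])
        m = Y.shape[1]
        j += options.tail_smoothing * float(
            np.sum(np.diff(series[m - 1 :], n=2) ** 2)
        )
    return j


def _solve_core(FX: np.ndarray, y_known: np.ndarray, L: int, options: SolverOptions) -> STISolution:
    FX = np.asarray(FX, dtype=float)
    y_known = np.asarray(y_known, dtype=float).ravel()
    d_feat, m = FX.shape
    if d_feat <= L:
        raise SolvabilityError(
            f"feature dimension {d_feat} must exceed embedding dimension L={L}"
        )
    if y_known.shape[0] != m:
        raise DimensionError("y_known length must match FX columns")
    if not (np.all(np.isfinite(FX)) and np.all(np.isfinite(y_known))):
        raise ValueError("inputs must be finite")

    h = build_hankel(y_known, L)
    tail = _init_tail(y_known, L, options.init_strategy)
    h.fill(tail)

    p = options.dropout_rate
    keep = 1.0 - p
    FX_pred = FX * keep if p > 0 else FX
    rng = np.random.default_rng(options.seed)

    n_complete = m - L + 1  # columns whose delay vector is fully observed
    a_cols = None if options.a_fit_columns == "all" else slice(0, n_complete)
    b_cols = None if options.b_fit_columns == "all" else slice(0, n_complete)

    diag = SolverDiagnostics()
    best = None  # (objective, A, B, tail)
    A = B = None
    converged = False
    for it in range(options.max_iter):
        if p > 0:
            mask = rng.random(d_feat) >= p
            while not mask.any():  # never fit on an empty feature set
                mask = rng.random(d_feat) >= p
        else:
            mask = None
        A, B = update_readout(
            FX,
            h.matrix,
            ridge=options.ridge,
            consistency_weight=options.consistency_weight,
            dropout_mask=mask,
            B_prev=B,
            primary_weight=options.primary_weight,
            conjugate_weight=options.conjugate_weight,
            a_columns=a_cols,
            b_columns=b_cols,
        )
        new_tail = update_tail(
            FX_pred, A, B, h,
            primary_weight=options.primary_weight,
            conjugate_weight=options.conjugate_weight,
            tail_smoothing=options.tail_smoothing,
        )
        rel_change = np.linalg.norm(new_tail - tail) / max(np.linalg.norm(tail), 1e-12)
        tail = new_tail
        h.fill(tail)
        obj = sti_objective(FX_pred, A, B, h.matrix, options)
        diag.objective.append(obj)
        if best is None or obj < best[0]:
            best = (obj, A.copy(), B.copy(), tail.copy())
        if rel_change < options.tol:
            converged = True
            break

    diag.iterations = len(diag.objective)
    diag.converged = converged
    if not converged and best is not None:
        # return the best iterate seen (relevant when dropout jitters the fits)
        _, A, B, tail = best
        h.fill(tail)
    diag.ab_identity_gap = float(np.linalg.norm(A @ B - np.eye(L)))
    series = h.series.copy()
    return STISolution(
        A=A, B=B, completed_series=series, forecast=series[h.m:].copy(), diagnostics=diag
    )


def solve_arnn(FX: np.ndarray, y_known: np.ndarray, L: int, options: SolverOptions | None = None) -> STISolution:
    """Solve the conjugated equations over reservoir features FX (D~ x m)."""
    return _solve_core(FX, y_known, L, options or SolverOptions())


def solve_linear_sti(X: np.ndarray, y_known: np.ndarray, L: int, options: SolverOptions | None = None) -> STISolution:
    """Linearized baseline: the identical algorithm with F = identity.

    Shares the exact code path with :func:`solve_arnn`, so an identity
    reservoir and this function agree bit for bit under equal options.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= L:
        raise SolvabilityError(
            f"need more variables than the embedding dimension (D={X.shape[0]}, L={L})"
        )
    return _solve_core(X, y_known, L, options or SolverOptions())
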