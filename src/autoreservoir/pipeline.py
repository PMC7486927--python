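"""End-to-end multistep-ahead prediction of one target variable.

One call assembles the stages: z-score each variable over the known window,
optionally keep only the variables most informative about the target
(mutual-information ranking), push the snapshots through the fixed random
tanh reservoir, solve the conjugated primary/conjugate equations for the
readout and the future tail, and map the tail back to the target's original
units.  All randomness (reservoir weights, dropout masks) derives from one
master seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DimensionError
from .reservoir import ReservoirNet, default_widths, init_reservoir
from .selection import select_variables
from .solver import SolverOptions, STISolution, _solve_core

_STD_FLOOR = 1e-12


def _subseed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PredictConfig:
    """Configuration of one prediction.

    target_index selects the row of X to forecast; horizon is the number of
    future steps (the embedding dimension is L = horizon + 1).  keep_d
    switches on mutual-information variable selection when set (the target
    row is always retained).  reservoir is "auto" (default four-layer tanh
    net sized from the data), "identity" (bypass F: the linearized
    baseline), or a prebuilt :class:`ReservoirNet`.
    """

    target_index: int
    horizon: int
    keep_d: int | None = None
    n_bins: int | None = None
    reservoir: str | ReservoirNet = "auto"
    widths: list[int] | None = None
    weight_scale: float | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    sd_safe = np.where(sd < _STD_FLOOR, 1.0, sd)
    return (X - mu[:, None]) / sd_safe[:, None], mu, sd_safe


def predict_target(
    X: np.ndarray, config: PredictConfig
) -> tuple[np.ndarray, STISolution, dict]:
    """Forecast ``horizon`` future values of the target row of X (n x m).

    Returns the forecast in the target's original units, the full solver
    solution (in standardized units when standardize=True), and a
    provenance record of seeds, selected variables and the reservoir spec.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D (variables x time) matrix")
    n, m = X.shape
    if not (0 <= config.target_index < n):
        raise ConfigError("target_index out of range")
    if 2 * config.horizon >= m:
        warnings.warn(
            "horizon is half the known window or more: extrapolating near the "
            "information content of the window"
        )
    L = config.horizon + 1

    ss = np.random.SeedSequence(config.seed)
    ss_reservoir, ss_solver = ss.spawn(2)

    if config.standardize:
        Xs, mu, sd = _standardize_rows(X)
    else:
        Xs, mu, sd = X, np.zeros(n), np.ones(n)

    if config.keep_d is not None:
        selected = select_variables(Xs, config.target_index, config.keep_d, config.n_bins)
    else:
        selected = list(range(n))
    target_pos = selected.index(config.target_index)
    Xsel = Xs[selected]
    D = Xsel.shape[0]

    if isinstance(config.reservoir, ReservoirNet):
        net = config.reservoir
    elif config.reservoir == "identity":
        net = None
    elif config.reservoir == "auto":
        widths = config.widths or default_widths(D, L)
        net = init_reservoir(
            D, widths, seed=_subseed(ss_reservoir), weight_scale=config.weight_scale
        )
    else:
        raise ConfigError(f"unknown reservoir spec {config.reservoir!r}")

    FX = Xsel if net is None else net.transform(Xsel)
    opts = dataclasses.replace(config.solver, seed=_subseed(ss_solver))
    y_known = Xs[config.target_index]
    solution = _solve_core(FX, y_known, L, opts)

    forecast = (
        mu[config.target_index] + sd[config.target_index] * solution.forecast
    )
    provenance = {
        "master_seed": config.seed,
        "reservoir": None if net is None else net.spec(),
        "solver_options": dataclasses.asdict(opts),
        "selected_variables": selected,
        "target_position_in_selection": target_pos,
        "standardize": config.standardize,
        "target_mean": float(mu[config.target_index]),
        "target_std": float(sd[config.target_index]),
        "converged": solution.diagnostics.converged,
        "iterations": solution.diagnostics.iterations,
    }
    return forecast, solution, provenance


def rolling_forecast(
    X: np.ndarray, config: PredictConfig, m: int
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Whole-series evaluation: stride non-overlapping windows by the horizon.

    Successive known windows of length ``m`` start at 0, horizon,
    2*horizon, ...; each window's forecast covers the next ``horizon`` true
    values.  Returns the concatenated forecasts, the matching true values
    and per-window provenance records.
    """
    X = np.asarray(X, dtype=float)
    n_time = X.shape[1]
    h = config.horizon
    if m + h > n_time:
        raise DimensionError("series too short for one rolling window")
    preds, truths, records = [], [], []
    window = 0
    for start in range(0, n_time - m - h + 1, h):
        cfg = dataclasses.replace(config, seed=config.seed + window)
        fc, _, prov = predict_target(X[:, start : start + m], cfg)
        preds.append(fc)
        truths.append(X[config.target_index, start + m : start + m + h])
        prov["window_start"] = start
        records.append(prov)
        window += 1
    return np.concatenate(preds), np.concatenate(truths), records
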