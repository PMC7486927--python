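"""Forecast scoring and the coupled-Lorenz comparison study.

Scores are the normalized root-mean-square error (RMSE divided by the
standard deviation of the true future segment, so 1 is roughly the trivial
mean predictor) and the Pearson correlation.  The benchmark draws many
independent short windows from fresh 90-dimensional coupled-Lorenz
trajectories under one of three regimes -- time-invariant noise-free,
time-invariant with additive noise sigma = 1, and time-varying parameters --
predicts a randomly chosen target variable with the pipeline, and aggregates
the per-case normalized RMSE.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DegenerateNormalizationError, SimulationDivergedError
from .lorenz import LorenzConfig, add_observation_noise, simulate_coupled_lorenz
from .pipeline import PredictConfig, predict_target
from .solver import SolverOptions

REGIMES = ("noisefree", "noise1", "timevarying")

#: window starts are drawn uniformly from [0, OFFSET_MAX] samples into the
#: trajectory; at the default observation interval this spans one full
#: parameter switch period, so time-varying switches hit windows at uniform
#: random phases and the known segment lands at varying attractor positions
OFFSET_MAX = 1000


def rmse_normalized(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE divided by the std (population) of the true segment being scored.

    Scale-free: rescaling pred and truth together leaves it unchanged.  A
    constant truth segment has no scale and raises.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape or pred.shape[0] < 2:
        raise ConfigError("pred and truth must be equal-length vectors, k >= 2")
    sd = truth.std()
    if sd == 0:
        raise DegenerateNormalizationError("constant truth segment")
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / sd)


def pearson_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation coefficient between forecast and truth."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    return float(np.corrcoef(pred, truth)[0, 1])


@dataclass
class BenchmarkResult:
    """Per-case and aggregate scores for one regime/setting/method."""

    regime: str
    method: str
    m: int
    horizon: int
    rmse_values: list[float]
    pcc_values: list[float]
    master_seed: int
    regenerated: int = 0

    @property
    def n_cases(self) -> int:
        return len(self.rmse_values)

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_values))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse_values, ddof=1)) if self.n_cases > 1 else 0.0

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.pcc_values))

    def summary(self) -> dict:
        return {
            "regime": self.regime,
            "method": self.method,
            "m": self.m,
            "horizon": self.horizon,
            "n_cases": self.n_cases,
            "mean_rmse": self.mean_rmse,
            "sd_rmse": self.sd_rmse,
            "mean_pcc": self.mean_pcc,
            "master_seed": self.master_seed,
            "regenerated": self.regenerated,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        d = self.summary()
        d["rmse_values"] = self.rmse_values
        d["pcc_values"] = self.pcc_values
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _case_seeds(master_seed: int, case: int, attempt: int) -> tuple[int, int, int, np.random.Generator]:
    ss = np.random.SeedSequence([master_seed, case, attempt])
    sim_ss, noise_ss, pipe_ss, draw_ss = ss.spawn(4)
    to_int = lambda s: int(s.generate_state(1)[0] % (2**31))
    return to_int(sim_ss), to_int(noise_ss), to_int(pipe_ss), np.random.default_rng(
        draw_ss
    )


def run_lorenz_benchmark(
    regime: str,
    m: int = 50,
    horizon: int = 18,
    n_cases: int = 50,
    master_seed: int = 0,
    method: str = "arnn",
    lorenz_overrides: dict | None = None,
    solver_options: SolverOptions | None = None,
    normalization: str = "series",
) -> BenchmarkResult:
    """Aggregate normalized RMSE of ``method`` over seeded Lorenz cases.

    Each case simulates a fresh trajectory (fresh initial condition; fresh
    parameter schedule when time-varying), picks a random window start and a
    random target among the 90 variables, predicts ``horizon`` steps from
    the ``m``-point known window, and scores against the true continuation
    (the noisy observable in the noise regime).  A diverged simulation or a
    degenerate truth segment is regenerated with the next sub-seed and
    counted in ``regenerated``.

    method: "arnn" (reservoir), "linear" (identity reservoir), "mean"
    (known-window mean of the target, the trivial baseline).

    normalization: which standard deviation divides the RMSE.  "series"
    (default) uses the target's whole observed series for the case, a
    stable scale comparable across cases; "future" uses only the scored
    future segment, which is noisy for short horizons (a smooth
    ``horizon``-point arc can have near-zero spread).
    """
    if regime not in REGIMES:
        raise ConfigError(f"regime must be one of {REGIMES}")
    if method not in ("arnn", "linear", "mean"):
        raise ConfigError("method must be arnn | linear | mean")
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    if normalization not in ("series", "future"):
        raise ConfigError("normalization must be 'series' or 'future'")

    overrides = dict(lorenz_overrides or {})
    n_samples = m + horizon + OFFSET_MAX
    rmses: list[float] = []
    pccs: list[float] = []
    regenerated = 0

    for case in range(n_cases):
        for attempt in range(20):
            sim_seed, noise_seed, pipe_seed, rng = _case_seeds(
                master_seed, case, attempt
            )
            cfg = LorenzConfig(
                n_samples=n_samples,
                time_varying=(regime == "timevarying"),
                seed=sim_seed,
                **overrides,
            )
            try:
                traj = simulate_coupled_lorenz(cfg)
            except SimulationDivergedError:
                regenerated += 1
                continue
            if regime == "noise1":
                traj = add_observation_noise(traj, 1.0, noise_seed)
            offset = int(rng.integers(0, OFFSET_MAX + 1))
            target = int(rng.integers(0, traj.n_variables))
            window = traj.values[:, offset : offset + m + horizon]
            known, truth = window[:, :m], window[target, m:]
            try:
                if method == "mean":
                    forecast = np.full(horizon, known[target].mean())
                else:
                    pc = PredictConfig(
                        target_index=target,
                        horizon=horizon,
                        reservoir="auto" if method == "arnn" else "identity",
                        solver=solver_options or SolverOptions(),
                        seed=pipe_seed,
                    )
                    forecast, _, _ = predict_target(known, pc)
                if normalization == "series":
                    scale = float(traj.values[target].std())
                    if scale == 0:
                        raise DegenerateNormalizationError("constant target series")
                    rmses.append(float(np.sqrt(np.mean((forecast - truth) ** 2)) / scale))
                else:
                    rmses.append(rmse_normalized(forecast, truth))
                pccs.append(pearson_correlation(forecast, truth))
            except DegenerateNormalizationError:
                regenerated += 1
                continue
            break
        else:
            raise RuntimeError(f"case {case} failed after 20 regeneration attempts")

    return BenchmarkResult(
        regime=regime,
        method=method,
        m=m,
        horizon=horizon,
        rmse_values=rmses,
        pcc_values=pccs,
        master_seed=master_seed,
        regenerated=regenerated,
    )
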