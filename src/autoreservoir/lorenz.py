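"""Coupled-Lorenz benchmark simulator.

A ring of ``n_subsystems`` classic Lorenz oscillators supplies the
high-dimensional test bed for short-term forecasting: subsystem ``j`` obeys

    dx_j/dt = sigma_j (y_j - x_j) + c * x_{j-1}
    dy_j/dt = x_j (rho_j - z_j) - y_j
    dz_j/dt = x_j y_j - beta_j z_j

with indices taken modulo the ring size, so the full state has
``D = 3 * n_subsystems`` coordinates.  Integration is fixed-step RK4 and every
``sample_every``-th step is observed after a transient burn-in.  Two
perturbed regimes are supported: additive Gaussian observation noise on the
sampled values, and time-varying dynamics where each subsystem's
``(sigma, rho, beta)`` is redrawn from uniform ranges every ``switch_period``
time units.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationDivergedError

CLASSIC_SIGMA = 10.0
CLASSIC_RHO = 28.0
CLASSIC_BETA = 8.0 / 3.0

#: absolute state bound beyond which the integration is declared divergent
_DIVERGENCE_BOUND = 1e6


def default_param_ranges(rel: float = 0.2) -> dict[str, tuple[float, float]]:
    """Redraw intervals of +-``rel`` (relative) around the classic parameters."""
    return {
        "sigma": (CLASSIC_SIGMA * (1 - rel), CLASSIC_SIGMA * (1 + rel)),
        "rho": (CLASSIC_RHO * (1 - rel), CLASSIC_RHO * (1 + rel)),
        "beta": (CLASSIC_BETA * (1 - rel), CLASSIC_BETA * (1 + rel)),
    }


@dataclass(frozen=True)
class LorenzConfig:
    """Configuration of the coupled-Lorenz simulation.

    Parameters
    ----------
    n_subsystems
        Number of 3-dimensional Lorenz oscillators in the ring; the observed
        dimension is ``D = 3 * n_subsystems`` (default 30, i.e. D = 90).
    sigma, rho, beta
        Classic Lorenz parameters used in the time-invariant regime.
    coupling
        Strength ``c`` of the unidirectional ring coupling term ``c x_{j-1}``
        in each x-equation.
    dt
        RK4 integration step in model time units.
    sample_every
        An observation is recorded every ``sample_every`` integration steps,
        so the observation interval is ``dt * sample_every`` (default: every
        step, interval 0.01).
    n_samples
        Number of observations returned.
    transient_steps
        Integration steps discarded before the first observation.
    noise_strength
        Standard deviation of additive Gaussian observation noise applied to
        the sampled values (0 = noise free).
    time_varying
        When true, every subsystem's ``(sigma, rho, beta)`` is redrawn
        uniformly from ``param_ranges`` each time the integrated time crosses
        a multiple of ``switch_period`` (including t = 0).
    switch_period
        Time units between parameter redraws.
    param_ranges
        Mapping ``{"sigma": (lo, hi), "rho": ..., "beta": ...}``; defaults to
        +-20% around the classic values.
    seed
        Seeds the initial condition, the parameter schedule and the
        observation noise; identical seeds give bit-identical trajectories.
    """

    n_subsystems: int = 30
    sigma: float = CLASSIC_SIGMA
    rho: float = CLASSIC_RHO
    beta: float = CLASSIC_BETA
    coupling: float = 0.1
    dt: float = 0.01
    sample_every: int = 1
    n_samples: int = 200
    transient_steps: int = 1000
    noise_strength: float = 0.0
    time_varying: bool = False
    switch_period: float = 10.0
    param_ranges: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subsystems < 1:
            raise ConfigError("n_subsystems must be >= 1")
        if self.dt <= 0 or self.sample_every < 1 or self.n_samples < 1:
            raise ConfigError("dt, sample_every and n_samples must be positive")
        if self.transient_steps < 0:
            raise ConfigError("transient_steps must be >= 0")
        if self.noise_strength < 0:
            raise ConfigError("noise_strength must be >= 0")
        if self.time_varying and self.switch_period <= 0:
            raise ConfigError("switch_period must be > 0 when time_varying")

    @property
    def dimension(self) -> int:
        return 3 * self.n_subsystems

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LorenzConfig":
        d = json.loads(text)
        if d.get("param_ranges") is not None:
            d["param_ranges"] = {k: tuple(v) for k, v in d["param_ranges"].items()}
        return cls(**d)


@dataclass
class Trajectory:
    """Observed multivariate time series: ``values`` is D x n_samples."""

    values: np.ndarray
    times: np.ndarray
    config: LorenzConfig

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times.shape[0]:
            raise ConfigError("values must be D x n_samples matching times")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Rows = variables, columns = time points, header row of times."""
        df = pd.DataFrame(
            self.values,
            index=[f"x{i + 1}" for i in range(self.values.shape[0])],
            columns=self.times,
        )
        df.to_csv(path, index_label="variable")

    @classmethod
    def from_csv(cls, path: str | Path, config: LorenzConfig | None = None) -> "Trajectory":
        df = pd.read_csv(path, index_col=0)
        times = np.asarray([float(c) for c in df.columns])
        cfg = config if config is not None else LorenzConfig(
            n_subsystems=max(1, df.shape[0] // 3), n_samples=df.shape[1]
        )
        return cls(values=df.to_numpy(dtype=float), times=times, config=cfg)

    def save_fixture(self, stem: str | Path) -> None:
        """Write ``<stem>.json`` (config) and ``<stem>.csv`` (values) side by side."""
        stem = Path(stem)
        stem.with_suffix(".json").write_text(self.config.to_json())
        self.to_csv(stem.with_suffix(".csv"))

    @classmethod
    def load_fixture(cls, stem: str | Path) -> "Trajectory":
        stem = Path(stem)
        cfg = LorenzConfig.from_json(stem.with_suffix(".json").read_text())
        return cls.from_csv(stem.with_suffix(".csv"), config=cfg)


def _rhs(state: np.ndarray, sigma, rho, beta, coupling: float) -> np.ndarray:
    # state has shape (3, n); parameters are scalars or length-n vectors
    x, y, z = state
    dx = sigma * (y - x) + coupling * np.roll(x, 1)
    dy = x * (rho - z) - y
    dz = x * y - beta * z
    return np.stack([dx, dy, dz])


def simulate_coupled_lorenz(
    config: LorenzConfig, initial_state: np.ndarray | None = None
) -> Trajectory:
    """Integrate the ring of Lorenz subsystems and return sampled observations.

    ``initial_state`` (shape (3, n_subsystems)) overrides the seeded random
    initial condition drawn uniformly from [-10, 10] per coordinate.

    Raises
    ------
    SimulationDivergedError
        If any state coordinate becomes non-finite or exceeds 1e6 in
        magnitude during integration (the offending step is reported).
    """
    n = config.n_subsystems
    ss = np.random.SeedSequence(config.seed)
    rng_ic, rng_par, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    if initial_state is not None:
        state = np.array(initial_state, dtype=float).reshape(3, n)
    else:
        state = rng_ic.uniform(-10.0, 10.0, size=(3, n))

    if config.time_varying:
        ranges = config.param_ranges or default_param_ranges()
        def redraw():
            return tuple(
                rng_par.uniform(*ranges[name], size=n)
                for name in ("sigma", "rho", "beta")
            )
        sigma, rho, beta = redraw()
        epoch = 0  # index of the current switch interval
    else:
        sigma, rho, beta = config.sigma, config.rho, config.beta

    dt = config.dt
    total_steps = config.transient_steps + (config.n_samples - 1) * config.sample_every
    samples = np.empty((3, n, config.n_samples))
    sample_idx = 0

    for step in range(total_steps + 1):
        if config.time_varying:
            new_epoch = int(np.floor(step * dt / config.switch_period))
            if new_epoch > epoch:
                sigma, rho, beta = redraw()
                epoch = new_epoch
        if step >= config.transient_steps and (
            (step - config.transient_steps) % config.sample_every == 0
        ):
            samples[:, :, sample_idx] = state
            sample_idx += 1
        if step == total_steps:
            break
        k1 = _rhs(state, sigma, rho, beta, config.coupling)
        k2 = _rhs(state + 0.5 * dt * k1, sigma, rho, beta, config.coupling)
        k3 = _rhs(state + 0.5 * dt * k2, sigma, rho, beta, config.coupling)
        k4 = _rhs(state + dt * k3, sigma, rho, beta, config.coupling)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > _DIVERGENCE_BOUND:
            raise SimulationDivergedError(step + 1)

    # (3, n, T) -> (D, T) with variable order x_1, y_1, z_1, x_2, ...
    values = samples.transpose(1, 0, 2).reshape(3 * n, config.n_samples)
    t0 = config.transient_steps * dt
    times = t0 + np.arange(config.n_samples) * (dt * config.sample_every)

    traj = Trajectory(values=values, times=times, config=config)
    if config.noise_strength > 0:
        traj.values = traj.values + rng_noise.normal(
            0.0, config.noise_strength, size=traj.values.shape
        )
    return traj


def add_observation_noise(traj: Trajectory, strength: float, seed: int) -> Trajectory:
    """Return a copy of ``traj`` with i.i.d. N(0, strength^2) added to every entry."""
    if strength < 0:
        raise ConfigError("noise strength must be >= 0")
    rng = np.random.default_rng(seed)
    values = traj.values.copy()
    if strength > 0:
        values += rng.normal(0.0, strength, size=values.shape)
    return Trajectory(values=values, times=traj.times.copy(), config=traj.config)


def classic_single_lorenz(config: LorenzConfig) -> Trajectory:
    """Convenience wrapper: a single, uncoupled classic Lorenz system."""
    if config.n_subsystems != 1 or config.coupling != 0:
        warnings.warn("classic_single_lorenz overrides n_subsystems=1, coupling=0")
        config = dataclasses.replace(config, n_subsystems=1, coupling=0.0)
    return simulate_coupled_lorenz(config)
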