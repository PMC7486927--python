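"""Fixed random multilayer tanh network used as the auto-reservoir.

The network F maps each spatial snapshot X^t (a D-vector) to a feature
vector F(X^t) of dimension D-tilde.  Weights are drawn once from a seeded
RNG and never trained; only the linear readout around F is estimated by the
solver.  Four tanh layers by default; zero biases unless configured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DimensionError


def default_widths(d_in: int, L: int) -> list[int]:
    """Default layer widths: three hidden layers of 1.5 D, output max(D, 3 L).

    Keeps the feature dimension comfortably above the embedding dimension L
    (the solvability requirement) with headroom against tanh saturation.
    """
    hidden = int(round(1.5 * d_in))
    out = max(d_in, 3 * L)
    return [hidden, hidden, hidden, out]


@dataclass
class ReservoirNet:
    """A fixed random feedforward tanh network.

    ``layer_weights[k]`` has shape (widths[k], widths[k-1]) with widths[-1]
    understood as ``d_in``; entries are i.i.d. uniform on [-s_k, s_k] where
    s_k is ``weight_scale`` or 1/sqrt(fan_in) when unset.
    """

    layer_weights: list[np.ndarray]
    layer_biases: list[np.ndarray]
    seed: int
    weight_scale: float | None = None

    @property
    def d_in(self) -> int:
        return self.layer_weights[0].shape[1]

    @property
    def d_out(self) -> int:
        return self.layer_weights[-1].shape[0]

    @property
    def widths(self) -> list[int]:
        return [w.shape[0] for w in self.layer_weights]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply F column-wise: (D x m) -> (D~ x m), entries in (-1, 1).

        Columns are mapped independently; there is no temporal mixing.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.d_in:
            raise DimensionError(
                f"input has {X.shape[0]} rows, reservoir expects {self.d_in}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("reservoir input must be finite")
        H = X
        for W, b in zip(self.layer_weights, self.layer_biases):
            H = np.tanh(W @ H + b[:, None])
        return H

    def spec(self) -> dict:
        return {
            "d_in": self.d_in,
            "widths": self.widths,
            "seed": self.seed,
            "weight_scale": self.weight_scale,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.spec(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ReservoirNet":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        text = p.read_text() if p is not None and p.exists() else str(text_or_path)
        spec = json.loads(text)
        return init_reservoir(**spec)


def init_reservoir(
    d_in: int,
    widths: list[int],
    seed: int = 0,
    weight_scale: float | None = None,
) -> ReservoirNet:
    """Draw the fixed random weights of a tanh reservoir.

    Weights of layer k are uniform on [-s, s] with s = ``weight_scale`` if
    given, else 1/sqrt(fan_in) so pre-activations stay O(1) on standardized
    inputs.  Biases are zero.  Identical (d_in, widths, seed, weight_scale)
    give elementwise-identical networks.
    """
    if d_in < 1:
        raise ConfigError("d_in must be >= 1")
    if not widths or any(w < 1 for w in widths):
        raise ConfigError("widths must be a non-empty list of positive ints")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    fan_in = d_in
    for w in widths:
        s = weight_scale if weight_scale is not None else 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-s, s, size=(w, fan_in)))
        biases.append(np.zeros(w))
        fan_in = w
    return ReservoirNet(
        layer_weights=weights, layer_biases=biases, seed=seed, weight_scale=weight_scale
    )
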