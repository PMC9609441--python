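"""Data augmentation of discrete D50(t) milling samples.

Wet-milling experiments only yield a handful of D50 samples (the mill
must be stopped to draw them).  Model calibration, however, needs a dense
comminution profile.  Two surrogates bridge the gap:

* a small feed-forward neural network — sigmoid hidden layers, ReLU
  output (regression, non-negative sizes), He-initialized weights,
  trained by full-batch gradient-descent backpropagation on min-max
  scaled inputs/outputs;
* polynomial least-squares regression (default order 2).

Both report the shared ``mse_percent`` training metric and can be
evaluated on a dense time grid to produce the reference profile used by
the breakage-model fits.  Training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import mse_percent

__all__ = [
    "AnnModel",
    "SurrogateProfile",
    "sigmoid",
    "relu",
    "he_init",
    "train_ann",
    "polyfit_profile",
    "PolynomialModel",
    "augment_profile",
]


def sigmoid(x):
    """Logistic activation 1 / (1 + exp(-x)), numerically stable."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    expx = np.exp(x[~pos])
    out[~pos] = expx / (1.0 + expx)
    return out if out.ndim else float(out)


def relu(x):
    """Rectified linear unit max(0, x)."""
    x = np.asarray(x, dtype=float)
    out = np.maximum(x, 0.0)
    return out if out.ndim else float(out)


def he_init(n_in: int, n_out: int, rng) -> np.ndarray:
    """He weight initialization: zero-mean normal, variance 2 / n_in.

    Suited to rectified activations; ``rng`` is a seeded Generator (or an
    int seed) so the draw is reproducible.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("layer sizes must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


@dataclass
class AnnModel:
    """Feed-forward D50(t) surrogate.

    ``layer_sizes`` includes input and output (default 1-8-8-1).  Hidden
    activations are sigmoid; the output unit is ReLU so predicted sizes
    are non-negative.  Inputs are min-max scaled to [0, 1] and outputs
    scaled by the maximum training D50; the scaling parameters are part
    of the model.
    """

    layer_sizes: tuple
    weights: list  # list of (n_in, n_out) arrays
    biases: list  # list of (n_out,) arrays
    seed: int
    t_min: float
    t_max: float
    d_scale: float
    mse_percent: float = float("nan")

    # -- forward pass ------------------------------------------------------

    def _scale_t(self, t):
        return (np.asarray(t, dtype=float) - self.t_min) / (self.t_max - self.t_min)

    def forward(self, t):
        """Predict D50 (um) at times t (s); vectorized."""
        a = self._scale_t(t).reshape(-1, 1)
        n_layers = len(self.weights)
        for idx, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = relu(z) if idx == n_layers - 1 else sigmoid(z)
        return a.ravel() * self.d_scale

    def __call__(self, t):
        return self.forward(t)

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "d_scale": self.d_scale,
            "mse_percent": self.mse_percent,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AnnModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(
            layer_sizes=tuple(data["layer_sizes"]),
            weights=[np.asarray(w) for w in data["weights"]],
            biases=[np.asarray(b) for b in data["biases"]],
            seed=data["seed"],
            t_min=data["t_min"],
            t_max=data["t_max"],
            d_scale=data["d_scale"],
            mse_percent=data["mse_percent"],
        )


def _forward_cached(weights, biases, a0):
    """Forward pass keeping the activations for backprop."""
    activations = [a0]
    zs = []
    a = a0
    n_layers = len(weights)
    for idx, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w + b
        zs.append(z)
        a = relu(z) if idx == n_layers - 1 else sigmoid(z)
        activations.append(a)
    return zs, activations


def ann_gradients(weights, biases, t_scaled, target_scaled):
    """Backpropagation gradients of the half-mean-squared training loss.

    Loss = mean over samples of 0.5 * (prediction - target)^2 on the
    scaled variables.  Returns (loss, dW list, db list).
    """
    a0 = t_scaled.reshape(-1, 1)
    target = target_scaled.reshape(-1, 1)
    zs, activations = _forward_cached(weights, biases, a0)
    n = a0.shape[0]
    n_layers = len(weights)
    pred = activations[-1]
    diff = pred - target
    loss = float(0.5 * np.mean(diff**2))
    grads_w = [None] * n_layers
    grads_b = [None] * n_layers
    # output layer: ReLU derivative
    delta = diff * (zs[-1] > 0) / n
    for layer in range(n_layers - 1, -1, -1):
        grads_w[layer] = activations[layer].T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            s = activations[layer]  # sigmoid output of the previous layer
            delta = (delta @ weights[layer].T) * s * (1.0 - s)
    return loss, grads_w, grads_b


def train_ann(
    data: pd.DataFrame,
    layer_sizes: Sequence[int] = (1, 8, 8, 1),
    seed: int = 42,
    epochs: int = 20000,
    learning_rate: float = 0.05,
) -> AnnModel:
    """Train the surrogate on (time_s, d50_um) samples.

    Full-batch gradient descent; the output bias starts at the mean
    scaled target so the ReLU unit is active from the first epoch.
    Raises if the loss diverges (advice: lower the learning rate).
    """
    if not {"time_s", "d50_um"} <= set(data.columns):
        raise ValueError("training data needs columns time_s and d50_um")
    if len(data) < 2:
        raise ValueError("need at least 2 training points")
    if list(layer_sizes)[0] != 1 or list(layer_sizes)[-1] != 1:
        raise ValueError("network maps one input (t) to one output (D50)")
    t = data["time_s"].to_numpy(dtype=float)
    d = data["d50_um"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise ValueError("D50 values must be positive")
    t_min, t_max = float(t.min()), float(t.max())
    if t_max == t_min:
        raise ValueError("training times are all identical")
    d_scale = float(d.max())
    t_scaled = (t - t_min) / (t_max - t_min)
    target_scaled = d / d_scale

    rng = np.random.default_rng(seed)
    sizes = list(layer_sizes)
    weights = [he_init(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    # center the ReLU output on the mean target so the unit starts active
    # (a dead output unit would never receive a gradient)
    z_out, _ = _forward_cached(weights[:-1], biases[:-1], t_scaled.reshape(-1, 1))
    hidden = sigmoid(z_out[-1]) if z_out else t_scaled.reshape(-1, 1)
    biases[-1][:] = target_scaled.mean() - float(np.mean(hidden @ weights[-1]))

    for epoch in range(epochs):
        loss, grads_w, grads_b = ann_gradients(weights, biases, t_scaled, target_scaled)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}; lower the learning rate"
            )
        for layer in range(len(weights)):
            weights[layer] -= learning_rate * grads_w[layer]
            biases[layer] -= learning_rate * grads_b[layer]

    model = AnnModel(
        layer_sizes=tuple(sizes),
        weights=weights,
        biases=biases,
        seed=seed,
        t_min=t_min,
        t_max=t_max,
        d_scale=d_scale,
    )
    model.mse_percent = mse_percent(model.forward(t), d)
    return model


# ---------------------------------------------------------------------------
# polynomial surrogate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolynomialModel:
    """Least-squares polynomial D50(t) surrogate (highest degree first)."""

    coefficients: np.ndarray
    t_min: float
    t_max: float
    mse_percent: float

    @property
    def order(self) -> int:
        return self.coefficients.size - 1

    def forward(self, t):
        return np.polyval(self.coefficients, np.asarray(t, dtype=float))

    def __call__(self, t):
        return self.forward(t)


def polyfit_profile(data: pd.DataFrame, order: int = 2) -> PolynomialModel:
    """Fit D50(t) with a polynomial of the given order.

    The order must be at least 1 and below the number of distinct times
    (otherwise the normal equations are rank-deficient).
    """
    if not {"time_s", "d50_um"} <= set(data.columns):
        raise ValueError("training data needs columns time_s and d50_um")
    t = data["time_s"].to_numpy(dtype=float)
    d = data["d50_um"].to_numpy(dtype=float)
    n_distinct = np.unique(t).size
    if order < 1:
        raise ValueError("order must be at least 1")
    if order >= n_distinct:
        raise ValueError(
            f"order {order} too high for {n_distinct} distinct sampling times"
        )
    coeffs = np.polyfit(t, d, order)
    fit = np.polyval(coeffs, t)
    return PolynomialModel(
        coefficients=coeffs,
        t_min=float(t.min()),
        t_max=float(t.max()),
        mse_percent=mse_percent(fit, d),
    )


# ---------------------------------------------------------------------------
# dense profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurrogateProfile:
    times: np.ndarray  # s
    d50: np.ndarray  # um, floored at 0
    mse_percent: float  # training fit error of the generating model
    method: str  # "ann" or "polynomial(order)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "d50_um": self.d50})


def augment_profile(model, t_grid, allow_extrapolation: bool = False) -> SurrogateProfile:
    """Evaluate a trained surrogate on a dense time grid.

    By default the grid must lie inside the training span; extrapolation
    must be requested explicitly.  Negative predictions are floored at 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if not allow_extrapolation:
        if t_grid.min() < model.t_min - 1e-9 or t_grid.max() > model.t_max + 1e-9:
            raise ValueError(
                "time grid extends beyond the training span "
                f"[{model.t_min}, {model.t_max}]; pass allow_extrapolation=True"
            )
    pred = np.clip(model.forward(t_grid), 0.0, None)
    if isinstance(model, AnnModel):
        method = "ann"
    elif isinstance(model, PolynomialModel):
        method = f"polynomial({model.order})"
    else:
        method = type(model).__name__
    return SurrogateProfile(
        times=t_grid, d50=pred, mse_percent=model.mse_percent, method=method
    )
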