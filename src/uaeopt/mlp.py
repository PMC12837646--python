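"""Single-hidden-layer perceptron surrogates.

The response-surface model is Y = g(W2 · f(W1 · X + B1) + B2): a 3-input
MLP whose hidden activation f and output activation g are one of tanh,
logistic or identity.  Forward evaluation with published weights, and
de-novo training by multi-restart quasi-Newton (BFGS) minimization of the
sum-of-squares loss in scaled space, both live here.  Gradients are exact
(one-hidden-layer backpropagation), restarts are independently seeded, and
training is capped at a fixed number of BFGS iterations, which plays the
role of an early-stopping epoch limit on this small, noise-limited dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .scaling import Scaler, fit_scaler

__all__ = [
    "MLPParameters", "TrainConfig", "TrainedSurrogate",
    "forward", "forward_scaled", "split_dataset", "train",
    "sweep_hidden_sizes", "predict_grid", "save_model", "load_model",
]

# activation -> (f, f' expressed through the activation output h)
ACTIVATIONS = {
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "logistic": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda h: h * (1.0 - h)),
    "identity": (lambda z: z, lambda h: np.ones_like(h)),
}

# default output-scaling interval matched to the codomain of the output
# activation; tanh outputs live in (-1, 1), the rest are unconstrained and
# use the unit interval.
OUTPUT_INTERVALS = {"tanh": (-1.0, 1.0), "logistic": (0.0, 1.0),
                    "identity": (0.0, 1.0)}
INPUT_INTERVAL = (-1.0, 1.0)


@dataclass(frozen=True)
class MLPParameters:
    """Weights, biases and activation identifiers of one surrogate."""

    W1: np.ndarray              # hidden x inputs
    B1: np.ndarray              # hidden
    W2: np.ndarray              # outputs x hidden
    B2: np.ndarray              # outputs
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self):
        W1, B1, W2, B2 = (np.asarray(m, dtype=float)
                          for m in (self.W1, self.B1, self.W2, self.B2))
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "B1", B1)
        object.__setattr__(self, "W2", W2)
        object.__setattr__(self, "B2", B2)
        if W1.ndim != 2 or W2.ndim != 2:
            raise ValueError("W1 and W2 must be 2-D matrices")
        if B1.shape != (W1.shape[0],):
            raise ValueError(
                f"B1 length {B1.shape} does not match W1 rows {W1.shape[0]}")
        if W2.shape[1] != W1.shape[0]:
            raise ValueError(
                f"W2 columns ({W2.shape[1]}) must equal W1 rows "
                f"({W1.shape[0]})")
        if B2.shape != (W2.shape[0],):
            raise ValueError(
                f"B2 length {B2.shape} does not match W2 rows {W2.shape[0]}")
        for which in (self.hidden_activation, self.output_activation):
            if which not in ACTIVATIONS:
                raise ValueError(f"unknown activation {which!r}")
        for m in (W1, B1, W2, B2):
            if not np.isfinite(m).all():
                raise ValueError("parameters contain non-finite entries")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.W2.shape[0]


def forward_scaled(params: MLPParameters, X_scaled: np.ndarray) -> np.ndarray:
    """Evaluate the network in scaled space: g(W2 · f(W1 · x + B1) + B2)."""
    X_scaled = np.atleast_2d(np.asarray(X_scaled, dtype=float))
    if X_scaled.shape[1] != params.n_inputs:
        raise ValueError(
            f"input dimension mismatch: network expects {params.n_inputs} "
            f"columns, got {X_scaled.shape[1]}")
    f_hidden = ACTIVATIONS[params.hidden_activation][0]
    f_output = ACTIVATIONS[params.output_activation][0]
    hidden = f_hidden(X_scaled @ params.W1.T + params.B1)
    return f_output(hidden @ params.W2.T + params.B2)


def forward(params: MLPParameters, X: np.ndarray,
            input_scaler: Scaler | None = None,
            output_scaler: Scaler | None = None) -> np.ndarray:
    """Evaluate the network on factor settings in original units.

    The input scaler is applied before the network and the output scaler is
    inverted afterwards, so predictions come back in response units.  With
    no scalers the evaluation is the bare network.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_scaled = input_scaler.apply(X) if input_scaler is not None else X
    Y_scaled = forward_scaled(params, X_scaled)
    if output_scaler is not None:
        return output_scaler.invert(Y_scaled)
    return Y_scaled


def split_dataset(n_samples: int, fractions=(0.6, 0.2, 0.2),
                  seed: int = 0) -> np.ndarray:
    """Randomly assign samples to 'train' / 'test' / 'valid' partitions.

    Sizes are the rounded fractions with the remainder going to the
    validation set, so 15 samples give the 9/3/3 split.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(round(n_samples * fractions[0]))
    n_test = int(round(n_samples * fractions[1]))
    n_valid = n_samples - n_train - n_test
    if min(n_train, n_test, n_valid) < 1:
        raise ValueError(
            f"too few samples ({n_samples}) for split fractions {fractions}")
    labels = np.array(["train"] * n_train + ["test"] * n_test +
                      ["valid"] * n_valid)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n_samples)]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: data split, restarts, optimizer budget, seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    restarts: int = 200
    max_epochs: int = 100
    early_stop_epoch: int = 70
    init_scale: float = 0.5
    input_interval: tuple[float, float] = INPUT_INTERVAL
    output_interval: tuple[float, float] | None = None  # by activation
    select_by: str = "train"              # partition scoring the restarts
    seed: int = 0

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 1 <= self.early_stop_epoch <= self.max_epochs:
            raise ValueError("early_stop_epoch must lie in "
                             "[1, max_epochs]")
        if self.select_by not in ("train", "test", "valid"):
            raise ValueError("select_by must be 'train', 'test' or 'valid'")


@dataclass
class TrainedSurrogate:
    """A fitted surrogate together with its scalers and split bookkeeping.

    ``predict`` returns responses in original units; the stored performance
    is the pooled coefficient of determination (1 - SSE/SST in scaled
    space) per partition, and ``errors`` the scaled sum-of-squares.
    """

    parameters: MLPParameters
    input_scaler: Scaler
    output_scaler: Scaler
    response_names: list[str]
    split: np.ndarray
    performance: dict[str, float]
    errors: dict[str, float]
    config: TrainConfig = field(default=None)
    restarts_failed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return forward(self.parameters, X, self.input_scaler,
                       self.output_scaler)


def _pack(W1, B1, W2, B2):
    return np.concatenate([W1.ravel(), B1, W2.ravel(), B2])


def _unpack(theta, n_in, n_hidden, n_out):
    i = 0
    W1 = theta[i:i + n_hidden * n_in].reshape(n_hidden, n_in)
    i += n_hidden * n_in
    B1 = theta[i:i + n_hidden]
    i += n_hidden
    W2 = theta[i:i + n_out * n_hidden].reshape(n_out, n_hidden)
    i += n_out * n_hidden
    B2 = theta[i:i + n_out]
    return W1, B1, W2, B2


def _loss_and_grad(theta, Xs, Ys, n_in, n_hidden, n_out, f_hidden, f_output):
    f1, d1 = ACTIVATIONS[f_hidden]
    f2, d2 = ACTIVATIONS[f_output]
    W1, B1, W2, B2 = _unpack(theta, n_in, n_hidden, n_out)
    H = f1(Xs @ W1.T + B1)
    Yhat = f2(H @ W2.T + B2)
    R = Yhat - Ys
    loss = float(np.sum(R * R))
    G2 = 2.0 * R * d2(Yhat)
    gW2 = G2.T @ H
    gB2 = G2.sum(axis=0)
    GH = (G2 @ W2) * d1(H)
    gW1 = GH.T @ Xs
    gB1 = GH.sum(axis=0)
    return loss, _pack(gW1, gB1, gW2, gB2)


def train(X: np.ndarray, Y: np.ndarray, hidden_size: int,
          config: TrainConfig = TrainConfig(),
          response_names: list[str] | None = None,
          hidden_activation: str = "tanh",
          output_activation: str = "identity") -> TrainedSurrogate:
    """Fit a surrogate by best-of-restarts quasi-Newton optimization.

    Every restart draws fresh uniform initial weights, runs BFGS on the
    scaled sum-of-squares training loss for at most ``early_stop_epoch``
    iterations, and the restart with the best training fit is kept (with a
    fixed training partition the best training r-squared and the lowest
    training loss coincide).  A restart whose loss turns non-finite is
    discarded and counted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    n, n_in = X.shape
    n_out = Y.shape[1]
    if response_names is None:
        response_names = [f"y{j + 1}" for j in range(n_out)]

    split = split_dataset(n, config.fractions, seed=config.seed)
    train_idx = np.flatnonzero(split == "train")
    if train_idx.size < 5:
        raise ValueError("need at least 5 training samples")

    out_interval = (config.output_interval or
                    OUTPUT_INTERVALS[output_activation])
    input_scaler = fit_scaler(X, "minmax", interval=config.input_interval)
    output_scaler = fit_scaler(Y, "minmax", interval=out_interval)
    Xs, Ys = input_scaler.apply(X), output_scaler.apply(Y)

    n_params = hidden_size * (n_in + 1) + n_out * (hidden_size + 1)
    rng = np.random.default_rng(config.seed)
    best_loss, best_theta, failed = np.inf, None, 0
    args = (Xs[train_idx], Ys[train_idx], n_in, hidden_size, n_out,
            hidden_activation, output_activation)
    select_idx = np.flatnonzero(split == config.select_by)
    select_args = (Xs[select_idx], Ys[select_idx], n_in, hidden_size, n_out,
                   hidden_activation, output_activation)
    for _ in range(config.restarts):
        theta0 = rng.uniform(-config.init_scale, config.init_scale, n_params)
        result = minimize(_loss_and_grad, theta0, args=args, jac=True,
                          method="BFGS",
                          options={"maxiter": config.early_stop_epoch,
                                   "gtol": 1e-10})
        if not np.isfinite(result.fun) or not np.isfinite(result.x).all():
            failed += 1
            continue
        score = (result.fun if config.select_by == "train"
                 else _loss_and_grad(result.x, *select_args)[0])
        if score < best_loss:
            best_loss, best_theta = score, result.x
    if best_theta is None:
        raise RuntimeError("all restarts diverged")
    if failed:
        warnings.warn(f"{failed} restart(s) discarded (non-finite loss)",
                      stacklevel=2)

    params = MLPParameters(
        *_unpack(best_theta, n_in, hidden_size, n_out),
        hidden_activation=hidden_activation,
        output_activation=output_activation)
    Yhat_s = forward_scaled(params, Xs)
    performance, errors = {}, {}
    for part in ("train", "test", "valid"):
        idx = np.flatnonzero(split == part)
        resid = Yhat_s[idx] - Ys[idx]
        sse = float(np.sum(resid * resid))
        sstot = float(np.sum((Ys[idx] - Ys[idx].mean(axis=0)) ** 2))
        errors[part] = sse
        performance[part] = 1.0 - sse / sstot if sstot > 0 else np.nan
    return TrainedSurrogate(
        parameters=params, input_scaler=input_scaler,
        output_scaler=output_scaler, response_names=list(response_names),
        split=split, performance=performance, errors=errors, config=config,
        restarts_failed=failed)


def sweep_hidden_sizes(X, Y, sizes, config: TrainConfig = TrainConfig(),
                       **train_kwargs) -> tuple[pd.DataFrame, int]:
    """Train at each hidden-layer size; recommend the argmax training fit.

    Ties are broken toward the smaller network.  Returns the per-size
    table and the recommended size.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("size range must be non-empty")
    records = []
    for size in sizes:
        fit = train(X, Y, size, config=config, **train_kwargs)
        records.append({"hidden_size": size,
                        "train_r2": fit.performance["train"],
                        "train_sse": fit.errors["train"]})
    table = pd.DataFrame.from_records(records)
    best = table.loc[table["train_r2"].idxmax(), "train_r2"]
    recommended = int(table.loc[table["train_r2"] >= best,
                                "hidden_size"].min())
    return table, recommended


def predict_grid(surrogate: TrainedSurrogate, bounds: dict, step: dict,
                 margin: float = 0.25) -> pd.DataFrame:
    """Tabulate surrogate predictions on a regular factor grid.

    ``bounds`` maps factor name -> (lo, hi) and ``step`` maps factor name
    -> grid step.  Bounds further than ``margin`` times the fitted range
    outside the design box are refused: the surrogate is an interpolator
    and far extrapolation is meaningless.
    """
    factors = ("time", "temperature", "ratio")
    axes = []
    for k, name in enumerate(factors):
        lo, hi = bounds[name]
        h = step[name]
        if h <= 0:
            raise ValueError(f"step for {name} must be positive")
        fit_lo = surrogate.input_scaler.data_min[k]
        fit_hi = surrogate.input_scaler.data_max[k]
        slack = margin * max(fit_hi - fit_lo, 1.0)
        if lo < fit_lo - slack or hi > fit_hi + slack:
            raise ValueError(
                f"bounds for {name} ({lo}, {hi}) lie far outside the design "
                f"box ({fit_lo}, {fit_hi}); refusing to extrapolate")
        axes.append(np.arange(lo, hi + 0.5 * h, h))
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    predictions = surrogate.predict(grid)
    frame = pd.DataFrame(grid, columns=factors)
    for j, name in enumerate(surrogate.response_names):
        frame[name] = predictions[:, j]
    return frame


def save_model(surrogate: TrainedSurrogate, path: str | Path) -> Path:
    """Serialize a surrogate (parameters + scalers) to a JSON bundle."""
    p = surrogate.parameters
    doc = {
        "response_names": surrogate.response_names,
        "hidden_activation": p.hidden_activation,
        "output_activation": p.output_activation,
        "W1": p.W1.tolist(), "B1": p.B1.tolist(),
        "W2": p.W2.tolist(), "B2": p.B2.tolist(),
        "input_scaler": surrogate.input_scaler.to_dict(),
        "output_scaler": surrogate.output_scaler.to_dict(),
        "split": surrogate.split.tolist(),
        "performance": surrogate.performance,
        "errors": surrogate.errors,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_model(path: str | Path) -> TrainedSurrogate:
    doc = json.loads(Path(path).read_text())
    params = MLPParameters(
        W1=doc["W1"], B1=doc["B1"], W2=doc["W2"], B2=doc["B2"],
        hidden_activation=doc["hidden_activation"],
        output_activation=doc["output_activation"])
    return TrainedSurrogate(
        parameters=params,
        input_scaler=Scaler.from_dict(doc["input_scaler"]),
        output_scaler=Scaler.from_dict(doc["output_scaler"]),
        response_names=doc["response_names"],
        split=np.asarray(doc["split"]),
        performance=doc["performance"], errors=doc["errors"])
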