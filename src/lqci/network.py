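"""Feed-forward 17-6-1 backpropagation network, written from scratch.

The model is a three-layer perceptron with sigmoid hidden units trained by
full-batch gradient descent on the squared-error objective

    E = 1/2 * sum_n || y_n - yhat_n ||^2

with early stopping when ``E < R`` (the target error) or an epoch cap is
reached.  The low-level functions (:func:`sigmoid`, :func:`forward`,
:func:`error_E`, :func:`gradients`, :func:`train_bp`) operate on explicit
:class:`NetworkParams`; :class:`BPRegressor` wraps them in a scikit-learn
estimator that also owns the min-max scaling of inputs (to [0, 1]) and
targets (to [margin, 1 - margin], so a sigmoid output unit can reach every
training target with slack for denormalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "NetworkTopology",
    "NetworkParams",
    "TrainConfig",
    "TrainingDivergence",
    "sigmoid",
    "init_params",
    "forward",
    "error_E",
    "gradients",
    "train_bp",
    "BPRegressor",
]


class TrainingDivergence(RuntimeError):
    """Raised when the training error becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training error became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes; the study network is 17-6-1."""

    n_in: int = 17
    n_hidden: int = 6
    n_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def n_genes(self) -> int:
        """Total parameter count (the GA chromosome length)."""
        return (self.n_hidden * (self.n_in + self.n_out)
                + self.n_hidden + self.n_out)


@dataclass
class NetworkParams:
    """Weights and biases: ``v1`` (in->hidden), ``b1``, ``w2``
    (hidden->out), ``b2``."""

    v1: np.ndarray   # (n_in, n_hidden)
    b1: np.ndarray   # (n_hidden,)
    w2: np.ndarray   # (n_hidden, n_out)
    b2: np.ndarray   # (n_out,)

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        n_in, n_hidden = self.v1.shape
        if self.b1.shape != (n_hidden,):
            raise ValueError("b1 shape inconsistent with v1")
        if self.w2.shape[0] != n_hidden:
            raise ValueError("w2 shape inconsistent with v1")
        if self.b2.shape != (self.w2.shape[1],):
            raise ValueError("b2 shape inconsistent with w2")
        if not all(np.all(np.isfinite(a)) for a in (self.v1, self.b1, self.w2, self.b2)):
            raise ValueError("parameters must be finite")

    @property
    def topology(self) -> NetworkTopology:
        return NetworkTopology(self.v1.shape[0], self.v1.shape[1],
                               self.w2.shape[1])

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.v1.copy(), self.b1.copy(),
                             self.w2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings.

    ``target_error`` is the early-stop threshold R on E; learning rate and
    R both default to the study values (0.001).  ``momentum`` defaults to
    the classical 0.9 heavy-ball coefficient: at lr = 0.001 plain descent
    cannot reach R on the study problem in any practical epoch budget,
    while momentum descent does (see the methods note).
    """

    learning_rate: float = 0.001
    target_error: float = 0.001
    max_epochs: int = 200_000
    momentum: float = 0.9
    output_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.target_error <= 0:
            raise ValueError("target_error must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValueError("output_activation must be sigmoid or linear")


def sigmoid(x):
    """Logistic activation ``1 / (1 + exp(-x))``, saturating, in (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def init_params(topology: NetworkTopology, rng: np.random.Generator,
                bound: float = 1.0) -> NetworkParams:
    """Uniform random parameters in (-bound, bound)."""
    t = topology
    return NetworkParams(
        v1=rng.uniform(-bound, bound, (t.n_in, t.n_hidden)),
        b1=rng.uniform(-bound, bound, t.n_hidden),
        w2=rng.uniform(-bound, bound, (t.n_hidden, t.n_out)),
        b2=rng.uniform(-bound, bound, t.n_out),
    )


def _forward_full(params: NetworkParams, X: np.ndarray,
                  output_activation: str):
    u = sigmoid(X @ params.v1 + params.b1)
    z = u @ params.w2 + params.b2
    yhat = sigmoid(z) if output_activation == "sigmoid" else z
    return u, z, yhat


def forward(params: NetworkParams, x, output_activation: str = "sigmoid"
            ) -> np.ndarray:
    """Network output for one input vector or a (n, n_in) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.v1.shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.v1.shape[0]}")
    _, _, yhat = _forward_full(params, X, output_activation)
    return yhat[0] if single else yhat


def error_E(params: NetworkParams, X, y,
            output_activation: str = "sigmoid") -> float:
    """Squared-error objective ``E = 1/2 sum ||y - yhat||^2``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    _, _, yhat = _forward_full(params, X, output_activation)
    return 0.5 * float(np.sum((y - yhat) ** 2))


def gradients(params: NetworkParams, X, y,
              output_activation: str = "sigmoid") -> NetworkParams:
    """Analytic gradient of E with respect to every parameter."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
    u, z, yhat = _forward_full(params, X, output_activation)
    d = yhat - y
    if output_activation == "sigmoid":
        d = d * yhat * (1.0 - yhat)
    g_w2 = u.T @ d
    g_b2 = d.sum(axis=0)
    du = (d @ params.w2.T) * u * (1.0 - u)
    g_v1 = X.T @ du
    g_b1 = du.sum(axis=0)
    return NetworkParams(g_v1, g_b1, g_w2, g_b2)


def train_bp(params_init: NetworkParams, X, y, config: TrainConfig,
             record_every: int = 100) -> tuple[NetworkParams, list[float]]:
    """Full-batch gradient descent with optional momentum and early stop.

    Stops when ``E < target_error`` or after ``max_epochs``.  Returns the
    trained parameters and the error history (epoch 0 plus every
    ``record_every``-th epoch and the final one).  Raises
    :class:`TrainingDivergence` if E becomes non-finite.  Deterministic for
    a fixed initialization and config.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
    act = config.output_activation
    sig_out = act == "sigmoid"
    lr, mom = config.learning_rate, config.momentum
    v1, b1 = params_init.v1.copy(), params_init.b1.copy()
    w2, b2 = params_init.w2.copy(), params_init.b2.copy()
    mv1, mb1 = np.zeros_like(v1), np.zeros_like(b1)
    mw2, mb2 = np.zeros_like(w2), np.zeros_like(b2)

    # one fused forward+backward per epoch; the loop is the hot path
    def _forward():
        u = sigmoid(X @ v1 + b1)
        z = u @ w2 + b2
        yhat = sigmoid(z) if sig_out else z
        return u, yhat

    u, yhat = _forward()
    resid = yhat - y
    e = 0.5 * float(np.sum(resid ** 2))
    history = [e]
    if e < config.target_error:
        return NetworkParams(v1, b1, w2, b2), history
    for epoch in range(1, config.max_epochs + 1):
        d = resid * yhat * (1.0 - yhat) if sig_out else resid
        du = (d @ w2.T) * u * (1.0 - u)
        mw2 = mom * mw2 - lr * (u.T @ d)
        mb2 = mom * mb2 - lr * d.sum(axis=0)
        mv1 = mom * mv1 - lr * (X.T @ du)
        mb1 = mom * mb1 - lr * du.sum(axis=0)
        v1 += mv1
        b1 += mb1
        w2 += mw2
        b2 += mb2
        u, yhat = _forward()
        resid = yhat - y
        e = 0.5 * float(np.sum(resid ** 2))
        if not np.isfinite(e):
            raise TrainingDivergence(epoch)
        if epoch % record_every == 0:
            history.append(e)
        if e < config.target_error:
            break
    if history[-1] != e:
        history.append(e)
    return NetworkParams(v1, b1, w2, b2), history


class BPRegressor(RegressorMixin, BaseEstimator):
    """Backpropagation network regressor in scikit-learn style.

    A 17-6-1-shaped multilayer perceptron (hidden size configurable) with
    sigmoid hidden units, trained by full-batch gradient descent on
    ``E = 1/2 sum (y - yhat)^2`` with early stop at ``target_error``.
    Inputs are min-max scaled to [0, 1] and targets to
    ``[y_margin, 1 - y_margin]`` inside :meth:`fit`; predictions are
    returned on the original target scale.

    Parameters follow the study protocol: ``learning_rate=0.001``,
    ``target_error=0.001``, six hidden units, uniform (-1, 1) random
    initialization.
    """

    def __init__(self, n_hidden: int = 6, learning_rate: float = 0.001,
                 target_error: float = 0.001, max_epochs: int = 200_000,
                 momentum: float = 0.9, output_activation: str = "sigmoid",
                 y_margin: float = 0.1, init_bound: float = 1.0,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.target_error = target_error
        self.max_epochs = max_epochs
        self.momentum = momentum
        self.output_activation = output_activation
        self.y_margin = y_margin
        self.init_bound = init_bound
        self.random_state = random_state

    # -- scaling -----------------------------------------------------------
    def _scale_X(self, X: np.ndarray) -> np.ndarray:
        rng_ = self.x_max_ - self.x_min_
        rng_ = np.where(rng_ == 0, 1.0, rng_)
        return (X - self.x_min_) / rng_

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        span = self.y_max_ - self.y_min_
        if span == 0:
            return np.full_like(y, 0.5)
        lo, hi = self.y_margin, 1.0 - self.y_margin
        return lo + (y - self.y_min_) * (hi - lo) / span

    def _unscale_y(self, t: np.ndarray) -> np.ndarray:
        span = self.y_max_ - self.y_min_
        lo, hi = self.y_margin, 1.0 - self.y_margin
        return self.y_min_ + (t - lo) * span / (hi - lo)

    # -- hooks for the GA-initialized subclass ----------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           target_error=self.target_error,
                           max_epochs=self.max_epochs,
                           momentum=self.momentum,
                           output_activation=self.output_activation)

    def _initial_params(self, topology: NetworkTopology, Xs, ys,
                        rng: np.random.Generator) -> NetworkParams:
        return init_params(topology, rng, self.init_bound)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        y = y.astype(float)
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        self.y_min_ = float(y.min())
        self.y_max_ = float(y.max())
        Xs = self._scale_X(X)
        ys = self._scale_y(y).reshape(-1, 1)
        topology = NetworkTopology(X.shape[1], self.n_hidden, 1)
        rng = np.random.default_rng(self.random_state)
        p0 = self._initial_params(topology, Xs, ys, rng)
        self.params_, self.error_history_ = train_bp(
            p0, Xs, ys, self._train_config())
        self.final_error_ = self.error_history_[-1]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X)
        Xs = self._scale_X(np.asarray(X, dtype=float))
        t = forward(self.params_, Xs, self.output_activation)
        return self._unscale_y(t[:, 0])
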