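"""Quantity-effect back-propagation network.

A small fully-connected feed-forward network maps min-max-normalized
component contents to a (min-max-normalized) integration-effect value and
is trained by full-batch error back-propagation.  The default training
scheme is batch gradient descent with momentum and an adaptive learning
rate: after each epoch the step is accepted if the training MSE did not
rise by more than 4%, the rate grows by 5% on improvement and shrinks by
30% (with the step rejected and momentum reset) otherwise.  Plain
fixed-rate descent is available via ``momentum=0, adaptive_lr=False``.

Training stops on whichever comes first: the MSE goal, the epoch budget,
a vanishing gradient, or six consecutive rises of the MSE on a held-out
validation split (generalization check).  Validation is sampled every few
epochs with a small relative tolerance so that the damped oscillation the
momentum term produces around loss plateaus does not masquerade as
overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DivergenceError

__all__ = [
    "MinMaxParams",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "split_train_test",
    "TrainTestSplit",
    "QuantityEffectRegressor",
    "train_network",
    "relative_errors",
    "sweep",
    "summarize_sweep",
]


# ---------------------------------------------------------------------------
# min-max normalization: y = (x - MinValue) / (MaxValue - MinValue)


@dataclass(frozen=True)
class MinMaxParams:
    """Per-feature minimum and maximum of the fitting data."""

    min_: np.ndarray
    max_: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Mask of constant features (max == min)."""
        return self.max_ == self.min_


def minmax_fit(X) -> MinMaxParams:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples to fit min-max normalization")
    return MinMaxParams(min_=X.min(axis=0), max_=X.max(axis=0))


def minmax_apply(X, params: MinMaxParams) -> np.ndarray:
    """Map to [0,1] on the fitting range; constant features map to 0.5."""
    X = np.asarray(X, dtype=float)
    span = np.where(params.degenerate, 1.0, params.max_ - params.min_)
    out = (X - params.min_) / span
    if params.degenerate.any():
        out = np.where(params.degenerate, 0.5, out)
    return out


def minmax_invert(Y, params: MinMaxParams) -> np.ndarray:
    """Inverse of :func:`minmax_apply`; constant features return their min."""
    Y = np.asarray(Y, dtype=float)
    span = np.where(params.degenerate, 0.0, params.max_ - params.min_)
    return Y * span + params.min_


# ---------------------------------------------------------------------------
# group split


@dataclass(frozen=True)
class TrainTestSplit:
    train_labels: tuple[str, ...]
    test_labels: tuple[str, ...]


def split_train_test(group_labels, test_labels, strict: bool = False) -> TrainTestSplit:
    """Designate test groups for relative-error reporting.

    In the default (study) mode every group trains the network and the
    named test groups are only singled out for error reporting; ``strict``
    removes the test groups from the training set instead.
    """
    groups = list(group_labels)
    unknown = [t for t in test_labels if t not in groups]
    if unknown:
        raise ValueError(f"unknown test group label(s): {unknown}")
    if strict:
        train = tuple(g for g in groups if g not in set(test_labels))
    else:
        train = tuple(groups)
    return TrainTestSplit(train_labels=train, test_labels=tuple(test_labels))


# ---------------------------------------------------------------------------
# the regressor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class QuantityEffectRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward BP network regressor with built-in min-max scaling.

    Parameters
    ----------
    hidden_layer_sizes : 1-3 hidden layers, default ``(20, 20)``.
    learning_rate : initial step size, default 0.02.
    max_epochs : epoch budget, default 1000.
    mse_goal : stop when the training MSE falls to this value, default 1e-7.
    n_validation_failures : stop after this many consecutive rises of the
        validation MSE (default 6); validation is a seeded random
        ``validation_fraction`` holdout of the training rows, disabled when
        too few rows remain or the fraction is 0.
    validation_tol, validation_interval : a rise only counts when the
        validation MSE exceeds the previous check by more than the relative
        tolerance (default 0.1%), and checks run every
        ``validation_interval`` epochs (default 5) so plateau oscillations
        do not trip the counter.
    momentum, adaptive_lr, lr_increase, lr_decrease, max_mse_increase :
        the adaptive momentum scheme (see module docstring); set
        ``momentum=0, adaptive_lr=False`` for plain gradient descent.
    gradient_tol : stop when the gradient norm falls below this, 1e-10.
    activation : hidden activation, ``"sigmoid"`` (default) or ``"tanh"``;
        the output unit is always linear.
    normalize : min-max normalize X and y internally (default True; the
        inputs are then expected on their raw scale).
    random_state : seeds weight initialization and the validation split.

    Attributes
    ----------
    weights_, biases_ : per-layer weight matrices (fan_in x fan_out) and
        bias vectors.
    loss_curve_ : training MSE per epoch (normalized scale).
    stop_reason_ : ``"goal" | "max_epochs" | "gradient" | "validation"``.
    """

    def __init__(self, hidden_layer_sizes=(20, 20), learning_rate=0.02,
                 max_epochs=1000, mse_goal=1e-7, n_validation_failures=6,
                 validation_fraction=0.15, momentum=0.9, adaptive_lr=True,
                 lr_increase=1.05, lr_decrease=0.7, max_mse_increase=1.04,
                 gradient_tol=1e-10, validation_tol=1e-3, validation_interval=5, activation="sigmoid",
                 normalize=True, random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.mse_goal = mse_goal
        self.n_validation_failures = n_validation_failures
        self.validation_fraction = validation_fraction
        self.momentum = momentum
        self.adaptive_lr = adaptive_lr
        self.lr_increase = lr_increase
        self.lr_decrease = lr_decrease
        self.max_mse_increase = max_mse_increase
        self.gradient_tol = gradient_tol
        self.validation_tol = validation_tol
        self.validation_interval = validation_interval
        self.activation = activation
        self.normalize = normalize
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _act(self, z):
        return _sigmoid(z) if self.activation == "sigmoid" else np.tanh(z)

    def _act_deriv(self, a):
        return a * (1.0 - a) if self.activation == "sigmoid" else 1.0 - a ** 2

    def _forward(self, X, Ws, bs):
        acts = [X]
        a = X
        last = len(Ws) - 1
        for k, (W, b) in enumerate(zip(Ws, bs)):
            z = a @ W + b
            a = z if k == last else self._act(z)
            acts.append(a)
        return acts

    def _gradients(self, acts, y, n):
        err = acts[-1] - y
        delta = 2.0 * err / n
        gWs, gbs = [], []
        for k in range(len(self._Ws) - 1, -1, -1):
            gWs.append(acts[k].T @ delta)
            gbs.append(delta.sum(axis=0))
            if k > 0:
                delta = (delta @ self._Ws[k].T) * self._act_deriv(acts[k])
        return gWs[::-1], gbs[::-1]

    # -- API ----------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x components)")
        y2 = y.reshape(-1, 1) if y.ndim == 1 else y
        if y2.shape[0] != X.shape[0]:
            raise ValueError("X and y sample counts differ")
        hidden = tuple(int(h) for h in np.atleast_1d(self.hidden_layer_sizes))
        if not 1 <= len(hidden) <= 3 or any(h < 1 for h in hidden):
            raise ValueError("hidden_layer_sizes must give 1-3 layers of >= 1 neurons")
        if self.activation not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.max_epochs < 1 or self.learning_rate <= 0:
            raise ValueError("max_epochs must be >= 1 and learning_rate > 0")
        rng = np.random.default_rng(self.random_state)

        if self.normalize:
            self.x_params_ = minmax_fit(X)
            self.y_params_ = minmax_fit(y2)
            Xn = minmax_apply(X, self.x_params_)
            yn = minmax_apply(y2, self.y_params_)
        else:
            self.x_params_ = self.y_params_ = None
            Xn, yn = X, y2

        sizes = (X.shape[1],) + hidden + (y2.shape[1],)
        Ws = [rng.uniform(-0.5, 0.5, (fi, fo)) / np.sqrt(fi)
              for fi, fo in zip(sizes[:-1], sizes[1:])]
        bs = [np.zeros(fo) for fo in sizes[1:]]

        n_all = Xn.shape[0]
        use_val = (self.n_validation_failures is not None
                   and self.validation_fraction > 0
                   and int(round(self.validation_fraction * n_all)) >= 1
                   and n_all - int(round(self.validation_fraction * n_all)) >= 2)
        if use_val:
            nv = int(round(self.validation_fraction * n_all))
            perm = rng.permutation(n_all)
            val_idx, tr_idx = perm[:nv], perm[nv:]
            Xt, yt, Xv, yv = Xn[tr_idx], yn[tr_idx], Xn[val_idx], yn[val_idx]
        else:
            Xt, yt = Xn, yn
            Xv = yv = None

        self._Ws, self._bs = Ws, bs
        n = Xt.shape[0]
        lr = float(self.learning_rate)
        vW = [np.zeros_like(W) for W in Ws]
        vb = [np.zeros_like(b) for b in bs]
        loss, vloss = [], []
        prev_val = np.inf
        fails = 0
        stop = "max_epochs"

        def mse(A, B, Ws, bs):
            return float(np.mean((self._forward(A, Ws, bs)[-1] - B) ** 2))

        perf = mse(Xt, yt, Ws, bs)
        for epoch in range(1, self.max_epochs + 1):
            if not np.isfinite(perf):
                raise DivergenceError(epoch)
            loss.append(perf)
            if perf <= self.mse_goal:
                stop = "goal"
                break
            acts = self._forward(Xt, Ws, bs)
            gWs, gbs = self._gradients(acts, yt, n)
            gnorm = np.sqrt(sum(float(np.sum(g ** 2)) for g in gWs + gbs))
            if gnorm < self.gradient_tol:
                stop = "gradient"
                break
            damp = 1.0 - self.momentum
            vW = [self.momentum * v - damp * lr * g for v, g in zip(vW, gWs)]
            vb = [self.momentum * v - damp * lr * g for v, g in zip(vb, gbs)]
            newWs = [W + v for W, v in zip(Ws, vW)]
            newbs = [b + v for b, v in zip(bs, vb)]
            newperf = mse(Xt, yt, newWs, newbs)
            if self.adaptive_lr and newperf > perf * self.max_mse_increase:
                # reject the step, cool down and clear momentum
                lr *= self.lr_decrease
                vW = [np.zeros_like(W) for W in Ws]
                vb = [np.zeros_like(b) for b in bs]
                continue
            if self.adaptive_lr and newperf < perf:
                lr *= self.lr_increase
            Ws, bs, perf = newWs, newbs, newperf
            self._Ws, self._bs = Ws, bs
            if use_val and epoch % self.validation_interval == 0:
                vperf = mse(Xv, yv, Ws, bs)
                vloss.append(vperf)
                if vperf > prev_val * (1.0 + self.validation_tol):
                    fails += 1        # the validation error rose again
                elif vperf < prev_val:
                    fails = 0         # generalization still improving
                prev_val = vperf
                if fails >= self.n_validation_failures:
                    stop = "validation"
                    break
        self.weights_ = Ws
        self.biases_ = bs
        self.loss_curve_ = loss
        self.validation_curve_ = vloss
        self.stop_reason_ = stop
        self.n_epochs_ = epoch
        self.final_lr_ = lr
        self.n_features_in_ = X.shape[1]
        self.architecture_ = sizes
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if self.normalize:
            X = minmax_apply(X, self.x_params_)
        out = self._forward(X, self.weights_, self.biases_)[-1]
        if self.normalize:
            out = minmax_invert(out, self.y_params_)
        return out.ravel() if out.shape[1] == 1 else out


def train_network(X, y, hidden_layer_sizes=(20, 20), **config) -> QuantityEffectRegressor:
    """Functional wrapper: fit a :class:`QuantityEffectRegressor`."""
    return QuantityEffectRegressor(hidden_layer_sizes=hidden_layer_sizes, **config).fit(X, y)


def relative_errors(net: QuantityEffectRegressor, X, y_true) -> np.ndarray:
    """Signed per-sample relative error ``(predicted - true) / true``.

    Samples with ``true == 0`` have an undefined relative error and are
    returned as NaN.
    """
    pred = np.asarray(net.predict(X), dtype=float)
    true = np.asarray(y_true, dtype=float).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (pred - true) / true
    return np.where(true == 0, np.nan, rel)


# ---------------------------------------------------------------------------
# hyperparameter sweep


def sweep(X, y, grid: list[dict], repeats: int = 5, seed: int = 0,
          test_index=None, **base_config) -> pd.DataFrame:
    """Repeat trainings over a hyperparameter grid.

    ``grid`` is a list of parameter dicts (e.g. ``{"hidden_layer_sizes":
    (20, 20), "learning_rate": 0.02}``); each grid point is trained
    ``repeats`` times with fresh seeds derived from ``seed``, and the
    predicted / true / signed relative-error values of the test samples
    (``test_index``, default: all samples) are recorded one row per
    (grid point, repeat, sample).
    """
    if not grid:
        raise ValueError("empty grid")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    test_index = np.arange(X.shape[0]) if test_index is None else np.asarray(test_index)
    seeds = np.random.SeedSequence(seed).generate_state(len(grid) * repeats) % (2 ** 31)
    rows = []
    si = 0
    for gi, params in enumerate(grid):
        hl = tuple(np.atleast_1d(params.get("hidden_layer_sizes", (20, 20))))
        if len(hl) < 1:
            raise ValueError("grid point with no hidden layer")
        for rep in range(repeats):
            cfg = {**base_config, **params, "random_state": int(seeds[si])}
            si += 1
            net = QuantityEffectRegressor(**cfg).fit(X, y)
            pred = net.predict(X[test_index])
            true = y[test_index]
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(true == 0, np.nan, (pred - true) / true)
            for j, t in enumerate(test_index):
                rows.append({
                    "grid_index": gi,
                    "n_hidden_layers": len(hl),
                    "hidden_layer_sizes": "x".join(str(int(h)) for h in hl),
                    "learning_rate": cfg.get("learning_rate", 0.02),
                    "repeat": rep,
                    "sample": int(t),
                    "predicted": float(pred[j]),
                    "true": float(true[j]),
                    "relative_error": float(rel[j]),
                    "final_mse": net.loss_curve_[-1],
                    "stop_reason": net.stop_reason_,
                })
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of |relative error| per grid point."""
    out = (results.assign(abs_rel=results["relative_error"].abs())
           .groupby(["grid_index", "hidden_layer_sizes", "learning_rate"], sort=True)
           .agg(mean_abs_rel=("abs_rel", "mean"), sd_abs_rel=("abs_rel", "std"),
                mean_final_mse=("final_mse", "mean"), best_final_mse=("final_mse", "min"))
           .reset_index())
    return out
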