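"""Reference learners satisfying the fit/predict contract.

A learner is any object with ``fit(X, y, rng) -> fitted`` where the
fitted object exposes ``predict(X)``.  Fitting must be deterministic
given the supplied ``numpy.random.Generator`` and must not share state
between fits: the test drivers fit one model on the estimation subset
and an independent fresh model on its dual, and correlated fits would
distort the loss differences.

Shipped learners:

``RidgeLearner``
    Closed-form ridge regression with intercept.  Deterministic and
    cheap; consistent on linear designs, which makes it the workhorse
    for the desk-scale Monte-Carlo studies.
``MLPLearner``
    A small single-hidden-layer network (scikit-learn) trained with
    early stopping on a 20% validation split.
``SklearnLearner``
    Adapter cloning any scikit-learn estimator per fit.
``OracleLearner``
    Wraps a known true function; "fitting" is a no-op.  Under a null
    design the same function serves as both f* and g* (it never reads
    the masked columns), which isolates the inference-stage behaviour
    of the test statistics from estimation error.
``SlowOracleLearner``
    The oracle plus a random intercept bias shrinking at a configurable
    slow rate n^(-gamma).  Emulates a learner whose excess risk decays
    too slowly for the splitting condition at a fixed split ratio, the
    regime in which the unperturbed one-split statistic loses Type I
    control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import clone

__all__ = [
    "RidgeLearner",
    "MLPLearner",
    "SklearnLearner",
    "OracleLearner",
    "SlowOracleLearner",
]


class _LinearModel:
    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = coef
        self.intercept = intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


@dataclass(frozen=True)
class RidgeLearner:
    """Closed-form ridge regression: (X'X + lam I)^-1 X'y with intercept."""

    lam: float = 1e-3

    def fit(self, X, y, rng=None) -> _LinearModel:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        mx = X.mean(axis=0)
        my = y.mean()
        Xc = X - mx
        A = Xc.T @ Xc + self.lam * np.eye(X.shape[1])
        coef = np.linalg.solve(A, Xc.T @ (y - my))
        return _LinearModel(coef, my - mx @ coef)


@dataclass(frozen=True)
class SklearnLearner:
    """Clone-per-fit adapter for scikit-learn estimators."""

    estimator: object = None

    def fit(self, X, y, rng=None):
        est = clone(self.estimator)
        if rng is not None and "random_state" in est.get_params():
            est.set_params(random_state=int(rng.integers(2**31 - 1)))
        est.fit(np.asarray(X, dtype=float), np.asarray(y))
        return est


@dataclass(frozen=True)
class MLPLearner:
    """Single-hidden-layer network with early stopping (20% validation)."""

    width: int = 32
    epochs: int = 100
    patience: int = 10

    def fit(self, X, y, rng=None):
        from sklearn.neural_network import MLPRegressor

        seed = 0 if rng is None else int(rng.integers(2**31 - 1))
        est = MLPRegressor(
            hidden_layer_sizes=(self.width,),
            max_iter=self.epochs,
            early_stopping=True,
            validation_fraction=0.2,
            n_iter_no_change=self.patience,
            random_state=seed,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return est


class _FuncModel:
    def __init__(self, func: Callable, bias: float = 0.0):
        self.func = func
        self.bias = bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.func(np.asarray(X, dtype=float))).reshape(-1) + self.bias


@dataclass(frozen=True)
class OracleLearner:
    """Returns a fixed known function regardless of the training data."""

    func: Callable

    def fit(self, X, y, rng=None) -> _FuncModel:
        return _FuncModel(self.func)


@dataclass(frozen=True)
class SlowOracleLearner:
    """Oracle plus a random intercept bias of size c * n^(-gamma).

    Each fit draws an independent intercept

        b = c * n^(-gamma) * sign * magnitude,

    with a fair random sign and magnitude uniform on [0.5, 1.5], so two
    fits (f-role and g-role) disagree by a slowly vanishing random
    offset.  With gamma small the differenced regret decays slower than
    m^(-1/2) at any fixed split ratio, so the bias-to-sd ratio of the
    unperturbed statistic diverges and its Type I error inflates with
    the sample size.  The magnitude is bounded away from zero and
    infinity: every fit carries the drift, while the variance inflation
    of the perturbed statistic -- driven by the fourth moment of b --
    stays negligible, so a unit perturbation restores control.
    """

    func: Callable
    c: float = 0.1
    gamma: float = 0.1

    def fit(self, X, y, rng=None) -> _FuncModel:
        n = np.asarray(X).shape[0]
        scale = self.c * n ** (-self.gamma)
        if rng is not None:
            draw = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5))
        else:
            draw = 1.0
        return _FuncModel(self.func, bias=scale * draw)

    def fit_pair(self, X, y, rng) -> tuple[_FuncModel, _FuncModel]:
        """Correlated (f-role, g-role) fits for one replicate.

        Two models fitted on overlapping data have strongly correlated
        error magnitudes, so the pair shares one magnitude draw up to a
        20% factor while the error signs stay independent.  The shared
        magnitude makes the f/g squared-bias difference -- the term the
        perturbation must dominate -- nearly cancel, while the signed
        bias difference that breaks the unperturbed statistic remains.
        """
        n = np.asarray(X).shape[0]
        scale = self.c * n ** (-self.gamma)
        mag = float(rng.uniform(0.5, 1.5))
        ratio = float(rng.uniform(0.8, 1.2))
        s_f = float(rng.choice([-1.0, 1.0]))
        s_g = float(rng.choice([-1.0, 1.0]))
        return (
            _FuncModel(self.func, bias=scale * s_f * mag),
            _FuncModel(self.func, bias=scale * s_g * mag * ratio),
        )
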