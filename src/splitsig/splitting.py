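"""Estimation/inference sample splitting and data-adaptive tuning.

The validity of the split tests requires the inference size m to grow
slowly relative to the estimation size n (m = o(n^(2*gamma)) where
n^(-gamma) is the learner's convergence rate).  Two schemes are
provided:

* the *log-ratio* scheme, which chooses n as the root of
  x + c*ln(x) = N with c = N0 / (2 ln(N0/2)), so that m grows only
  logarithmically in n and the splitting condition holds for any
  gamma > 0;
* a permutation-based *data-adaptive* scheme that picks the smallest
  split ratio zeta and perturbation size rho whose estimated Type I
  error, measured by re-evaluating the fitted models on permuted
  inference subsets, is controlled at the nominal level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dualdata import Dataset, FeatureSet, LossSpec, make_dual, per_sample_loss, permute_features

__all__ = [
    "SplitPlan",
    "TuneConfig",
    "log_ratio_sizes",
    "split",
    "estimate_type1",
    "adaptive_tune",
]

logger = logging.getLogger(__name__)


class InsufficientSampleError(ValueError):
    """Total sample size below the minimal size N0 of the scheme."""


@dataclass(frozen=True)
class SplitPlan:
    """A realized estimation/inference partition."""

    n: int
    m: int
    zeta: float | str
    N0: int | None
    estimation_rows: tuple[int, ...]
    inference_rows: tuple[int, ...]

    def __post_init__(self):
        if self.n < 1 or self.m < 2:
            raise ValueError("need n >= 1 and m >= 2")
        if self.n != len(self.estimation_rows) or self.m != len(self.inference_rows):
            raise ValueError("row lists inconsistent with sizes")
        if set(self.estimation_rows) & set(self.inference_rows):
            raise ValueError("row lists must be disjoint")


@dataclass(frozen=True)
class TuneConfig:
    """Grids and permutation count for the data-adaptive scheme."""

    zeta_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    rho_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 1.0)
    T: int = 100
    alpha: float = 0.05

    def __post_init__(self):
        for g, lo, hi in ((self.zeta_grid, 0.0, 1.0), (self.rho_grid, 0.0, np.inf)):
            if not g or list(g) != sorted(g) or len(set(g)) != len(g):
                raise ValueError("grids must be nonempty and strictly ascending")
            if not all(lo < v < hi for v in g):
                raise ValueError("grid values out of range")
        if self.T < 20:
            raise ValueError("T must be at least 20")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


def log_ratio_sizes(N: int, N0: int = 1000) -> tuple[int, int]:
    """Estimation/inference sizes (n, m) from the log-ratio scheme.

    n = ceil(x0) where x0 solves x + c*ln(x) = N with
    c = N0 / (2 ln(N0/2)); m = N - n.  Logarithms are natural.  The
    left side is strictly increasing in x so the root is unique; it is
    bracketed on [1, N] and found to absolute tolerance 1e-9.
    """
    if N0 < 4:
        raise ValueError("N0 must be at least 4")
    if N < N0:
        raise InsufficientSampleError(f"N={N} below the minimal sample size N0={N0}")
    c = N0 / (2.0 * math.log(N0 / 2.0))
    x0 = brentq(lambda x: x + c * math.log(x) - N, 1.0, float(N), xtol=1e-9)
    # snap to integer before the ceiling: at N = N0 the root is exactly N0/2
    if abs(x0 - round(x0)) < 1e-6:
        n = int(round(x0))
    else:
        n = int(math.ceil(x0))
    return n, N - n


def _stratified_rows(y: np.ndarray, n: int, rng: np.random.Generator):
    """Per-class allocation of n estimation rows by largest remainder."""
    N = y.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    exact = counts * n / N
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:short]] += 1
    est = []
    for cls, take in zip(classes, base):
        rows = np.flatnonzero(y == cls)
        rng.shuffle(rows)
        est.extend(rows[:take])
    est = np.array(sorted(est))
    mask = np.ones(N, dtype=bool)
    mask[est] = False
    return est, np.flatnonzero(mask)


def split(
    data: Dataset,
    n: int,
    m: int,
    rng: np.random.Generator,
    stratify: bool = False,
    N0: int | None = None,
    zeta: float | str | None = None,
) -> tuple[Dataset, Dataset, SplitPlan]:
    """Uniform random disjoint partition into estimation and inference sets."""
    N = data.n_samples
    if n + m != N:
        raise ValueError(f"n + m = {n + m} must equal N = {N}")
    if stratify and data.outcome.dtype.kind in "iub":
        est_rows, inf_rows = _stratified_rows(data.outcome, n, rng)
    else:
        perm = rng.permutation(N)
        est_rows, inf_rows = np.sort(perm[:n]), np.sort(perm[n:])
    plan = SplitPlan(
        n=n,
        m=m,
        zeta=zeta if zeta is not None else n / N,
        N0=N0,
        estimation_rows=tuple(int(i) for i in est_rows),
        inference_rows=tuple(int(i) for i in inf_rows),
    )
    return data.take(est_rows), data.take(inf_rows), plan


def estimate_type1(
    fitted_f,
    fitted_g,
    inference: Dataset,
    fs: FeatureSet,
    rho: float,
    T: int,
    alpha: float,
    test_kind: str = "one_split",
    rng=None,
    loss: LossSpec = LossSpec(),
) -> float:
    """Permutation estimate of the Type I error for fixed fitted models.

    The hypothesized columns of the inference subset are permuted T
    times; each permuted set satisfies the null by construction, and the
    rejection fraction of the test p-values estimates the Type I error.
    The masked (dual) losses are permutation-invariant, so g_hat is
    evaluated once.  A permutation whose statistic degenerates counts as
    a rejection, which is conservative for the tuning scheme.
    """
    from .inference import (
        DegenerateVarianceError,
        one_split_statistic,
        two_split_statistic,
    )

    if T < 1:
        raise ValueError("T must be at least 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dual = make_dual(inference, fs)
    loss_g = per_sample_loss(fitted_g.predict(dual.features), dual.outcome, loss)
    m = inference.n_samples
    rejections = 0
    for _ in range(T):
        perm = permute_features(inference, fs, rng)
        loss_f = per_sample_loss(fitted_f.predict(perm.features), perm.outcome, loss)
        try:
            if test_kind == "one_split":
                _, p, _ = one_split_statistic(loss_f, loss_g, rho, rng)
            elif test_kind == "two_split":
                order = rng.permutation(m)
                _, p = two_split_statistic(
                    loss_f[order[: m // 2]], loss_g[order[m // 2 :]]
                )
            else:
                raise ValueError(f"unknown test_kind {test_kind!r}")
        except DegenerateVarianceError:
            rejections += 1
            continue
        if p <= alpha:
            rejections += 1
    return rejections / T


def adaptive_tune(
    data: Dataset,
    fs: FeatureSet,
    learner,
    loss: LossSpec = LossSpec(),
    cfg: TuneConfig = TuneConfig(),
    test_kind: str = "one_split",
    rng=None,
) -> tuple[float, float, dict]:
    """Select the smallest (zeta, rho) controlling the permutation Type I.

    Iterates zeta ascending (outer loop; each zeta costs one pair of
    model fits) and rho ascending (inner loop; re-evaluation only).  For
    each zeta the hypothesized columns of the estimation subset are
    permuted once, the models are fitted on that permuted subset and its
    dual, and the permutation Type I estimate is computed for each rho.
    Returns the first pair with estimated error <= alpha; if no grid
    point passes, returns the largest pair with a warning (the largest
    estimation set minimizes the estimation bias carried into the
    statistic).  For the two-split test the rho loop collapses to a
    single rho = 0 evaluation, as no perturbation is used.
    """
    fs.validate(data, allow_empty=False)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    N = data.n_samples
    rho_grid = (0.0,) if test_kind == "two_split" else cfg.rho_grid
    err_grid: dict[tuple[float, float], float] = {}
    fits = 0
    for zeta in cfg.zeta_grid:
        n = int(np.floor(zeta * N))
        m = N - n
        est, inf, _ = split(data, n, m, rng, zeta=zeta)
        perm_est = permute_features(est, fs, rng)
        dual_est = make_dual(perm_est, fs)
        f_hat = learner.fit(
            perm_est.features, perm_est.outcome, np.random.default_rng(rng.integers(2**31 - 1))
        )
        g_hat = learner.fit(
            dual_est.features, dual_est.outcome, np.random.default_rng(rng.integers(2**31 - 1))
        )
        fits += 1
        for rho in rho_grid:
            err = estimate_type1(
                f_hat, g_hat, inf, fs, rho, cfg.T, cfg.alpha, test_kind, rng, loss
            )
            err_grid[(zeta, rho)] = err
            if err <= cfg.alpha:
                diag = {"err_grid": err_grid, "model_fits": fits, "fallback": False}
                return zeta, rho, diag
    logger.warning(
        "adaptive tuning: no (zeta, rho) grid point controlled the permutation "
        "Type I estimate at alpha=%.3g; falling back to the largest pair",
        cfg.alpha,
    )
    diag = {"err_grid": err_grid, "model_fits": fits, "fallback": True}
    return cfg.zeta_grid[-1], rho_grid[-1], diag
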