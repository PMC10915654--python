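"""Synthetic designs and a Monte-Carlo Type I/II error harness.

Every study in this package runs on generated data, so each design is
first-class, seeded and bit-reproducible:

* a nonparametric regression truth given by a random ReLU network whose
  first-layer columns for the nondiscriminative set S0 are zeroed, so
  the null holds exactly for S = S0 (``gen_relu_truth`` +
  ``gen_regression_data``, AR(1)-correlated Gaussian features);
* a small linear benchmark with correlated uniform features,
  Y = 0.02 (X1 + X2 + X3) + 0.05 eps (``gen_linear_example``);
* a partially observed design with star-shaped feature covariance in
  which only the first d_N = floor(d (1 - 1/ln N)) columns are recorded
  (``gen_partial_feature_data``) -- the regime used to study the
  unperturbed statistic's loss of Type I control;
* ``hf_sets``, the four canonical hypothesized sets (one null, three
  alternatives at increasing distance from S0);
* ``error_rates``, the rejection-rate harness with per-replicate seed
  derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dualdata import Dataset, FeatureSet

__all__ = [
    "SimConfig",
    "ReluTruth",
    "gen_relu_truth",
    "gen_regression_data",
    "hf_sets",
    "gen_linear_example",
    "gen_partial_feature_data",
    "local_alternative_loss_pair",
    "error_rates",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the ReLU-truth regression design.

    ``B`` scales the feature covariance, ``r`` the AR(1) correlation
    r^|i-j|, ``s0_size`` the size of the nondiscriminative set
    S0 = {first s0_size columns}, (``L``, ``width``, ``tau``) the truth
    network's depth, hidden width and column-norm scale.
    """

    N: int = 2000
    d: int = 100
    B: float = 0.4
    r: float = 0.25
    s0_size: int = 5
    L: int = 3
    width: int = 128
    tau: float = 2.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if not 0 <= self.r < 1:
            raise ValueError("r must be in [0,1)")
        if self.B <= 0 or self.tau <= 0:
            raise ValueError("B and tau must be positive")
        if not (1 <= self.s0_size <= self.d and self.L >= 1 and self.width >= 1):
            raise ValueError("inconsistent dimensions")


class ReluTruth:
    """f*(x) = A(W_L A(W_{L-1} ... A(W_1 x))), A = ReLU, no biases.

    Each column of W_l is a uniform random direction scaled to Euclidean
    norm tau / sqrt(d_{l-1}); the first-layer columns indexed by S0 are
    zeroed afterwards, so f* never reads x_{S0} and the null holds
    exactly for any hypothesized set inside S0.
    """

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        dims = [cfg.d] + [cfg.width] * (cfg.L - 1) + [1]
        self.weights = []
        for l in range(cfg.L):
            d_in, d_out = dims[l], dims[l + 1]
            W = rng.standard_normal((d_out, d_in))
            W /= np.linalg.norm(W, axis=0, keepdims=True)
            W *= cfg.tau / math.sqrt(d_in)
            if l == 0:
                W[:, : cfg.s0_size] = 0.0
            self.weights.append(W)
        self.s0_size = cfg.s0_size

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        H = X[None, :] if single else X
        for W in self.weights:
            H = np.maximum(H @ W.T, 0.0)
        out = H[:, 0]
        return float(out[0]) if single else out


def gen_relu_truth(cfg: SimConfig, rng) -> ReluTruth:
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return ReluTruth(cfg, rng)


def _ar1_features(N: int, d: int, B: float, r: float, rng: np.random.Generator) -> np.ndarray:
    """X ~ N(0, B * Sigma), Sigma_ij = r^|i-j|, via the AR(1) recursion."""
    X = np.empty((N, d))
    X[:, 0] = rng.standard_normal(N)
    scale = math.sqrt(1.0 - r * r)
    for j in range(1, d):
        X[:, j] = r * X[:, j - 1] + scale * rng.standard_normal(N)
    return X * math.sqrt(B)


def gen_regression_data(cfg: SimConfig, truth: Callable, rng) -> Dataset:
    """Y = f*(X) + noise, X ~ N(0, B Sigma) with AR(1) correlation."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = _ar1_features(cfg.N, cfg.d, cfg.B, cfg.r, rng)
    y = np.asarray(truth(X), dtype=float) + cfg.noise_sd * rng.standard_normal(cfg.N)
    return Dataset(X, y)


def hf_sets(s0_size: int, p: int, mask_value: float = 0.0) -> dict[str, FeatureSet]:
    """The four canonical hypothesized sets (printed 1-based, inclusive).

    (i)   {1, ..., |S0|}                      -- equal to S0: pure null;
    (ii)  {floor(|S0|/2), ..., floor(|S0|/2)+|S0|}   -- half overlap;
    (iii) {floor(p/2), ..., floor(p/2)+|S0|}  -- middle of the feature axis;
    (iv)  {p-|S0|, ..., p}                    -- far end.
    Converted to 0-based indices at this boundary.
    """
    s = s0_size

    def rng1(a: int, b: int) -> FeatureSet:
        if not (1 <= a <= b <= p):
            raise ValueError("hypothesized range out of 1..p")
        return FeatureSet(tuple(range(a - 1, b)), mask_value)

    return {
        "i": rng1(1, s),
        "ii": rng1(s // 2, s // 2 + s),
        "iii": rng1(p // 2, p // 2 + s),
        "iv": rng1(p - s, p),
    }


def gen_linear_example(N: int, rng) -> Dataset:
    """Five correlated uniform features, Y = 0.02 (X1+X2+X3) + 0.05 eps.

    Features are uniform on [-1, 1] with pairwise correlation 0.5^|i-j|
    induced by a Gaussian copula (the correlation is matched on the
    latent Gaussian scale).
    """
    from scipy.stats import norm as _norm

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = 5
    Z = _ar1_features(N, d, 1.0, 0.5, rng)
    X = 2.0 * _norm.cdf(Z) - 1.0
    y = 0.02 * (X[:, 0] + X[:, 1] + X[:, 2]) + 0.05 * rng.standard_normal(N)
    return Dataset(X, y)


def partial_feature_dim(d: int, N: int) -> int:
    """d_N = floor(d * (1 - 1/ln N)): the number of observed columns."""
    if N < 3:
        raise ValueError("N must be at least 3 so that ln N > 1")
    return int(math.floor(d * (1.0 - 1.0 / math.log(N))))


def gen_partial_feature_data(
    N: int, d: int, B: float, truth: Callable, rng, noise_sd: float = 1.0
) -> Dataset:
    """Partially observed design with star-shaped feature covariance.

    The latent X is N(0, B*Sigma) with unit diagonal, Sigma_1j = 0.1 for
    all j and zero elsewhere.  Only the first d_N columns are observed;
    the outcome is computed from the zero-padded observed vector, so the
    null S = S0 holds exactly on the observed data.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Sigma = np.eye(d)
    Sigma[0, 1:] = 0.1
    Sigma[1:, 0] = 0.1
    Lc = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((N, d)) @ Lc.T * math.sqrt(B)
    d_N = partial_feature_dim(d, N)
    X_tilde = np.zeros_like(X)
    X_tilde[:, :d_N] = X[:, :d_N]
    y = np.asarray(truth(X_tilde), dtype=float) + noise_sd * rng.standard_normal(N)
    return Dataset(X[:, :d_N], y)


def local_alternative_loss_pair(
    m: int, delta: float, sigma1: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample loss pair whose difference is N(-delta/sqrt(m), sigma1^2).

    An idealized inference subset with no estimation error: the loss
    difference has exactly the local-alternative mean -delta/sqrt(m)
    and limiting standard deviation sigma1, the regime of the limiting
    Type II formulas.  delta = 0 gives the null boundary.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    diff = -delta / math.sqrt(m) + sigma1 * rng.standard_normal(m)
    return diff, np.zeros(m)


def error_rates(
    design: Callable[[np.random.Generator], Dataset],
    test: Callable[[Dataset, np.random.Generator], float],
    reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
    under: str = "H0",
) -> tuple[float, float]:
    """Monte-Carlo rejection rate and its binomial standard error.

    ``design`` regenerates a dataset from a per-replicate generator;
    ``test`` returns the p-value.  Replicate r uses the r-th spawn of a
    single seed sequence, so runs are reproducible and order-independent.
    A replicate that raises is counted as a rejection under H0 and as a
    non-rejection under Ha (conservative in both directions).
    """
    if reps < 10:
        raise ValueError("reps must be at least 10")
    if under not in ("H0", "Ha"):
        raise ValueError("under must be 'H0' or 'Ha'")
    children = np.random.SeedSequence(seed).spawn(reps)
    rejections = 0
    for ss in children:
        rng = np.random.default_rng(ss)
        try:
            data = design(rng)
            p = test(data, rng)
        except Exception:
            rejections += 1 if under == "H0" else 0
            continue
        if p <= alpha:
            rejections += 1
    rate = rejections / reps
    return rate, math.sqrt(max(rate * (1.0 - rate), 1e-12) / reps)
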