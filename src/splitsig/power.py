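"""Limiting Type II error of the one-split test and its combined versions.

Under the local alternative Ha: R(f*) - R_S(g*) = -delta / sqrt(m), the
one-split test has limiting Type II error

    beta(delta) = Phi(z_alpha - delta / sigma1)

with sigma1 the limiting standard deviation of the per-sample loss
difference (perturbation included) and z_alpha = Phi^-1(1 - alpha).

For the combined tests the limiting Type II error is bounded by

    q-order:  min( U * alpha / q * Gamma, 1 )
    Hommel:   min over q of min( C_U * U * alpha / q * Gamma(q), 1 )

where, with h0 = delta / (2 sigma1) and Owen's T function T(h, a),

    Gamma(q) = ((q-1)/(U-q+1)) * (Phi(h0) - Phi(h0)^2 - 2 T(-h0, a))
               + Phi(-h0),     a = sqrt(3)/3.

The constant a = 1/sqrt(3) is the wedge slope (1-r)/sqrt(1-r^2) at
correlation r = 1/2 between two split statistics sharing half their
data; both a and the factor 2 in h0 are exposed as parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

__all__ = [
    "PowerParams",
    "owens_t",
    "limiting_type2_one_split",
    "limiting_type2_combined_bound",
]

_SQRT3_INV = math.sqrt(3.0) / 3.0


def owens_t(h: float, a: float) -> float:
    """Owen's T function by adaptive quadrature of its integral form.

    T(h, a) = (1/2pi) * int_0^a exp(-h^2 (1+x^2)/2) / (1+x^2) dx,
    the probability that a standard bivariate normal falls in the wedge
    between the ray at slope a and the horizontal, beyond height h.
    Satisfies T(h, 0) = 0, T(0, a) = arctan(a)/(2pi), T(-h, a) = T(h, a)
    and T(h, -a) = -T(h, a).
    """
    if a == 0.0:
        return 0.0
    if a < 0.0:
        return -owens_t(h, -a)
    h2 = h * h
    val, _ = quad(
        lambda x: math.exp(-0.5 * h2 * (1.0 + x * x)) / (1.0 + x * x),
        0.0,
        a,
        epsabs=1e-14,
        epsrel=1e-12,
    )
    return val / (2.0 * math.pi)


@dataclass(frozen=True)
class PowerParams:
    """Parameters of the limiting Type II formulas.

    ``delta`` is the local-alternative magnitude (the risk gap is
    -delta/sqrt(m)); ``sigma1`` the limiting standard deviation of the
    perturbed loss difference; ``U`` and ``q`` the combining parameters.
    ``h0_scale`` and ``owen_a`` parameterize the combined-bound
    constants h0 = delta/(h0_scale * sigma1) and the Owen wedge slope.
    """

    delta: float
    sigma1: float
    alpha: float = 0.05
    U: int = 5
    q: int = 3
    h0_scale: float = 2.0
    owen_a: float = _SQRT3_INV

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 1 <= self.q <= self.U:
            raise ValueError("q must be in 1..U")

    @property
    def h0(self) -> float:
        return self.delta / (self.h0_scale * self.sigma1)

    @property
    def z_alpha(self) -> float:
        return float(norm.ppf(1.0 - self.alpha))

    @property
    def C_U(self) -> float:
        return sum(1.0 / q for q in range(1, self.U + 1))


def limiting_type2_one_split(p: PowerParams) -> float:
    """Phi(z_alpha - delta/sigma1): limiting Type II of the one-split test."""
    return float(norm.cdf(p.z_alpha - p.delta / p.sigma1))


def _gamma(p: PowerParams, q: int) -> float:
    h0 = p.h0
    phi_h0 = float(norm.cdf(h0))
    core = phi_h0 - phi_h0**2 - 2.0 * owens_t(-h0, p.owen_a)
    return (q - 1) / (p.U - q + 1) * core + float(norm.cdf(-h0))


def limiting_type2_combined_bound(p: PowerParams, method: str = "hommel") -> float:
    """Upper bound on the limiting Type II error of the combined test."""
    if method == "q_order":
        return float(min(p.U * p.alpha / p.q * _gamma(p, p.q), 1.0))
    if method == "hommel":
        return float(
            min(
                min(p.C_U * p.U * p.alpha / q * _gamma(p, q), 1.0)
                for q in range(1, p.U + 1)
            )
        )
    raise ValueError("method must be 'q_order' or 'hommel'")
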