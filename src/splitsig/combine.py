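"""P-value combination across repeated random splits.

A single random split makes the test outcome depend on the realized
partition.  Repeating the split U times (U is small, typically 3-10,
since each repetition costs two model fits) and aggregating the U
p-values stabilizes the decision.  Two order-statistic rules are
provided for p-values P_(1) <= ... <= P_(U):

    q-order:  min( (U/q) * P_(q), 1 )                 (generalized Bonferroni)
    Hommel:   min( C_U * min_q (U/q) * P_(q), 1 ),    C_U = sum_{q=1}^U 1/q

Both control the asymptotic Type I error at the nominal level under the
same conditions as the single-split test; Hommel is the default since
it is robust to the choice of q while retaining power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dualdata import Dataset, FeatureSet, LossSpec
from .inference import OneSplitConfig, TestResult, one_split_test, two_split_test
from .splitting import TuneConfig, adaptive_tune

__all__ = ["CombineConfig", "q_order_combine", "hommel_combine", "combined_test"]


@dataclass(frozen=True)
class CombineConfig:
    """Number of repeated splits and the combining rule."""

    U: int = 5
    method: str = "hommel"
    q: int | None = None  # order index for q_order; default ceil(U/2)

    def __post_init__(self):
        if self.U < 2:
            raise ValueError("U must be at least 2")
        if self.method not in ("q_order", "hommel"):
            raise ValueError("method must be 'q_order' or 'hommel'")
        q = math.ceil(self.U / 2) if self.q is None else self.q
        if not 1 <= q <= self.U:
            raise ValueError("q must be in 1..U")
        object.__setattr__(self, "q", q)

    @property
    def C_U(self) -> float:
        return sum(1.0 / q for q in range(1, self.U + 1))


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float).reshape(-1)
    if p.size < 1 or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.sort(p)


def q_order_combine(pvals, q: int) -> float:
    """min((U/q) * P_(q), 1) with P_(q) the q-th smallest p-value."""
    p = _check_pvals(pvals)
    U = p.size
    if not 1 <= q <= U:
        raise ValueError(f"q={q} out of range 1..{U}")
    return float(min(U / q * p[q - 1], 1.0))


def hommel_combine(pvals) -> float:
    """min(C_U * min_q (U/q) * P_(q), 1), C_U the harmonic number."""
    p = _check_pvals(pvals)
    U = p.size
    C_U = sum(1.0 / q for q in range(1, U + 1))
    inner = min(U / q * p[q - 1] for q in range(1, U + 1))
    return float(min(C_U * inner, 1.0))


def combined_test(
    data: Dataset,
    fs: FeatureSet,
    learner,
    loss: LossSpec = LossSpec(),
    split="log-ratio",
    cfg: OneSplitConfig = OneSplitConfig(),
    comb: CombineConfig = CombineConfig(),
    test_kind: str = "one_split",
    rng=None,
    N0: int = 1000,
    tune: TuneConfig | None = None,
    seed: int | None = None,
) -> TestResult:
    """Run the chosen single-split test on U independent random splits
    and combine the p-values.

    With ``split="adaptive"`` the pair (zeta, rho) is tuned once by the
    permutation scheme on the first split's data and reused for all U
    splits (re-tuning per split would double the model fits without a
    corresponding gain).  A split that fails with a degenerate statistic
    contributes p = 1, which is conservative.
    """
    from .inference import DegenerateVarianceError

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        seed if rng is None else rng
    )
    warnings: list[str] = []
    zeta_rho: tuple[float, float] | None = None
    if split == "adaptive":
        tune = tune or TuneConfig(alpha=cfg.alpha)
        zeta_hat, rho_hat, diag = adaptive_tune(
            data, fs, learner, loss, tune, test_kind, rng
        )
        if diag["fallback"]:
            warnings.append("adaptive tuning fell back to the largest grid point")
        split = zeta_hat
        cfg = OneSplitConfig(rho=rho_hat, alpha=cfg.alpha)
        zeta_rho = (zeta_hat, rho_hat)
    pvals = []
    last = None
    for u in range(comb.U):
        child = np.random.default_rng(rng.integers(2**31 - 1))
        try:
            if test_kind == "one_split":
                last = one_split_test(
                    data, fs, learner, loss, split, cfg, child, N0=N0
                )
            else:
                last = two_split_test(
                    data, fs, learner, loss, split, cfg.alpha, child, N0=N0
                )
            pvals.append(last.p_value)
        except DegenerateVarianceError:
            warnings.append(f"split {u}: degenerate statistic, p set to 1")
            pvals.append(1.0)
    if comb.method == "q_order":
        p_bar = q_order_combine(pvals, comb.q)
    else:
        p_bar = hommel_combine(pvals)
    return TestResult(
        statistic=float("nan"),
        p_value=p_bar,
        method=f"combined_{test_kind}",
        n=last.n if last else 0,
        m=last.m if last else 0,
        zeta=zeta_rho[0] if zeta_rho else (last.zeta if last else None),
        rho=zeta_rho[1] if zeta_rho else (cfg.rho if test_kind == "one_split" else 0.0),
        seed=seed,
        U=comb.U,
        q=comb.q,
        per_split_pvalues=[float(p) for p in pvals],
        warnings=warnings,
    )
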