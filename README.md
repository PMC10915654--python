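# splitsig — significance tests of feature relevance for black-box learners

`splitsig` answers a question that comes up whenever a flexible predictive
model (a neural network, a gradient-boosted ensemble, any fit/predict
black box) is used on scientific data: **is this set of features actually
relevant to predicting the outcome, at a controlled error rate?**
Typical users are biostatisticians and ML practitioners who need a p-value
for a *group* of features — a gene set, an image region, a block of assay
measurements — without assuming a parametric model or a known feature
distribution.

## The hypothesis and the tests

Let `X ∈ R^d` be the features, `Y` the outcome, `l` a loss, and `S` the
hypothesized feature set. Form the **dual data** `Z` by overwriting the
columns in `S` with a constant `M` (default 0). With

    R(f)   = E[ l(f(X), Y) ],      f* = argmin R(f)
    R_S(g) = E[ l(g(Z), Y) ],      g* = argmin R_S(g)

the null hypothesis is **risk invariance**:

    H0: R(f*) − R_S(g*) = 0     vs.     Ha: R(f*) − R_S(g*) < 0.

Conditional independence `Y ⊥ X_S | X_{S^c}` implies H0 for any loss, and
under cross-entropy the two are equivalent (the package ships an exact
finite-support oracle, `risk_difference_oracle`, that verifies both
directions by enumeration).

**One-split test.** Split the N samples into an estimation subset (size
n) and an inference subset (size m). Fit `f̂` on the estimation subset
and `ĝ` on its dual, with any learner meeting the fit/predict contract.
On the inference subset compute the perturbed loss differences

    Δ_j = l(f̂(x_j), y_j) − l(ĝ(z_j), y_j) + ρ ε_j,   ε_j ~ N(0,1),

and the statistic `Λ = Σ_j Δ_j / (√m σ̂)`, with p-value `Φ(Λ)`. The
perturbation `ρ > 0` keeps `σ̂` bounded away from zero under H0, where
the raw differences degenerate and the bias-to-sd ratio otherwise
destroys the normal null limit.

**Two-split test.** Halve the inference subset, score `f̂` on one half
and `ĝ` on the duals of the other, and use a Welch-normalized unpaired
difference — no perturbation needed.

**Splitting schemes.** `log_ratio_sizes` solves
`x + (N0 / (2 ln(N0/2))) ln x = N` and takes `n = ⌈x0⌉`, so m grows only
logarithmically and the splitting condition `m = o(n^{2γ})` holds for any
learner rate γ > 0. `adaptive_tune` instead picks the smallest `(ζ, ρ)`
from a grid whose permutation-estimated Type I error is ≤ α.

**Combining.** `combined_test` repeats the split U times and aggregates
p-values with the q-order rule `min((U/q) P_(q), 1)` or Hommel's rule
`min(C_U · min_q (U/q) P_(q), 1)`, `C_U = Σ 1/q`.

**Power.** `limiting_type2_one_split` evaluates the limiting Type II
error `Φ(z_α − δ/σ^(1))` under the local alternative
`R(f*) − R_S(g*) = −δ/√m`, and `limiting_type2_combined_bound` the
tail bound for the combined tests (via Owen's T function, implemented by
quadrature).

## Worked example

```python
import numpy as np
from splitsig import (FeatureSet, LossSpec, OneSplitConfig, CombineConfig,
                      one_split_test, combined_test)
from splitsig.learners import RidgeLearner
from splitsig.simulate import gen_linear_example

# benchmark: 5 correlated uniform features, Y = 0.02 (X1+X2+X3) + 0.05 eps
data = gen_linear_example(1000, np.random.default_rng(42))
ridge = RidgeLearner()
cfg = OneSplitConfig(rho=0.005)   # perturbation sized to the loss scale

signal = one_split_test(data, FeatureSet((0, 1, 2)), ridge, LossSpec(),
                        split=0.2, cfg=cfg, rng=np.random.default_rng(7))
null = one_split_test(data, FeatureSet((3, 4)), ridge, LossSpec(),
                      split=0.2, cfg=cfg, rng=np.random.default_rng(7))
print(signal.statistic, signal.p_value)   # -2.7039  0.00343
print(null.p_value)                       #  0.53658

comb = combined_test(data, FeatureSet((0, 1, 2)), ridge, LossSpec(), 0.2,
                     cfg, CombineConfig(U=5), "one_split",
                     np.random.default_rng(7))
print(comb.p_value)                       #  0.00571
```

Masking the true signal columns {1,2,3} raises the achievable loss, the
mean loss difference goes negative, and the left-tail p-value 0.0034
rejects H0; the irrelevant set {4,5} gives p = 0.54. The Hommel-combined
test over five random splits stabilizes the decision (p = 0.0057).

The same pipeline is available from the shell:

```bash
splitsig test --data data.csv --outcome y --features 1-3 \
              --learner ridge --split fixed:0.2 --rho 0.005 --seed 7
splitsig power --sigma1 1.0 -U 5 -q 3          # limiting Type II table
splitsig simulate configs/example1_sample_size.json --seed 1 --out ledger.tsv
```

Feature ranges on the command line are 1-based inclusive; image regions
("rows 2:4, cols 0:3" with `--grid 5x5`) are 0-based half-open,
row-major. `configs/` holds full-scale Monte-Carlo experiment configs
(1000 null / 100 alternative replicates with neural learners); the test
suite asserts the same designs at desk scale.

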