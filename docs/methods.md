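# Methods

This note records the statistical model behind `splitsig`, the numerical
and design choices that were genuinely open, what the synthetic designs
do and do not emulate, and the known limitations.

## Model and assumptions

The object under test is the population risk gap
`R(f*) − R_S(g*)`, where `g*` is the best predictor allowed to see only
the dual data (hypothesized columns replaced by the constant `M`).
Everything rests on three conditions:

1. **Estimation consistency.** The learner's differenced regret
   `R(f̂_n) − R(f*) − (R_S(ĝ_n) − R_S(g*))` vanishes at some rate
   `n^{−γ}`, γ > 0. This is the user's responsibility; the package
   cannot verify it and does not try. Over-parameterized learners slow γ;
   under-parameterized learners can break the assumption outright
   (their approximation error never vanishes), which shows up as Type I
   inflation.
2. **A Lyapunov and a variance condition** on the perturbed loss
   differences, which hold automatically when ρ > 0 because the
   perturbation contributes a fixed `ρ²` to the limiting variance.
3. **The splitting condition** `m = o(n^{2γ})`. Under it the bias term
   `√m · O(n^{−γ}) / σ̂` vanishes and `Λ → N(0,1)` under H0.

Why perturbation matters: with ρ = 0 and a consistent learner, the raw
loss differences collapse toward zero under H0, so both the numerator
and `σ̂` vanish and their ratio is driven by the difference of the two
fits' errors — a quantity with random sign whose scale grows like
`√m · n^{−γ}`. The left tail then exceeds α and worsens with N. The
package treats ρ = 0 strictly as an ablation (`OneSplitConfig` documents
this).

**Perturbation scale.** ρ competes with the per-sample loss differences,
so it must be commensurate with the loss scale. The default grid
{0.01, 0.05, 0.1, 0.5, 1} assumes O(1) losses (e.g. unit-variance
regression noise). On designs with tiny losses — the shipped linear
benchmark has outcome noise 0.05 and loss-difference sd ≈ 3·10⁻³ —
even ρ = 0.01 dominates the signal and costs power; choose ρ a fraction
of the unperturbed loss-difference sd in such cases. Power is monotone
decreasing in ρ; Type I control only needs ρ > 0 with the splitting
condition.

## Splitting schemes

`log_ratio_sizes(N, N0)` solves `x + c ln x = N`, `c = N0/(2 ln(N0/2))`,
by bracketed root-finding (absolute tolerance 1e−9; the left side is
strictly increasing so the root is unique) and returns `n = ⌈x0⌉`,
`m = N − n`. Logarithms are natural — base 10 fails to reproduce the
scheme's published size table, which the test suite pins exactly. At
`N = N0` the root is exactly `N0/2`; a near-integer snap (1e−6) before
the ceiling guards against the floating-point root landing a hair above
the integer. The default minimal size is `N0 = 1000`, configurable;
`N0 = 2000` matches the published size table.

The data-adaptive scheme estimates the Type I error of a candidate
`(ζ, ρ)` by permuting the hypothesized columns of the inference subset
T = 100 times (jointly, with a single permutation shared by all columns
of S, which preserves within-S dependence while breaking the link to
outcome and remaining features) and re-evaluating the fixed fitted pair.
Loop order is ζ-outer / ρ-inner, both ascending, stopping at the first
pair with estimated error ≤ α: the smallest ζ maximizes the inference
set (power), the smallest ρ minimizes variance inflation, and ζ-outer
minimizes model fits, the expensive step. The estimation subset is
permuted once per ζ, not refreshed per ρ. If nothing passes, the
largest pair is returned with a warning — the largest estimation set
minimizes the bias carried into the statistic. Permutations whose
statistic degenerates count as rejections (conservative). T = 100
resolves the error estimate to 0.01 at the default α = 0.05.

## Two-split statistic

The inference subset is halved at random (the rows are exchangeable, so
random halving is as valid as deterministic and is recorded via the
seed); `f̂` is scored on one half, `ĝ` on the duals of the other, and
the statistic is the Welch-normalized unpaired mean difference
(unpooled variances — valid without an equal-variance assumption).
These two choices are isolated in `two_split_statistic`.

## Combining

q-order and Hommel rules operate on the U per-split p-values; the
default is Hommel with `q = ⌈U/2⌉` for the q-order rule (the median
order statistic; the choice is configurable, nothing in the theory fixes
it). With the adaptive scheme, `(ζ̂, ρ̂)` is tuned once on the first
split and reused — re-tuning per split would double the training cost
for no guarantee. A split that fails contributes p = 1 (conservative).
Bonferroni and Cauchy combination are deliberately not shipped: both
fail Type I control in this setting; the combiner interface is pluggable
if a user wants them anyway.

## Limiting power formulas

`Φ(z_α − δ/σ^(1))` is the limiting Type II error of the one-split test
under the local alternative `−δ/√m`. The combined-test bound uses
`Γ(q) = ((q−1)/(U−q+1))(Φ(h0) − Φ(h0)² − 2T(−h0, a)) + Φ(−h0)` with
`h0 = δ/(2σ^(1))` and `a = √3/3`. Two constants here were genuinely
ambiguous and are exposed as parameters (`h0_scale`, `owen_a`): the
package reads `a` as `(1−r)/√(1−r²)` at correlation `r = 1/2` between
two split statistics sharing half their data (which gives exactly
`1/√3`), and the factor 2 in `h0` as the matching half-weight of the
shared local mean. Note `Φ(h)−Φ(h)²−2T(−h,a)` equals the covariance-type
term `Φ₂(h,h;1/2) − Φ(h)²` of the bivariate normal, which is how the
quadrature is cross-checked in the tests.

The combined bound is a **tail bound**: at δ = 0 it is far below the
true Type II error (which approaches 1 − α), and simulations with
correlation-1/2 splits exceed it for δ/σ ≲ 3. It becomes a genuine
envelope for large standardized alternatives (δ/σ ≳ 4–5), which is the
regime the test suite checks. Treat it as a rate statement, not a
finite-δ guarantee.

Owen's T is computed by adaptive quadrature of its integral definition
(accuracy over speed; it is not on a hot path) and is cross-checked in
the tests against an independent library implementation and a
brute-force bivariate wedge integral.

## Synthetic designs

* **ReLU-network truth** (`gen_relu_truth`): weights with columns drawn
  as uniform random directions scaled to norm `τ/√d_in`, no biases, and
  the first-layer columns of the nondiscriminative set S0 zeroed — the
  only construction that makes `f*` exactly independent of `x_{S0}` for
  arbitrary deeper weights, so case-(i) nulls hold by construction.
  Scale analysis: each hidden layer multiplies the signal variance by
  roughly `τ²/(2w)` (w = width), so deep/wide truths carry vanishing
  signal at small τ. The default τ = 2 is kept for compatibility with
  the published configuration; desk-scale power studies in the test
  suite use τ = 5 with d = 20, L = 2, w = 32 (signal variance ≈ 0.8
  against unit noise). Set τ ≈ √(2w) per hidden layer for O(1) signal.
* **Feature designs**: AR(1) Gaussian features `N(0, B·Σ)`,
  `Σ_ij = r^{|i−j|}`, generated by the exact AR recursion; the linear
  benchmark uses uniform marginals on [−1,1] with a Gaussian copula
  (correlation matched on the latent scale — the uniform-scale
  correlation is `(6/π) arcsin(ρ/2)`, e.g. 0.48 for latent 0.5).
* **Partially observed design** (`gen_partial_feature_data`):
  star-shaped covariance (unit diagonal, 0.1 coupling to the first
  feature), observed prefix of `d_N = ⌊d(1 − 1/ln N)⌋` columns, outcome
  computed from the zero-padded observed vector so the null is exact.
* **Slowly converging learner** (`SlowOracleLearner`): the true function
  plus a random intercept bias `c·n^{−γ}·sign·U(0.5, 1.5)`, defaults
  c = 0.1, γ = 0.1. With γ this small the splitting condition fails at
  any fixed ζ, and the unperturbed statistic's Type I error grows with
  N, while a unit perturbation restores control. `fit_pair` draws the
  (f, g) pair with a shared magnitude (up to a 20% factor) and
  independent signs, emulating the strongly correlated error magnitudes
  of two fits on overlapping data; with independent magnitudes the
  squared-bias difference `b_f² − b_g²` adds a fourth-moment fluctuation
  that leaves a small residual inflation even at ρ = 1, which is not the
  mechanism under study.

What the designs do **not** emulate: heteroscedastic or heavy-tailed
noise, feature distributions with discrete or bounded-support structure
beyond the uniform benchmark, label noise in classification, and real
learners' optimization pathologies (the shipped MLP is a small
scikit-learn network with early stopping). Passing tests therefore
demonstrate the inference machinery under correctly specified nulls and
smooth alternatives, not robustness to arbitrary real data.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen so the whole suite stays in the
low minutes: Type I studies use the N = 1000 linear benchmark with the
closed-form ridge learner (500 replicates single tests, 300 combined);
the limiting-power comparison uses 2000 replicates of an
estimation-error-free oracle at m = 1000; the perturbation ablation uses
1500 replicates at N ∈ {500, 2000, 5000} (replicate counts sized so
two-sigma binomial bands resolve the effects cleanly); the Type II trend
uses 100 replicates per cell with the truth network regenerated per
replicate — with a single fixed truth draw, the random per-feature
importance heterogeneity dominates the between-case ordering. Cases
(iii) and (iv) of the hypothesized-set ladder are statistically
indistinguishable at desk scale (their difference is a
correlation-proximity effect of order r⁵), so the trend assertions
compare (ii) against each of them rather than ordering (iii) vs (iv).
Full-scale configurations (1000/100 replicates, neural learners,
d = 100) ship in `configs/` for cluster use.

## Numerical choices and degenerate inputs

* p-values are one-sided left-tail, `Φ(Λ)`; Ha drives Λ negative.
* `σ̂` uses the m−1 divisor; `σ̂ = 0` (possible only at ρ = 0 with
  constant differences) raises `DegenerateVarianceError` advising ρ > 0.
* Cross-entropy predictions are clipped at 1e−12 before the log;
  probability rows must sum to 1 within 1e−8.
* Indices are 0-based internally; the CLI accepts 1-based inclusive
  ranges and converts at the boundary. Grid regions are row-major,
  0-based, half-open.
* The mask constant M is a scalar (per-feature constants are not
  supported).
* Learners are re-instantiated per fit — no state leaks between the f̂
  and ĝ fits, which would correlate their errors beyond the design.
* All randomness flows through `numpy.random.Generator`; every driver
  records its seed in the result, and Monte-Carlo harness replicates use
  spawned seed sequences (order-independent, parallel-safe).

## Limitations

* Splitting halves the data available to either stage; the log-ratio
  scheme is deliberately conservative (tiny inference sets), trading
  power for validity.
* Estimation consistency (assumption 1) is unverifiable inside the
  package; a badly misspecified learner invalidates the Type I
  guarantee and no diagnostic here will flag it reliably.
* The adaptive tuner estimates Type I under permutation, which breaks
  the S-to-rest dependence; with strong dependence the permuted null
  can differ from the true null.
* The combined-test power bound is informative only in its tail regime
  (above).
* Multiple hypothesized sets / FDR control across feature groups are
  out of scope.
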