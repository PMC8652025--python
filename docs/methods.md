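# Methods

## Model

A genomic signal `x_i` (read count, fold enrichment, or log Poisson p-value
per interval) is modelled as a draw from a position-specific distribution
with mean `μ_i` and a variance that depends on the mean only through a
dataset-wide function: `var(x_i) = σ(μ_i)²`. Given `σ`, the classical
variance-stabilizing transform

    t(x) = ∫₀ˣ du / σ(u)

makes `var(t(x_i))` approximately constant (first-order delta method). The
package estimates `σ` empirically from replicates and tabulates `t`.

### Estimation

With M replicate tracks aligned to N common intervals, every ordered pair of
replicates contributes its values to a *base* and an *auxiliary* vector of
length `N·M·(M−1)`. Entries are sorted by base value (stable sort, original
index as tiebreak) and chunked into bins of `b` entries; each bin yields
`μ_j = mean(aux)` and `σ_j² = population variance(aux)`. Bin variances are
then smoothed across a window of `2w+1` neighbouring bins with weights
`2^(−b|k|/β)` for offset `k`, where `w = round(−β·ln 0.01 / (b·ln 2))`
(the window that keeps all weights ≥ 0.01), floored at 0; neighbours beyond
the first or last bin are dropped and the remaining weights renormalized.
Finally a cubic smoothing spline of `σ̄_j` against `μ_j` — weights equal to
bin occupancy, penalty weight chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`), or pinned via `spar` — gives
the continuous curve `σ̂(μ)`.

Zero-inflated signal types (raw counts, FE) get a dedicated bin for
positions with base exactly 0; its `(μ₀, σ₀)` enters the spline fit as one
extra point weighted by its occupancy but is excluded from the cross-bin
smoothing window, whose exponential weights only make sense between
homogeneous, equally-sized signal bins.

### Defaults and parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `b` | pairs per bin | 10⁵ (raw/FE), 10³ (LPPV) | bias–variance: larger = smoother, less local |
| `β` | smoothing bandwidth | 10³ (raw/FE), 10⁷ (LPPV) | with the raw/FE defaults `w = 0`: no cross-bin mixing |
| `spar` | spline penalty | GCV | pin for exact reproducibility |
| `n_grid` | integration grid | 4096 | trapezoid error O(h²), ~1e−4 relative on [0, 100] |
| `sigma_floor` | positivity clamp | max(1e−4, 1e−3·median σ̄) | prevents a divergent integral if the spline undershoots near 0 |
| metric bin | instability bin size | 10⁴ | independent of the estimation `b` |

Desk-scale runs in the tests, examples and acceptance script use 10⁵
positions per chromosome with `b = 10³, β = 10³` (the raw-signal `b = 10⁵`
needs ≳10⁷ non-zero pairs to form multiple bins, i.e. genome-scale input);
training is on chr22 and evaluation on chr21 throughout.

### Transform construction and evaluation

`1/σ̂` is integrated by the composite trapezoid rule on a uniform grid of
`n_grid` points over `[0, x_max]` (default `x_max` = training-domain
maximum), anchored at `t(0) = 0`, and stored as a monotone piecewise-linear
lookup table. Above `x_max` the transform continues linearly with slope
`1/σ̂(x_max)`; below 0 (possible for LPPV-like signals) it is reflected with
the left boundary slope — total and monotone without inventing curve shape
where there is no data. The mean–variance relationship a transform
implicitly assumes is `σ̃(u) = 1/t′(u)`; for the lookup table the derivative
is the segment slope, and for log/asinh/identity the closed forms
(`u+c`, `√(u²+1)`, `1`).

Two evaluation metrics:

* **Quality of fit** — `mean_i log N(aux_i | base_i, σ̃(base_i))`, the
  average Gaussian log density (the maximum-entropy distribution for a given
  mean and variance). Maximized when `σ̃` matches the conditional sd of aux
  given base.
* **Variance instability** — sort by transformed base value, chunk into
  full bins of 10⁴ (remainder discarded), let `v_j` be the per-bin **sum** of
  squared between-replicate differences, and report
  `var(v_{1:B}) / (σ₁²σ₂²)` with population variances throughout; the
  normalization makes the score exactly invariant to rescaling `t`. A
  per-position variant (mean instead of sum, differing by the constant `b²`)
  is available behind `--per-position`.

## What the estimator converges to (and why that is acceptable)

The bin statistic is the sd of the auxiliary replicate *conditioned on* the
base replicate's value. This conditional variance decomposes as
`E[σ(μ)² | bin] + var(μ | bin)`: the within-position noise plus the spread
of latent means compatible with the observed base value. For count-type
noise with a broad mean distribution the second term is comparable to the
first (`var(μ | x) ≈ μ` for Poisson), so the learned curve sits roughly
`√2` above the marginal `σ_true(μ)` — the parameter-recovery check in the
acceptance suite measures this directly (~40% median inflation, flagged red
there deliberately rather than absorbed into the tolerance).

Two consequences keep the method sound. First, the inflation is nearly a
constant factor, so `t = ∫1/σ̂` is a near-constant rescaling of the ideal
transform and stabilizes variance just as well — the transform orderings
against log/asinh/identity are unaffected. Second, the conditional sd is
*exactly* the quantity the Gaussian quality-of-fit metric is maximized by,
which is why the learned curve dominates the alternatives on that metric.
Users who need the marginal `σ(μ)` (e.g. for power calculations) should not
read it off the learned curve.

## Synthetic data: what it emulates, and what it does not

Each simulated position draws a latent mean — with probability
`zero_fraction` (default 0.6) a background level (default 0.5 expected
reads per 25 bp bin, standing in for stray/multimapped reads), otherwise
log-normal(`ln 20`, 0.8), optionally boosted by a peak component — and each
replicate then draws independently from the noise model. Defaults:
negative binomial with dispersion `φ = 0.1` (`σ(μ) = √(μ + 0.1μ²)`), a law
distinct from both `s·μ` and `s·√(μ²+1)`, so neither log nor asinh can
fully stabilize it and the comparison is informative.

The background mean is deliberately non-zero: if background positions were
structurally silent, both replicates would read exactly 0 there, the zero
bin would be degenerate (`σ₀ = 0`) and no transform — not even one built
from the true conditional sd — could flatten the 0-vs-signal step in the
instability profile. Real zero-base positions do show noise in the other
replicate, which is the reason a zero bin exists at all.

Not emulated: mappability structure and spatial autocorrelation along the
genome, batch effects between replicates (replicates are i.i.d. given
`μ_i`), fragment-length effects, and the FE/LPPV derivation from ChIP plus
control — simulated "raw" counts are used for all signal types' code paths.
Passing tests therefore demonstrate correctness of the estimation and
evaluation machinery under a realistic marginal signal distribution, not
robustness to replicate-quality pathologies (a known practical limitation:
irreproducible replicates inflate the learned variance globally and shrink
all transformed signals).

A calibration helper generates pairs whose conditional law is exactly
`aux | base ~ N(base, σ(base))` (base equals the latent mean); on these the
quality-of-fit metric provably peaks at the true curve, which the acceptance
suite checks against 0.5×/2× misscalings. With both replicates noisy the
peak sits at the conditional sd instead (≈ `√2 σ`), so that construction —
not the symmetric one — is the correct calibration target.

## Numerical and design choices

* **Partial final bin** kept (weighted by its true count in the spline
  fit): discarding it would bias the right tail, where signal is highest.
* **Sort ties** broken by original index (stable sorts everywhere):
  deterministic output; tied values share adjacent bins, which the smoothing
  window then averages over.
* **Smoothing weights** use offset `k` from the centre bin
  (`2^(−b|k|/β)`), matching the window definition `w`.
* **Variance conventions** are population (1/n) throughout — bin variances,
  the instability `var(v)`, and `σ₁, σ₂` (computed over exactly the
  evaluated positions).
* **Spline smoothing parameter** lives on the penalized-least-squares `λ`
  scale of `make_smoothing_spline`; reproducibility across ecosystems is
  provided by pinning `spar`, not by replicating another library's
  parameterization.
* **Duplicate bin means** (possible for discrete signals) are merged by
  weighted average before the spline fit, which requires strictly
  increasing abscissae.
* **Alignment** re-tiles tracks onto the union of interval boundaries
  (finest grid) restricted to jointly covered bases; dropped bases are
  counted and logged. Coordinates are 0-based half-open; signals are
  strandless.
* **Degenerate inputs**: all-zero data, fewer non-zero pairs than `b`
  (single bin, warning), fewer than 4 distinct bin means (error), constant
  transformed signal in the instability metric (error) are all handled
  explicitly rather than producing NaNs.

## Serialization

Models serialize to a single JSON document: hyperparameters, zero-bin
summary, training chromosomes, a 512-point curve grid and the full
transform lookup grid with boundary slopes. Loading reconstructs the curve
as a piecewise-linear interpolant — exact at the stored grid points, so
round-trips reproduce `σ̂` and `t` to well within 1e−6 there; between grid
points the linear interpolant differs from the original spline by ordinary
interpolation error.
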