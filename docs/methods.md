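# Methods

This note documents the models implemented in `palaeodiv`, the numerical
and design choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. Time is always Ma before
present (present = 0, increasing into the past); a species' lifespan runs
from its time of speciation `Ts` down to its time of extinction `Te`, with
`Te = 0` exactly for extant species.

## 1. Piecewise birth–death with preservation ("fossils" mode)

### Model

Species arise by budding cladogenesis (the ancestor persists) at rate
λ(t) per lineage and go extinct at rate μ(t), both piecewise-constant on a
fixed shift grid (10-Myr bins or geological epochs; the grid is user
input, not estimated). With `B_j` speciation events, `D_j` extinction
events and `S_j` total lineage-Myr in bin `j`, the log-likelihood of a set
of lifespans is

    Σ_j [ B_j ln λ_j + D_j ln μ_j − (λ_j + μ_j) S_j ].

The single oldest `Ts` is treated as the conditioned origin of the process
and contributes no λ factor. Bins where events occur at zero rate give
−∞. This closed form is cross-checked in the test suite against an
independent brute-force quadrature of `N(t)·(λ(t)+μ(t))` on a 10⁻³ Myr
grid (agreement ≤ 10⁻⁶ over 100 random datasets).

Fossil occurrences along a lifespan follow an inhomogeneous Poisson
process with epoch-wise preservation rate `q(t)` (occurrences/lineage/
Myr), scaled per species by a multiplier `m_i ~ Gamma(α, mean 1)` to
capture heterogeneous preservation across taxa. The public
`preservation_loglik` marginalises over a discretised gamma
(`n_categories` equal-probability categories, mean per category; default
K = 4). Inside the MCMC kernel the multiplier is instead integrated out in
closed form,

    log L_i = Σ_x ln q(x) + ln Γ(α+n_i) − ln Γ(α) + α ln α − (α+n_i) ln(α+Λ_i),

with `n_i` the occurrence count and `Λ_i = ∫_{Te}^{Ts} q` — the exact
K → ∞ limit of the discretisation, cheaper and free of a tuning constant.
A test verifies the discretised form converges to this expression as K
grows.

### Sampler

A Metropolis–Hastings sampler (numba-compiled) updates three blocks:

* **rates** (probability 0.3): one λ_j or μ_j by a log-scale multiplier
  move (window 1.2);
* **preservation** (0.2): one q epoch or α, same move type;
* **times** (0.5): a random subset of species' `(Ts, Te)` by sliding-window
  moves (window 2 Myr) reflected at their bounds — `Ts ≥` oldest
  occurrence age, `Te ≤` youngest, `Te = 0` fixed for extant species.
  Reflection keeps the proposal symmetric, so bound rejections never
  freeze the chain. The subset fraction is capped at ~12 species per move;
  larger joint updates make the acceptance probability collapse as the
  product of many per-species ratios.

Priors: λ_j, μ_j, q ~ Gamma(1.1, 1) i.i.d. (vague), α ~ Exponential(1),
flat priors on `(Ts, Te)` within their admissible intervals. The λ
marginal of an extant-only (pure-birth) run is checked against its
analytic conjugate posterior Gamma(1.1 + B, 1 + S) by a KS test.

Each of the `n_replicates` (default 20) chains runs on an independently
age-resampled dataset: every occurrence age is drawn uniformly between its
stratigraphic bounds. Per-species `Ts`/`Te` are reported as posterior
means per replicate; rate samples are pooled across replicates after a 10%
burn-in. Desk-scale defaults are 10⁶ iterations sampled every 10³
(`McmcSettings.paper_scale_fossils()` / `paper_scale_combined()` switch to
the 10⁷ / 2×10⁷ analyses' settings).

The standing-diversity correction (`extant_diversity = N`) augments the
data with `N − n_observed_extant` latent extant lifespans whose `Ts` is
sampled by MCMC; they enter the birth–death likelihood but not the
preservation likelihood. This is one defensible mechanism for correcting
the under-sampling of living species without fossils; it restores missing
extant species only (see §6).

Rates-through-time summaries report per-bin posterior mean and 95% HPD of
λ, μ and net diversification r = λ − μ (computed per sample). Two adjacent
bins differ significantly only when the mean of each lies outside the 95%
HPD of the other — both directions required.

## 2. Combining with phylogeny-derived origination times

For each extant species sampled in a dated tree, `Ts` is the age of the
tip's parent node — the divergence from its sister lineage — matched by tip
label across (possibly topologically different) posterior trees, with the
median over trees as the point estimate. Divergence from a sister is not
literally speciation of the tip species; this equivalence is the standard
reading and its bias (overestimated `Ts` on long or undersampled
branches) is inherited knowingly.

The combination rule: the union of fossil-based and phylogeny-based
species; any species with both estimates keeps the fossil-based `(Ts, Te)`;
phylogeny-only species enter with `(Ts_median, 0)`. For replicate
analyses, fossil age-resampling replicate `k` is paired with posterior
tree draw `k`. Range-through diversity is `N(t) = #{i : Te_i ≤ t ≤ Ts_i}`
on a 0.1-Myr grid (endpoints inclusive); because lifespans are continuous
intervals the curve has no Lazarus gaps by construction.

`compare_shared_ts` quantifies the phylogeny-vs-fossil `Ts` discrepancy
for doubly-estimated species: mean difference (phylogeny − fossil), OLS of
phylogeny on fossil ages, with optional removal of the `n` largest
absolute-residual outliers (the count is user input; no automatic
criterion is imposed).

## 3. Environmental covariates

Covariate curves are two-column (age, value) series. The δ18O-based
deep-sea temperature uses the classic palaeotemperature quadratic
`T = 16.5 − 4.3·δ + 0.14·δ²` (°C); no ice-volume or seawater correction is
applied — long-term interpolated curves smooth those biases, and the
coefficients are exposed in `EPSTEIN_COEFFS`. Curves from different eras
are merged at a switch age (young source strictly below, old at/above,
with a 1-Myr coverage check). Subsampling to a regular 0.5-Myr grid uses a
penalised natural cubic smoothing spline whose penalty is solved by
bisection so that the trace of the smoother matrix equals a target
equivalent degrees of freedom (default df = 200, matching common practice
for sea-level and δ13C series); with df ≥ n the fit degenerates to an
interpolating spline. SciPy has no df-targeted smoothing spline, so the
Reinsch penalty matrix is built directly and eigendecomposed (exact edf,
exact fit). Inside the rate models covariates are evaluated by linear
interpolation with constant extrapolation beyond the ends — the 0.5-Myr
grid is dense relative to any rate variation of interest. Covariates are
kept in raw units throughout the public interface.

The clade's own range-through diversity can be appended as a
"self-diversity" covariate for diversity-dependence tests; the `rm_dd`
flag removes it (the default for order-level analyses, where mixing widely
different ecologies makes diversity dependence uninterpretable).

## 4. Multivariate (covariate-driven) birth–death

Rates vary continuously as `λ(t) = λ0·exp(Σ_i Gλ_i C_i(t))` and
equivalently for μ. The log-likelihood has speciation factors at every
`Ts` (oldest excluded, as above), extinction factors at every `Te > 0`,
minus `∫ N(t)(λ(t)+μ(t)) dt`. The integral projects the piecewise-constant
`N(t)` onto the piecewise-linear hat basis of the integration grid
(default step 0.1 Myr), which integrates the lineage-count step function
exactly and the smooth rate factor at O(step²); with constant covariates
the model then reduces *exactly* to the single-bin piecewise likelihood
(asserted to 10⁻⁹ in the tests).

### Horseshoe prior and shrinkage weights

Each coefficient has prior `G_i ~ N(0, τ²ε_i²)` with `ε_i, τ ~
half-Cauchy(0, 1)`; the scales are updated by the inverse-gamma
auxiliary-variable Gibbs scheme. The shrinkage weight
`ω_i = 1 − 1/(1 + τ²ε_i²)` summarises suppression (ω → 0) vs release
(ω → 1), and an effect is flagged strongly significant only under the
double condition ω > 0.5 **and** 95% HPD of `G_i` excluding 0.

Two implementation choices matter here:

* **Internal coefficient scale.** ω has the normal-means semantics
  "signal exceeds noise at ω = 0.5" only if coefficients are measured in
  units of their own posterior (likelihood) standard error. Covariates are
  therefore centred and scaled internally by `sd(C)·√(n_events/2)` —
  approximately unit Fisher information per coefficient — and coefficients
  are transformed back to raw units for reporting (the baseline rates are
  back-transformed correspondingly). Under raw-unit or plain
  range/z-scored parameterisations, a coefficient as strong as an e-fold
  rate effect across the covariate's range sits *at or below* the ω = 0.5
  boundary and the selection rule loses all power; under unit-information
  scaling the same rule detects such effects reliably while all-null
  datasets stay clean (measured in the calibration experiments).
* **Funnel-proof moves.** The centred Gibbs scheme alone deadlocks in the
  shrinkage funnel: once τ²ε_i² collapses, random-walk moves on `G_i` are
  never accepted and the scales random-walk to the numerical floor. The
  sampler therefore interleaves two exact Metropolis scale moves — jointly
  rescaling `(G_i, ε_i)` and jointly rescaling `(all G, τ)` — plus a
  prior-scaled component in the coefficient random walk. All moves
  preserve the exact target; a test verifies that with an
  information-free dataset the sampler reproduces the half-Cauchy
  marginal of τ.

Baseline rates carry Gamma(1.1, 1) priors and move by multipliers.
Desk-scale defaults are 2×10⁵ iterations sampled every 200 with 10
replicate chains (paper-scale: 2×10⁷ / 2×10⁴). Summaries report posterior
mean and 95% HPD per coefficient, the mean ω, the significance flag, and
posterior envelopes of λ(t), μ(t), r(t) on the covariate grid.

## 5. Traits and size classes

Anterior tooth crown height (mm) proxies body size and trophic ecology.
Missing crown heights of extant species are imputed from per-family OLS
regressions of crown height on compiled body length (cm); families with
fewer than three complete pairs are reported unfitted, measured values are
never altered, and imputed records carry a flag. Size classes
(small/medium/large) use half-open crown-height cut-offs `[c1, c2)`
supplied by configuration — the published cut-off values live in an
external compilation and are deliberately not hard-coded. Partitioning
lifespans by class is exhaustive and disjoint over classified species;
unclassified species are reported, never silently dropped.

## 6. Synthetic data: what it emulates, and what passing tests show

The generator produces every input the analysis consumes:

* **Lifespans** by forward budding birth–death from one lineage at the
  origin age, with piecewise rates and thinning (rejection) sampling of
  event times — exact and simple at this scale. Clades that die out
  completely are redrawn from a fresh deterministic substream
  (conditioning on survival, standard in birth–death simulation).
  Bifurcating or anagenetic speciation, in which the ancestor's `Te` is
  set by the splitting event, is *not* modelled; budding matches the
  estimator's reading of `Ts`/`Te` as lifespan endpoints.
* **Occurrences** by per-species gamma multipliers and epoch-wise Poisson
  preservation, then discretised to stage bins (`[young, old)`; an age on
  a boundary belongs to the younger stage) — the true age is discarded,
  mirroring real stratigraphic data.
* **Covariates** with documented generating equations (linear trend +
  AR(1) noise, sinusoid, white noise, single step).
* **Traits** with family-wise linear body-length/crown-height relations
  plus noise and a missing-data fraction.

A preset scenario mimics the ground-shark history: origin 190 Ma, low
Mesozoic diversification, extinction pulses in the 66–70 and 34–38 Ma
bins, strong Cenozoic radiation (median extant richness across seeds
within a factor of two of the 284 living species), epoch-shifting
preservation with a poorly sampled recent interval, one covariate
co-varying with log-λ(t) and one white-noise covariate.

Problem sizes in the validation experiments: constant-rate recovery uses
clades of 200–400 fossil-sampled species over 50 Myr (λ = 0.2, μ = 0.1,
q = 1.0), 10⁶ MCMC iterations, 20 seeds; covariate calibration uses clades
of 200–600 species over 60 Myr with a cyclic driver (range 20 units,
period 25 Myr, coefficient 0.05/unit — an e-fold rate swing) and 2×10⁵
iterations over 20 seeds. A cyclic rather than monotone driver is used
because a monotone covariate is partially confounded with the clade's own
stochastic growth trend: a single realisation carries limited effective
information about a time-trend coefficient regardless of clade size
(between-seed spread of the estimate about twice the within-dataset
standard error, measured), which no estimator can overcome. Recovery
datasets use 1-Myr stage bins so that stratigraphic age error does not
confound sampler validation: with 5-Myr stages, uniform age-resampling
systematically overshoots true lifespan endpoints and deflates both rates
by a further ~20% — a real property of coarsely binned data (and one
reason the analysis averages 20 age-resampled replicates), not of the
sampler.

What passing tests do **not** show about real data: the generator draws
occurrence ages independently per species (no geographic clustering or
facies control), preservation epochs are known rather than selected, stage
boundaries are exact, and taxonomy is error-free. Real fossil occurrence
data violate all four.

## 7. Known limitations

* **Unsampled species bias both rates low.** The likelihood conditions on
  the fossil-sampled species as if they were the complete set. Species
  leaving no fossils — concentrated among the shortest-lived (a fraction
  ≈ μ/(μ+q) of extinct species) and the youngest extant — remove birth and
  death events while removing little lineage time, deflating λ and μ. At
  q = 1, μ = 0.1 the deflation is ~15%, exceeding the posterior HPD width
  for clades of a few hundred species, so nominal HPD coverage of the
  generating rates fails even though per-species `Ts`/`Te` recovery is
  essentially exact (r ≥ 0.99). The estimator on *complete* lifespans is
  unbiased (verified: λ̂ = 0.1998, μ̂ = 0.1009 over 30 simulations). The
  standing-diversity augmentation restores the missing extant species
  (roughly halving the λ bias) but cannot restore unsampled extinct
  species; correcting those requires a model of non-sampled lineages,
  which is outside this package's scope. Zero-truncating the preservation
  likelihood per sampled species would slightly sharpen duration
  estimates but cannot restore the missing events either; it is not
  applied.
* **Divergence times are not speciation times.** Phylogeny-derived `Ts`
  inherits incomplete taxon sampling: missing extant relatives lengthen
  terminal branches and push `Ts` older.
* **ω is convention-dependent.** The shrinkage weight's numeric value
  depends on the internal covariate scaling (see §4); comparisons of ω
  across analyses are only meaningful under a fixed convention.
* **Fixed shift grids.** Rate-shift times are user input; no reversible-
  jump search over shift placement, and no model selection for
  preservation epochs.
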