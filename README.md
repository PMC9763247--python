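# palaeodiv

Bayesian diversification analysis that combines the fossil record with
dated molecular phylogenies — built around the kind of question posed by
ground sharks (Carcharhiniformes), a clade with a rich Mesozoic–Cenozoic
tooth record but a fossil record that thins out exactly when the living
diversity exploded.

`palaeodiv` is for palaeobiologists and macroevolution researchers who want
to estimate species lifespans and speciation/extinction rates from fossil
occurrence tables, merge them with origination times of extant species
extracted from dated trees, and test environmental drivers of
diversification — all with a synthetic-data generator that makes every step
testable against known truth.

## The models

**Species lifespans and piecewise rates from fossils.** Each species has a
time of speciation `Ts` and extinction `Te` (Ma before present; `Te = 0`
for living species). Fossil occurrences arise along the lifespan as a
Poisson process with epoch-wise preservation rate `q(t)`, optionally scaled
per species by a Gamma(α, mean 1) multiplier. Speciation and extinction are
a birth–death process with rates λ(t), μ(t) constant within fixed time bins
("birth–death with constrained shifts"): with `B_j` speciation events,
`D_j` extinction events and `S_j` total lineage time in bin `j`,

    log L = Σ_j [ B_j·ln λ_j + D_j·ln μ_j − (λ_j + μ_j)·S_j ]

(the single oldest `Ts` is the conditioned origin and contributes no
factor). A Metropolis–Hastings sampler (numba-compiled) jointly estimates
`{λ_j}`, `{μ_j}`, `{q}`, α and every species' `(Ts, Te)`, over replicate
datasets in which each occurrence age is resampled uniformly between its
stratigraphic bounds.

**Combination with the phylogeny.** For extant species sampled in a dated
tree, `Ts` is the age of the tip's parent node (divergence from the sister
lineage) and `Te = 0`. Species with both fossil- and phylogeny-based
estimates keep the fossil-based one. The combined lifespans give a
range-through diversity curve `N(t) = #{i : Te_i ≤ t ≤ Ts_i}` (no Lazarus
gaps by construction) and feed a rates-only run of the same birth–death
sampler.

**Environmental drivers (multivariate birth–death).** Rates vary
continuously with covariates `C_i(t)` (temperature, sea level, δ13C,
continental fragmentation, reef volume, optionally the clade's own
diversity):

    λ(t) = λ0 · exp( Σ_i Gλ_i · C_i(t) ),   μ(t) = μ0 · exp( Σ_i Gμ_i · C_i(t) )

Correlation coefficients carry a horseshoe prior (G ~ N(0, τ²ε_i²),
half-Cauchy local and global scales, inverse-gamma auxiliary Gibbs updates)
so noise covariates are shrunk to zero. A covariate's shrinkage weight
ω = 1 − 1/(1 + τ²ε_i²) summarises release vs suppression; an effect counts
as strongly significant only when ω > 0.5 **and** the 95% HPD of G
excludes 0.

## Worked example

```python
import numpy as np
from palaeodiv import (
    ShiftGrid, McmcSettings, mcmc_bdcs_occurrences, rtt_summary,
)
from palaeodiv.experiments import simulate_constant_rate_dataset

# a simulated clade: lambda=0.2, mu=0.1, preservation q=1.0, 1-Myr stages
occurrences, truth, n_extant = simulate_constant_rate_dataset(seed=1)
grid = ShiftGrid((50.0, 0.0))                       # one bin over 50 Myr
settings = McmcSettings(n_iterations=200_000, sampling_freq=500,
                        seed=1, n_replicates=2, extant_diversity=n_extant)
traces, tste = mcmc_bdcs_occurrences(occurrences, grid, grid, settings)
print(rtt_summary(traces)[["lambda_mean", "mu_mean"]].round(3))
ids = list(tste.index)
r = np.corrcoef([truth[s][0] for s in ids], tste.loc[ids, "ts_mean"])[0, 1]
print(f"Ts correlation with truth: r = {r:.3f}")
```

prints

```
   lambda_mean  mu_mean
0        0.166    0.077
Ts correlation with truth: r = 0.995
```

The per-species speciation/extinction times are recovered almost exactly
(`r = 0.995`). The rate estimates sit ~15 % below the generating values —
the likelihood treats fossil-sampled species as the complete species set,
so species that never fossilise (the shortest-lived and the youngest) are
invisible to it; `docs/methods.md` quantifies this and the
standing-diversity (`extant_diversity`) correction that restores the
missing *extant* part.

A full pipeline run (simulate → fossil analysis → combine → combined
analysis → covariate prep → driver selection → size classes) is one call:

```bash
palaeodiv run --config config.yaml -o runs/demo
```

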