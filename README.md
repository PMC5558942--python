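# endotrend

Did birds and mammals shrink over the 20th century? Museum collections
hold dated, geo-referenced, sexed body-mass measurements going back more
than a hundred years, which makes them a natural archive for testing
whether endotherm body size tracked global change — and whether aquatic
and terrestrial species responded differently. `endotrend` is a tested,
reusable implementation of that analysis for ecologists working with
specimen record tables: from raw records to per-species trends,
cross-species comparisons, and Bayesian phylogenetic mixed models.

## What it computes

**Per-species trends.** For each species, body mass is regressed on year
of collection with absolute latitude, longitude and sex as covariates
(OLS). The trend statistic is the partial correlation between mass and
year,

```
r_year = t / sqrt(t^2 + df_resid)
```

with `t` the year coefficient's t-statistic — identical to the Pearson
correlation of the mass- and year-residuals after removing the
covariates. Species are classed as increasing / no change / decreasing at
α = 0.05.

**Cross-species comparison.** A two-way ANOVA (taxonomic class ×
habitat, Type III sums of squares, sum-to-zero coding) and an ANCOVA
adding time-series length test whether `r_year` differs between birds and
mammals and between aquatic and terrestrial species, with
Kolmogorov–Smirnov, Levene and parallelism checks.

**Phylogenetic mixed models (PGLMM).** Individual standardized masses are
modelled as

```
z_ij = x_ij' β + u_s(i) + e_ij,   u ~ N(0, σ_a² A),   e ~ N(0, σ_e²)
```

where `A` is the shared-branch-length relatedness matrix from a species
phylogeny (all branch lengths 1 by default). A blocked conjugate Gibbs
sampler (near-flat Gaussian priors on β; inverse-Wishart priors with
scale = var(z)/2 and ν = 3 on both variances) yields posterior means,
equal-tailed 95% credible intervals, pMCMC (twice the minority-sign
posterior fraction, floored at 1/retained) and DIC. Three fixed-effect
structures are available: main effects only (A), + year×class (B),
+ year×habitat (C).

**Period contrast.** Records are split at 1950, per-period trends are
compared with a paired t-test, per-period PGLMMs are fitted, and the
iteration-wise difference of posterior coefficient draws ("after minus
before") gives a direct posterior test of whether the trend changed.

**Synthetic data.** `endotrend.simulate` generates record tables,
species metadata and trees with exactly this generative structure and a
ground-truth file, so every stage is verifiable without any downloads.

## Worked example

```python
import endotrend as et

config = et.SimConfig(seed=1)                      # 44-species synthetic study
tree = et.simulate_tree(config.total_species, seed=2)
records, meta, truth = et.simulate_records(config, tree=tree)

filtered, reports = et.apply_filter_chain(records)
trends = et.fit_species_trends(filtered)
print(et.trend_class_counts(trends))
# {'increase': 1, 'none': 26, 'decrease': 17}

mf = et.species_meta_frame(meta).loc[trends.index]
anova = et.two_way_anova(trends["r_year"], mf["taxo_class"], mf["habitat"])
print(anova["habitat"])
# F         9.714250e+01
# df_num    1.000000e+00
# df_den    4.000000e+01
# p         2.928685e-12

fit = et.PhylogeneticGLMM(model="C", total=25_000, burn_in=5_000,
                          thin=10, random_state=1).fit(
    filtered, meta=meta, tree=tree)
print(fit.summary_.loc["year_x_habitat_terrestrial"].round(4))
# post_mean   -0.0070
# l95         -0.0085
# u95         -0.0056
# pmcmc        0.0005
```

The habitat F on 1,40 df says aquatic and terrestrial species differ
strongly in their mass trends; the negative year×habitat interaction
(in standardized-mass units per year, pMCMC at the 1/2000 floor) says
terrestrial mass declines relative to aquatic once phylogeny and the
other covariates are accounted for — matching the generator's settings
(aquatic +0.003/yr; terrestrial flat before 1950, −0.006/yr after).

The same stages are available from the shell:

```
endotrend simulate --outdir data/sim --seed 1
endotrend run-all --simulate --outdir runs/demo --seed 1
```

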