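# Methods

## Data model

A MET is a tidy table of plot records (genotype, environment, replicate,
yield in t/ha).  Environments are location–year combinations written as
a location code plus a four-digit year (`PU2018`); replicates are RCBD
blocks local to their environment and never matched across environments.
All model fitting requires balance — every (genotype, environment,
replicate) cell exactly once.  Missing cells are a hard error; the
`subset_balanced` helper extracts a caller-specified complete block,
mirroring how balanced analysis sets are carved out of a breeding
program's historical series.  A wide genotype × environment means table
is accepted for means-only analyses (AMMI/GGE), with the replicate count
supplied separately where a plot basis is needed.

## ANOVA and AMMI

The joint fixed-effects ANOVA uses sources ENV (e−1), REP(ENV) (e(r−1)),
GEN (g−1), GEN:ENV ((g−1)(e−1)) and Residual (e(g−1)(r−1)); GEN and
GEN:ENV are tested against the residual, ENV against REP(ENV).  G/E/GE
shares are reported as fractions of SS_G + SS_E + SS_GE, excluding block
and residual strata.

AMMI decomposes the doubly-centered cell-mean matrix by SVD.  Axis tests
convert to the plot basis (SS_k = r·λ_k²) and use Gollob degrees of
freedom g + e − 1 − 2k.  Gollob's test is the dominant convention but is
known to be liberal: on pure-noise interaction it declares axes
significant far more often than the nominal rate, so "number of
significant axes" routinely exceeds the number of axes carrying real
signal.  The signal/noise partition (noise = df_GE · MS_res, signal the
remainder, clamped to [0, SS_GE]) is the better guide to how many axes
matter.  Ties in singular values are broken by the stable LAPACK
ordering, and each axis is oriented so its largest-magnitude genotype
loading is positive, making scores reproducible across platforms.

## BLUP

Genotypes and interaction are random; environments and blocks are fixed
and enter only through centering.  Variance components come from the
balanced-data expected-mean-square equations (σ̂²_res = MS_res,
σ̂²_ge = (MS_GE − MS_res)/r, σ̂²_g = (MS_G − MS_GE)/(er)), truncated at
zero *before* shrinkage weights are formed so the weights stay in
[0, 1].  On balanced data these estimators coincide with REML away from
truncation boundaries; the closed form is exactly testable, and the
test suite checks the resulting genotype predictions against a direct
Henderson mixed-model-equations solve (agreement to 1e−8).

The shrunken interaction matrix is s·Z with
s = σ²_ge/(σ²_ge + σ²_res/r) applied to the doubly-centered residuals.
This is the standard construction feeding WAASB; it is *not* the joint
Henderson BLUP of the cell-level interaction effects (which is not
doubly centered and couples with the genotype effects), and the two are
deliberately distinct in the tests.

## WAASB and quadrants

WAASB averages absolute IPCA scores over all p = min(g−1, e−1) axes of
the SVD of the shrunken interaction matrix, weighted by each axis's
variance share.  Scores use symmetric (√λ) scaling by default so
genotypes and environments share one biplot; the scaling is switchable.
Quadrant cut-offs default to the mean yield and mean WAASB of the
plotted entities; on the cut-off itself, yield counts as high and WAASB
as stable, so a point on both crosshairs falls in quadrant IV.  The
WAASBY blend rescales yield (best → 100) and WAASB (most stable → 100)
linearly and mixes them by a 0–100 performance weight.

## GGE

Centering is by environment means (the G+GE model), no scaling, with
genotype-focused singular-value partitioning — the conventional settings
for genotype-ranking biplots; all three are arguments.  Ranking geometry
always uses two axes (a rank-1 fit is zero-padded).  The ideal point
lies on the unit average-environment direction at the largest genotype
projection; distances to it order the genotypes.

## Cross-validation

Each resample holds one uniformly chosen complete block per environment
out for validation and trains on the rest.  Every AMMI member is refit
on the training cell means; BLUP predictions are
μ̂ + shrunken genotype effect + environment mean deviation + shrunken
interaction entry, with variance components re-estimated inside every
training resample.  RMSPD is scored over all g·e held-out plots.  The
"comparable accuracy" rule reports the fewest-axis AMMI member whose
mean RMSPD is within a configurable fraction (default 1%) of the best
AMMI member.

## Synthetic generator

Plot yields are drawn from the model all methods assume: Gaussian
centered main effects, a low-rank interaction on seeded orthonormal
centered axes, an optional iid Gaussian interaction background, Gaussian
blocks and plot error.  Negative draws are floored at zero (yields are
physical); with the shipped presets this touches ~0.3% of plots and has
no measurable effect on recovery, but recovery tests at large planted
interaction amplitudes must keep the grand mean high enough that the
floor never binds.

The `pea-like` preset (g=12, e=28, r=3; μ=2.7 t/ha; σ²_g=0.03,
σ²_e=0.88, σ²_block=0.01, σ²_res=0.09; planted axes λ=(2.45, 1.71) plus
diffuse background σ²_ge=0.015) reproduces the regime of a real pea
trial series: environment-dominated variation (expected G/E/GE shares
≈ 0.03/0.90/0.07), an interaction that is ≈60% signal, per-trial CVs
near 10%, and an interaction spectrum whose first six axes carry ≈87%
of the interaction variation.  The split of signal between the two
planted axes (two-thirds) and the diffuse background (one-third) was
calibrated to that spectrum shape: a pure rank-2 interaction is *not*
realistic — real trial series show several significant axes with the
top few carrying most, not all, of the signal.  A `winner_boost` option
plants a stable high-yielder (raised main effect, exactly zero
interaction rows) as a known target for the stability methods.

What the generator does not emulate: non-Gaussian or heteroscedastic
errors, spatial trend within trials, unbalanced or augmented designs,
and genotype–weather covariance.  Passing recovery tests therefore show
correctness of the estimators under the assumed model, not robustness
to field artifacts.

### Regime dependence of the CV comparison

Under the pea-like preset BLUP has the smallest expected RMSPD, and wins
at the default seed; across independent dataset realizations it wins
about two-thirds of the time, with AMMI2 (the planted rank) edging it by
<1% otherwise.  The margin favors BLUP more strongly as the interaction
becomes more diffuse, and flips toward truncated AMMI when the
interaction is exactly low-rank — worth remembering when interpreting a
single series.

## Weather module

Periods are days 1–10, 11–20 and 21–month-end (May–July by default,
August constructible); temperature is averaged, rainfall totalled, and
June/July get rainless-day (RF0) and hot-day (MaxT>90) counters.  The
hot-day threshold is 90 °F (32.2 °C), inclusive, and configurable — the
conventional heat-stress cutoff for this covariate family; the variable
names keep the MaxT>90 convention.  A period with any missing day yields
a missing covariate rather than a silently short aggregate.  PLSR runs
on autoscaled covariates with centered response via scikit-learn's
NIPALS implementation (2 latent components by default, the usual choice
for coefficient screening; with full-rank components it reproduces OLS,
which the tests check).  Coefficients are reported on the
standardized-predictor scale so variables are directly comparable.

## Numerical choices and degenerate inputs

Singular values below 1e−12 of the largest are zeroed; a rank-0
interaction is a valid AMMI fit with all λ = 0 and zero WAASB for every
entity.  Zero genetic variance collapses every BLUP to the grand mean;
zero interaction variance gives a zero shrunken matrix.  Heritability is
plot-basis (σ²_g/(σ²_g + σ²_res), the literal total-phenotypic-variance
reading) with negative components truncated, clamped to [0, 1]; trial
CVs are residual-based (RCBD residual MS), the trial-quality convention
in breeding reports, not raw standard deviations.  A constant trial (no
variation at all) is a degeneracy error, as is a GGE fit with no
genotypic signal or an ideal-genotype ranking with a degenerate
average-environment direction.

## Problem sizes

The shipped tests and the acceptance script use the preset's full
12 × 28 × 3 layout; rate estimates use 200 variance-component
replicates, 50 axis-detection seeds, 40 planted-winner seeds, 200 CV
resamples per dataset and 10 replicate datasets for the win rate —
enough for the Monte-Carlo error to sit well inside the asserted
tolerances.
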