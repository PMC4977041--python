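# Methods

## The model

`didmort` implements a difference-in-differences (DiD) analysis of long-term
fine-particle exposure and mortality on a census-tract by year panel. The
estimating model is an overdispersed (quasi-)Poisson regression with a log
link:

```
ln E(Y_ct) = b0 + b1 PM_ct + sum_{c != cR} b_c I_c + sum_{t != tR} b_t I_t
             + s(Ts_ct) + s(Tw_ct) + ln(P_c)
```

where `Y_ct` are annual natural-cause deaths in tract `c` and year `t`,
`PM_ct` is the annual mean PM2.5 (ug/m3), `I_c` and `I_t` are indicator
variables for every tract and year but one reference level each (the
lexicographically smallest tract and the earliest year), `Ts`/`Tw` are the
mean summer (June-August) and winter (January, February, December of the same
calendar year) temperatures entered as single-knot linear splines
`s(x) = a1 x + a2 max(0, x - knot)` with the knot at the unweighted mean of
the variable over the fitted records, and `ln(P_c)` is a log-population
offset. The tract dummies absorb every spatial confounder that is constant
over the study span; the year dummies absorb any common time trend, however
non-linear. What identification then requires is that no variable other than
the seasonal temperatures varies differentially over time *and* space in a
way correlated with the tract-level deviations of PM2.5 from its tract mean
and the state-wide yearly shift. On a 2-tract, 2-year panel the estimator
reduces exactly to the classical DiD contrast
`[dlog-rate(c) - dlog-rate(c')] / [(a - a') - (b - b')]`, which the test
suite asserts to 1e-8.

Effects are reported as percent changes per exposure increment, by default
the 2 ug/m3 interquartile range of annual PM2.5:
`100 (exp(2 b1) - 1)`, with 95% Wald intervals formed on the log scale.

## Fitting

The fit is plain Poisson maximum likelihood by iteratively reweighted least
squares (log link, offset), with dummies stored as sparse columns and the
weighted normal equations solved by a dense Cholesky factorization of the
`p x p` cross-product — exact and fast up to a few thousand tracts.
IRLS starts at `mu = y + 0.5` (handles zero counts) and stops when the
largest absolute coefficient change falls below `tol` (default 1e-8, at most
100 iterations); non-convergence returns a flagged partial result.
Overdispersion is the Pearson estimate `phi = sum (y - mu)^2 / mu / (n - p)`
and the coefficient covariance is `phi` times the inverse Fisher information,
so reported standard errors are exactly `sqrt(phi)` times the unscaled
Poisson ones. A saturated fit (zero residual degrees of freedom) succeeds
with `phi = NaN` and unscaled standard errors, with a warning — the worked
2x2 example needs this. Tracts whose deaths are zero in every year are
dropped before fitting (their dummy's MLE diverges) and logged; tracts seen
in a single year are kept but flagged. Rank deficiency is reported with the
names of the offending columns from a pivoted QR of the cross-product.

Scalar effect modifiers are centered at their fit-sample means and scaled by
their standard deviations before products with the exposure are formed, so
the main exposure coefficient is the slope "at the average" and the normal
equations stay well conditioned with dollar-scale covariates; spline
moderators contribute two product columns (their centered, scaled basis).
Modifiers that vary within tract (the county-year smoking and diabetes
prevalences) also enter as main effects; tract-constant modifiers are
absorbed by the tract dummies. Conditional effects at a covariate setting
use the delta method on the linear combination of the exposure and product
coefficients; interaction tests are Wald chi-squares on the product-term
block (1-df per-contrast for scalars, joint 2-df for a spline's set).
Whether the two seasonal product sets enter one at a time or together was an
open design choice; they enter together, matching how the conditional-effect
table is constructed.

Backward elimination starts from the model with all candidate products,
repeatedly drops the largest-p product (ties broken lexicographically) and
refits, stopping when everything retained has p < 0.05. Only products are
candidates; implied main effects stay.

The within-tract sensitivity analysis regresses each tract's yearly deaths
on its yearly PM2.5 (intercept, log-population offset, no year terms — the
minimal reading of the procedure) with plain Poisson standard errors:
per-tract Pearson dispersion from ~6 observations and 2 parameters would be
noise. Tracts with fewer than two years, no exposure contrast, or all-zero
deaths are flagged unusable and excluded from the pool, which is
DerSimonian-Laird: `Q = sum w (theta - theta_FE)^2` with fixed-effect
weights `w = 1/se^2`, `tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))`,
and random-effects weights `1 / (se^2 + tau2)`. With `tau2 = 0` the pool
reduces exactly to the inverse-variance fixed-effect estimate. Because the
within-tract fits carry no year adjustment, a common mortality trend that is
correlated with the state-wide exposure decline shifts the pooled estimate;
the agreement check between the pooled and DiD estimates therefore uses a
trend-free scenario, and the default scenario (which has such a trend)
illustrates precisely the confounding the DiD design removes.

## The synthetic-data generator

No mortality data ship with the package, so every downstream stage is
validated on synthetic panels with known truth. `generate_panel` draws, for
each tract: a population (uniform on 1,800-7,500 persons), a spatial
confounder `Z_c` (SD 0.25 on the log-rate scale) optionally correlated with
the tract's long-term mean PM2.5, long-term seasonal temperature means
(18.6 +/- 0.73 C summer, 5.9 +/- 0.73 C winter), and tract-level SES
modifiers (percent black residents, median income, median home value, as a
Gaussian copula over skewed marginals) plus county-year smoking and diabetes
prevalences with small yearly random walks. Exposure decomposes as
`PM_ct = tract mean + state-wide yearly shift + idiosyncratic deviation
(SD 0.4)`; only the deviation is correlated (through a shared meteorological
factor) with the tract-year temperature deviations, mirroring the claim that
residual exposure variation is meteorological. The yearly patterns of the
log rate (non-monotone), exposure (declining) and temperatures follow the
published state-wide tables in shape and scale, stretched by interpolation
for other panel lengths. Two age strata (at or below / above 65) are
generated with distinct baseline rates (2.1 and 40.1 per 1,000, population
share 13.55% elderly) and the all-ages records are their exact sums.

Counts are Poisson at dispersion 1 and otherwise negative binomial with size
`mu / (phi - 1)`, i.e. success probability `1/phi`, so the variance is
exactly `phi mu` and the Pearson dispersion is a recoverable parameter
(calibration `[1.9, 2.1]` at `phi = 2` over 10,000 records is asserted).
Planted effect modification adds `coeff (x - mean(x))` to the exposure
slope. Everything is deterministic given the scenario seed, and the exact
per-record log means are returned (`SimulationTruth.linear_predictors`) so
estimators can be checked against noise-free expectations.

What the generator does *not* emulate: real geography (tract labels are
opaque, counties are round-robin groupings), migration or population change,
age structure beyond two strata, spatial autocorrelation between neighbouring
tracts, and exposure-model measurement error. Passing tests therefore show
that the estimator recovers the truth under the declared confounding
structure — not that any particular real-data estimate is correct.

## Validation studies and their design

`didmort.studies` contains the Monte Carlo experiments the acceptance script
reruns; sizes were chosen for adequate power at around a minute of total
runtime.

**Recovery and coverage.** 200 panels of 200 tracts x 6 years with the
planted slope ln(1.03)/2 per ug/m3 (3.0% per IQR) and `phi = 2`; the mean
recovered percent change must sit within 3 Monte Carlo SEs of 3.0% and
empirical 95% CI coverage within [92%, 98%].

**Confounding.** Tract effects correlated with tract-mean PM2.5 at r = 0.5,
temperature effects off. The "planted" bias of the deliberately
mis-specified model without tract dummies is computed deterministically as
its pseudo-true slope: the same estimating equation solved with the exact
expected counts as response. A moment approximation,
`r sd(Z) sd(pm_tract) / (sd(pm_tract)^2 + sd(pm_dev)^2)` (about 0.079 per
ug/m3 against a true 0.0148), agrees with the pseudo-true value to ~2%. The
mis-specified fit must land within 20% of the planted bias; the DiD fit's
bias must be indistinguishable from zero.

**Berkson error.** Individual cohorts with personal exposures deviating from
the tract-year mean, analysis on the tract-year design mean. Two facts shaped
this design. First, with purely independent per-person deviations the
aggregated death count is *exactly* Poisson-binomial in the marginal death
probabilities (the law of total variance collapses: between-person
probability spread subtracts from the binomial part exactly what it adds
between replicates), so independent Berkson noise adds no tract-level
variance at all — the inflation clause is only testable when part of the
deviation is shared within a tract-year, which is also what spatially
correlated neighbourhood pollution gradients produce. The cohort generator
therefore takes separate independent and shared deviation SDs. Second, the
Bernoulli death probability `1 - exp(-hazard)` is concave in the hazard, so
large hazards attenuate the recovered slope in *both* arms; the scenario
keeps the marginal death rate at 0.012 per person-year (matched across arms
by adjusting the baseline for the lognormal mean `exp((b1 sd)^2 / 2)`) so
this curvature bias stays well inside the Monte Carlo noise. The frozen
design — 25 tracts x 4 years x ~100 persons, `b1 = 0.1` per ug/m3, total
deviation SD 10 with 30% shared variance, 500 replicates, common random
numbers across arms — is a deliberately stylized high-signal cohort sized by
a power analysis so that unbiasedness (within 3 MC SEs) and variance
inflation (observed ratio ~1.4-1.7) are both measurable.

**Temperature interaction ordering.** A winter interaction of 0.017 per
ug/m3 per degree C — the magnitude implied by published conditional
estimates of this design — is planted; in each of 200 replicates the
conditional effect at one degree above the mean winter temperature must
exceed the effect at the mean. With the planted value at roughly 3.5
standard errors of the fitted slope difference, the ordering is recovered in
effectively every replicate.

**Selection consistency.** One true interaction (median income, a slope
change of -0.1% per ug/m3 per $1,000, about 7 SE at 400 tracts) among the
five candidates. The true term is retained in every run. The *sole-survivor*
rate, however, plateaus near 72-85%: step-down elimination reaches its final
stage with the smallest-p null term still in the model, and since per-term
p-values barely change across refits, that term survives with probability
close to `1 - (1 - 0.05)^4 = 18.5%`. This ceiling is a property of the
literal procedure (it is the familiar type-I inflation of stepwise
selection), not of the implementation; the corresponding acceptance test
asserts the stated 90% bar and is expected to fail, by design left honest.

**Structural invariants.** Offset invariance (doubling populations and
deaths), exact `sqrt(phi)` SE scaling, spline continuity at the knot, and
exact absorption of tract- and year-constant shifts. Absorption is exact for
the estimand, not for any noisy realization, so it is asserted on noise-free
expected counts, where the fit recovers the planted slope to 1e-7 before and
after shifting.

## Numerical choices and edge cases

- IRLS tolerance 1e-8 on the max coefficient change, 100 iterations,
  linear predictors clipped at +/-40 to avoid overflow before convergence.
- Percentiles in the descriptive summary interpolate linearly between order
  statistics; the over-65 death share is rounded to the nearest percent.
- The `all` age stratum must equal the sum of the two age strata; the
  stratified runner warns when it does not.
- Duplicate panel keys, non-integer deaths, and deaths exceeding population
  are rejected at read time with the offending key or row named.
- Ties in backward elimination (equal p-values) drop the lexicographically
  smallest term name; the procedure is deterministic given the panel.
- `generate_individual_cohort`'s degenerate sd = 0 case matches the count
  panel's expectations only up to O(hazard^2), because the per-person death
  probability is `1 - exp(-h)` while the count model's mean sums hazards;
  the tests assert the bound rather than equality.

## Known limitations

- The estimator targets desk-scale panels (up to a few thousand tracts);
  the dense `p x p` solve would need an absorption/alternating-projection
  strategy well beyond that, which is deliberately out of scope.
- No clustered or autocorrelation-robust variances: the quasi-Poisson scale
  is the only variance adjustment, as in the design being implemented.
- The within-tract sensitivity estimator is unadjusted for year effects by
  construction and inherits trend confounding on purpose.
- Stepwise selection retains a null modifier in roughly one run in five at
  alpha = 0.05 with four null candidates; treat the selected set as
  descriptive, not inferential.
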