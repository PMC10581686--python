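# Methods

This note documents the statistical models implemented in `biointerest`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the limitations a user should know about.

## Sampling model

The sampling frame is a backbone taxonomy table with Darwin Core columns.
Cleaning keeps rows with `taxonomicStatus = accepted`, `taxonRank =
species` (subspecies and varieties are dropped) and no fossil flag; the
operation is idempotent and order-preserving, and unknown status/rank
vocabulary is an error rather than a silent drop.

Sampling is stratified by order.  Quotas, in priority order:

1. tetrapod orders (classes Amphibia, Reptilia, Aves, Mammalia by default —
   the set is configurable because "tetrapod" is a clade, not a rank):
   20 species, or 1 if the order has fewer than 10 species;
2. bracket caps for huge orders: 20 (10,001–50,000 species),
   40 (50,001–100,000), 60 (>100,000) — caps *replace* the fraction;
3. otherwise `ceil(0.002 n)`.

The ceiling (with its implicit minimum of 1) is our choice where rounding
is ambiguous: it guarantees every non-empty order contributes at least one
species, which matches the intent of sampling *all* extant orders.  A
`floor` mode is available for sensitivity checks.  Draws are uniform
without replacement from one seeded generator consumed in sorted
order-name sequence, so results are reproducible across platforms.

## Geography

*Dispersion range* is the mean great-circle (haversine, R = 6371 km)
distance over all unordered pairs of occurrence points — a range-size proxy
robust to uneven sampling effort.  The distance metric and units are our
choice (occurrence data are lon/lat; a Euclidean-degrees mode exists for
cross-checks).  Exact duplicate points are kept by default; deduplication
is an option.  Above 5000 points the pairwise mean is estimated from a
seeded draw of 10^6 ordered pairs (relative error well under 1%); below
that it is exact.

*Centroids* are spherical: points are averaged as 3-D unit vectors and the
mean is renormalised, which is correct across the antimeridian.  An
exactly antipodal configuration has no centroid and raises an error.
*Realm assignment* is a nearest-cell lookup into a user-supplied lon/lat
grid (the synthetic module ships a crude box-rule grid labelled as such);
polygon GIS is out of scope.

## Count mixed models

Let `y_i` be a species' paper or pageview count, `x_i` its standardized
covariate vector.  The families are

* Poisson: `Var = mu`;
* NB2: `Var = mu + mu^2 / theta`, theta > 0 on a log scale internally;
* ZINB2: a point mass at zero mixed with NB2,
  `P(0) = pi + (1 - pi) (theta/(theta+mu))^theta`, with an intercept-only
  mixing probability on a logit scale.  Intercept-only inflation is a
  documented reading of "standard zero-inflated model"; the structure is a
  config field so covariate-dependent inflation could be added.

Random intercepts are independent Gaussians per level of each grouping
factor.  The nested taxonomic intercept `(1 | Phylum/Class/Order)` is
expanded by composite keys into three factors (Phylum, Phylum:Class,
Phylum:Class:Order), each with its own variance, plus the crossed realm
factor.  Within-phylum model variants start the nesting at class, use
genus rather than family uniqueness, and drop divergence time (it has no
resolution within a phylum).

**Estimation.** The marginal likelihood integrates the stacked intercepts
`b` (dimension q = total number of levels, typically < 100) by a Laplace
approximation: damped Newton maximisation of the penalised log-likelihood
over `b` (backtracking line search; gradient tolerance 1e-8 relative to
the objective, since an absolute tolerance is unattainable in doubles for
large counts), then

```
log L = l(y|b̂) − b̂'D⁻¹b̂/2 − [logdet(Z'WZ + D⁻¹) + logdet D]/2 .
```

The determinant is computed after symmetric diagonal scaling so that trial
parameter values with extreme dynamic range remain finite; the linear
predictor is clipped at ±300 for the same reason (it never binds at any
plausible optimum).  With no random terms the objective reduces exactly to
the fixed-effects likelihood, and it converges to it continuously as the
variances go to zero (this is a unit test).  The outer maximisation is
L-BFGS-B over (beta, log theta, logit pi, log sigma_g) with box bounds;
log sigma is floored at −5 (a variance estimated at the floor is reported
as pinned at ~0, with a warning) and capped at 1.5.  Starting values:
Poisson GLM for beta, method-of-moments for theta, the excess-zero
fraction for pi, sigma² = 0.1.

**Validation of the implementation** (in the test suite): fixed-effects
Poisson against a from-scratch IRLS solver; fixed-effects NB2 against
statsmodels' independent implementation; the Laplace objective against
Gauss–Hermite quadrature on single-factor problems; and the full
nested+crossed NB2 model against glmmTMB (agreement to ~0.01 in
log-likelihood and coefficients on a 400-species dataset).

**Inference.** Standard errors come from the numerical Hessian (central
differences, step 5e-4 relative) of the Laplace log-likelihood at the
optimum; confidence intervals are Wald (the convention behind forest-plot
error bars; profile intervals are out of scope).  Significance uses
alpha = 0.01 — a deliberate, conservative convention for large samples.
AIC counts *all* estimated parameters: beta, theta, pi and each random
variance.

**Diagnostics.** The overdispersion check is the Pearson dispersion ratio
`sum(r_P²)/(n − p)` with family-specific variances and plug-in (conditional
on b̂) means, with a chi-square upper-tail p-value.  The zero check
compares observed zeros with `sum_i P(y_i = 0)` under the fitted model,
reporting predicted/observed (NaN with a note when no zeros are observed).
VIFs are computed per column of the numeric fixed-effects design excluding
the intercept (factor dummies assessed per column, not grouped), with the
usual all-below-3 convention.  Influence is probed by leave-one-out refits
of the K largest-|residual| observations, reported but never auto-removed.

## R² and variance partitioning

On the latent (log) scale, `R²m = var_f / (var_f + var_r + var_d)` and
`R²c = (var_f + var_r) / (…)`, where `var_f` is the variance of the fixed
linear predictor, `var_r` the summed random-intercept variances, and
`var_d` the distribution-specific variance.  For log-link count families
`var_d` uses the lognormal approximation `ln(1 + 1/lambda + 1/theta)`
(Poisson drops the `1/theta` term) with `lambda = exp(mean(eta) +
(var_f + var_r)/2)`; a trigamma variant is available behind a flag (the
two differ appreciably under strong overdispersion; the trigamma form is
the more conservative).  For ZINB2 fits R² is computed on the count
component conditional on non-inflation — a documented choice.

The partition refits the model with only the species-trait covariates and
only the cultural covariates (identical random structure), then

```
unique_species = R²m_full − R²m_culture,   unique_culture = R²m_full − R²m_species,
shared = R²m_species + R²m_culture − R²m_full,
```

so `unique_species + unique_culture + shared = R²m_full` holds as an
algebraic identity (asserted to 1e-10).  Shared variance can be negative
(suppression) and is reported as computed.  Default grouping: species
traits = size, colorfulness, range, habitat domain, uniqueness; culture =
common name, IUCN group, human use, harmfulness, divergence time.

## Imbalance scores

Both interest counts are transformed as `log10(1 + y)` (natural-log option
available); the transformed-scale smooth is our choice where the original
scale is ambiguous, and residuals are defined on that scale.  The smoother
is a Gaussian P-spline: 10 cubic B-splines on equally spaced, unclamped
knots extending past the data range, a second-difference coefficient
penalty, and GCV (`n·RSS/(n − edf)²`) minimised over a 61-point log-spaced
grid, lambda in 1e-6…1e6.  With this basis the penalty null space is
exactly the straight lines, so the infinite-penalty limit is the OLS line
and adding a constant to y shifts the fit by that constant; GCV selection
is invariant to affine transforms of y.  Basis size 10 and GCV (rather
than REML) selection are defaults of common additive-model practice.

The residuals (positive = societal excess) are modelled against the full
trait design with a Gaussian identity-link mixed model fitted by REML —
exact for the Gaussian case, no Laplace error — via statsmodels MixedLM
with one variance component per grouping factor, wrapped to present the
same reporting surface as the count fits.

## Synthetic-data generator

The generator emulates the statistical structure the models assume, with
every parameter explicit in `GeneratorConfig`:

* nested taxonomy with heavy-tailed (discrete lognormal, median ~150,
  log-sd 1.5) order sizes; genus/family labels assigned with geometric
  group sizes so uniqueness covariates can be tallied from the taxonomy
  itself; decoy synonym/subspecies/fossil rows exercise cleaning;
* traits: lognormal body sizes (median ~50 mm), Bernoulli cultural flags
  (e.g. common name 0.40, human use 0.30, harmful 0.10, colorful 0.25,
  model organism 0.005), a 9-code IUCN status (heavy on LC/NE/DD, as in
  real assessments) collapsed to 3 groups, a 4-level habitat domain with
  "multiple" the modal level, lognormal ranges and divergence times;
* counts: `eta = X beta + b_taxo + b_region` with per-level taxonomic
  intercept SD 0.5 and realm SD 0.3; papers ~ NB2(exp(eta), 0.7) with the
  intercept placed so roughly half the species have zero papers (the
  zero-heavy regime of real literature harvests); views ~ ZINB2 with
  theta = 0.3, pi = 0.05 and a larger intercept, giving few zeros beyond
  the inflation component and a heavy right tail (maxima well above 10^5).
  Coefficients are expressed on the standardized design scale, so refits
  recover them directly.

What it does **not** emulate: language-resolved pageview time series,
trait–taxonomy correlations (traits are drawn independently of the clade),
real biogeographic polygons, spatially clustered occurrences, or the
magnitudes of the most extreme real species (views in the tens of
millions).  Passing tests therefore demonstrate the *estimators* are
correct and calibrated under the assumed data-generating process, not that
any particular real-world effect size is right.

## Problem sizes

Defaults used by the shipped tests and the reproduction script: scenario
datasets of 3000 species (the scale of a real stratified harvest);
coefficient-recovery studies over 10 replicates in the test suite and 5 in
the reproduction script; diagnostics calibration over 20 seeded runs at
n = 2000; partition checks at n = 5000.  These sizes give Monte-Carlo
error comfortably below the tolerances asserted while keeping a full run
in the minutes range on a single CPU.

## Known limitations

* The Laplace approximation is biased for binary-like or tiny-count groups;
  with the group sizes generated here the error is ~1e-3 per observation
  (checked against quadrature).  No adaptive quadrature fallback.
* Wald intervals can undercover for variance parameters near zero; the
  coefficient coverage is the tested guarantee (~95% at n = 3000).
* The zero-inflation structure is intercept-only.
* Influential-observation handling reports, but does not remove, points;
  automated removal decisions are left to the analyst.
* The pipeline runner covers the simulated path end to end; external data
  enter through the documented TSV/CSV contracts and the library API.
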