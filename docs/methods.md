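# Methods

## Problem and data

Removal trapping programs for invasive animals produce, per management
area, a time series of daily removal counts and daily trap effort.
Raw catch-per-unit-effort confounds three processes: imperfect
detection (not every present animal is caught), availability bias
(temporary emigration — an animal's home range only partly overlaps
the trapping array, and the overlap shifts seasonally), and genuine
population dynamics (births, deaths, migration, and the removals
themselves). The package implements two open robust-design removal
models that disentangle these from unmarked removal counts alone.

Time is organised as a robust design: each year splits into
fixed-length primary periods (default 14 days, hence 26 per year
cycle, with the final period absorbing the calendar remainder), each
containing secondary occasions — the active trapping days. The
population is closed within a period except for removals and
availability, and open between periods. Only March–October records
enter the analysis; period 1 starts January 1, so the May 1 birth-pulse
anniversary falls in period 9. Day-of-year arithmetic uses a 365-day
convention (Feb 29 merges into the excluded February window).

## Observation model (shared)

For year `y`, period `t`, day `j`:

* capture efficiency `theta_y` — per-trap per-day capture probability
  of one animal, one per year (trap composition varies by year);
  vague Beta(1,1) prior.
* daily capture probability `p_{y,t} = 1 - (1 - theta_y)^Traps_{y,t}`,
  with `Traps` the mean daily trap count over the period's active days.
* removal-cell probabilities `pi_{t,j} = p (1-p)^(j-1)` — the
  geometric first-capture distribution over days within the period.
* availability `phi_{y,t}` — probability a superpopulation member is
  present and catchable in the period; independent Beta(1,1) per
  sampled period.
* temporal suitability `zprob_y` — probability a day is suitable for
  any captures at all; its complement is the daily zero-inflation
  rate. Beta(1,1) prior (the prior family is not dictated by the
  source formulation; flat beta matches the other observation priors).

Daily removals are Poisson with mean `lam * phi * pi_j * z`, where
`lam` is the expected superpopulation and `z` the daily suitability
indicator. The fitting layer uses the z-marginalized zero-inflated
Poisson likelihood (identical marginal likelihood, no discrete
latents); the pointwise form is also the WAIC unit (one term per
year–period–day).

Derived management quantities: the period effective removal rate
`pset = 1 - (1 - p*zprob*phi)^Ndays` and the annual rate
`pyear = 1 - prod(1 - pset_t)` — the probability that an animal whose
home range overlaps the array (for the period, or all year) is
removed.

## Random-walk trend model

The expected superpopulation follows a Gaussian random walk with
drift between consecutive sampled periods,
`lam[t+1] = lam[t] + Delta[t+1] - R[t]`, `Delta ~ N(mu_trend,
sd_trend)`, where `R[t]` are the observed removals. The drift mean
varies by year (`yearly` variant) or year×season (`seasonal`); the
step SD varies by year. Seasons are the four biological blocks of the
active year (breeding Mar–Apr, hatching May–Jun, post-hatching
Jul–Aug, pre-hibernation Sep–Oct; winter periods are folded into the
adjacent labels so every period has a season). Years are linked by a
single step with Normal(0, 31.62) prior (precision 0.001 — roughly
±63 animals over the winter dormancy gap); the final sampled period's
removals are subtracted before the annual step so no removals drop
out of the accounting (the source formulation is silent here; keeping
them would bias the linked year upward by one period's catch).

Priors: `mu_trend ~ N(0, 100)`; `sd_trend ~ half-t(df=1, scale=5)`
(half-Cauchy); initial abundance `lam[0] ~ Gamma(0.5, 1e-6)`, an
approximation to Jeffreys' prior for a Poisson rate. Expected
abundances are floored at `1e-6` wherever a subtraction could turn
them negative, preserving the Poisson domain without truncating step
priors.

`M_{y,t}` (realized superpopulation) is a posterior-predictive
Poisson draw given `lam_{y,t}`, not a sampled latent — the standard
Poisson-approximation formulation of the multinomial removal model.
`Nhat = phi * lam` is the expected available abundance.

### Identifiability

Within a period the likelihood constrains only the product
`lam * phi`; the level is resolved by the availability bound
`phi <= 1`, the random-walk smoothness, the between-year link, and —
substantially — the prior volume of the flat availability priors.
Posterior medians recover simulated truths well at high removal rates
(see the post-validation study) but individual estimates are wide;
intervals over-cover nominal 95%.

## 2-age-class informed population model (InfoPM)

All ancillary information enters as informative priors on a single
likelihood (an *informed* rather than integrated population model).
The explicit "adult" class is all animals one year and older,
scalarized from an underlying age-structured matrix model; its inputs
are a scalar annual adult survival `s_ad_year` and an effective birth
rate `b` (young produced per adult that survive their first year to
recruit). Both are configuration inputs (named parametric priors in
YAML), as is annual juvenile survival `s_juv`.

Dynamics run over *every* period of the chain from the first sampled
period to the last — including unsampled winter periods, with zero
removals — because survival and migration act per period:

* per-period adult survival `s_ad = s_ad_year^(1/26)` (constant
  within the year; time-varying survival would be confounded with
  net migration).
* net migration `IE_{y,t} ~ N(mu_IE, sd_IE)` per transition, with the
  mean by year (or year×season) and SD by year; hyperpriors
  `mu_IE ~ N(0, 100)`, `sd_IE ~ half-t(1, 5)`. Because it absorbs any
  unmodeled survival variation it is best read as *apparent* net
  migration.
* a single annual birth pulse anniversaried to May 1: the cohort born
  at year `y-1`'s pulse recruits to adults at year `y`'s pulse as
  `BtA = max(B_y - Rjuv_total, 0)` with `B_y = b_{y-1} *
  lam_ad(pulse of y-1)` and `Rjuv_total` the juveniles removed since
  the previous pulse. The pre-study adult scale gets a Uniform prior
  with configurable bounds.

The implicit juvenile cohort at `omega` periods since birth is
`lam_juv = B * s_juv^((omega - 26)/26) - Rjuv_cum` (floored at 0):
`B/s_juv` newborns at the pulse decaying to the `B` recruits after a
full cycle. The displayed exponent in the source presentation has the
opposite sign, which contradicts its own stated limits; the package
implements the sign satisfying the limits. `Rjuv_cum` is a plain
cumulative sum of allocated juvenile removals, without survival
adjustment.

Juveniles become catchable through a cumulative-normal emergence
curve: relative availability `phi_juv = Phi((14*omega - mu_emerge) /
sd_emerge)`, with days-since-birth taken at period boundaries
(`14*omega`; a midpoint convention is a configurable alternative).
Default priors: `mu_emerge ~ Uniform(150, 210)` days (mean 180),
`sd_emerge` a positive-half normal with mean 60 and precision 0.005;
one pair per calendar year (juveniles observed before the pulse use
that year's curve).

The combined likelihood uses the catchable total
`lam_catch = lam_ad + phi_juv * lam_juv` in place of `lam`; with
`phi_juv = 1` it reduces exactly to the one-class model. Observed
removals are allocated by the catchable age distribution
(`pc_ad = lam_ad / lam_catch`), conserving the total exactly. Derived
quantities: the corrected superpopulation `M*` (expectation
`lam_ad + lam_juv`), the catchable fraction `p_catch = lam_catch /
(lam_ad + lam_juv)` (defined as 1 when both classes are empty), and
corrected rates `pset* = 1 - (1 - p_catch*p*zprob*phi)^Ndays`,
`pyear* = 1 - prod(1 - pset*)` — always below their uncorrected
counterparts.

The adult/juvenile split is identified *only* through the prior
information (the likelihood sees the catchable total), so the birth
rate and pre-study cohort priors play the role expert elicitation
plays on real data. `M` and `M*` differ most right after the pulse
and converge as the emergence curve saturates before the next one.

### No-removal counterfactual

For each posterior draw the dynamics recursion is re-run with all
removal terms dropped, holding survival, birth rates, emergence and
the draw's implied net-migration increments fixed. It is implemented
as an exact nonnegative delta-recursion on the estimated adult path
(`d' = d*s_ad + r_ad + (bta_cf - bta)`, `d[0] = 0`), which makes the
counterfactual bit-identical to the estimate when no removals were
observed and dominate it draw-by-draw otherwise. `M`/`M*` draws for
the two scenarios share uniform variates (Poisson quantile coupling)
so the dominance carries to the integer draws.

## Posterior computation

No probabilistic-programming backend is used; both models compile
their joint log posterior to machine code (numba) and are sampled by
a general-purpose adaptive Metropolis-within-Gibbs with extra move
families targeting the posterior's known slow directions:

* coordinatewise Gaussian random-walk updates, scales adapted in
  batches of 50 sweeps toward 0.44 acceptance (Robbins-Monro,
  frozen after warm-up); heavy-tailed scale parameters and the tiny
  capture efficiency move on the log scale;
* *ridge shifts*: a common additive shift of an abundance block
  (period, year, or whole study) with availability compensated as
  `phi' = phi*lam/lam'`, preserving every product — and hence the
  likelihood and the step priors — exactly (Jacobian
  `prod lam/lam'`); *tilts* shear a year's path linearly while moving
  its drift mean;
* a *funnel rescale* that jointly multiplies a year's step residuals
  and its step SD (the residual sums telescope, making the map affine
  with Jacobian `a^(n+1)`), letting chains traverse the narrow-SD
  funnel of the hierarchical step prior;
* exact conjugate Gibbs draws for the Gaussian drift means;
* an adaptive-covariance (Haario-style) full-vector proposal whose
  covariance is learned during warm-up and frozen afterwards.

The abundance *path* is the sampled quantity in both models; the
random-walk steps / net-migration increments it implies carry their
Gaussian priors (a unit-Jacobian reparameterization that mixes far
better under coordinatewise updates than sampling the steps).

Chains are seeded deterministically and exactly reproducible.
Convergence is all-parameter rank-normalized split-chain R-hat < 1.1
(arviz). Point estimates are posterior medians; abundance-type
quantities get 95% highest-posterior-density intervals (shortest
window containing `ceil(0.95 n)` sorted draws), everything else
central quantile intervals. The full production profile (10k
adaptation + 100k burn-in + 200k kept at thin 10 × 3 chains = 60,000
draws) is retained as `PAPER_MCMC`; tests and the desk-scale studies
use reduced profiles (typically 3 chains × (6k warm-up + 4k kept)).
The age-structured model mixes more slowly than the random-walk model
(its split and recruitment-source ridges are prior-identified);
production-quality inference for it wants chain lengths toward the
full profile.

## Goodness of fit and comparison

Freeman-Tukey discrepancy `sum (sqrt(y) - sqrt(E[y]))^2` against the
marginal expected daily removals, with full generative replicates
(suitability re-sampled from `zprob`); Bayesian p-value counts
`T_rep > T_obs` with ties worth half, and c-hat is
`mean(T_obs)/mean(T_rep)` (the standard posterior-predictive variance
inflation ratio; no closed definition exists to inherit). WAIC uses
the stable log-sum-exp `lppd` and the variance penalty, one
year–period–day observation per point; between drift variants the
simpler (yearly) model is selected whenever its WAIC is within 0.5
units of the minimum. Comparisons are meaningful within a model class.

## Synthetic data and post-validation

The generator draws, per sampled period, a realized superpopulation
`M ~ Poisson(lam)` and produces daily removals under one of three
mechanisms:

* `sequential` (default) — animals are removed day by day without
  replacement: a Bernoulli suitability flip, then a binomial catch
  over the remaining superpopulation at `phi * p` (availability as a
  fresh binomial thinning each occasion, as under temporary
  emigration; day-level binomial catches are equivalent to simulating
  individual traps under the model's independence assumptions). The
  expected period total is exactly `M * pset`, the closed-form
  effective removal rate.
* `multinomial` — availability is drawn once per period
  (`Binomial(M, phi)`: an animal is in or out of the effective area
  for the whole period) and the available pool is depleted day by day
  at the daily capture probability `p`. This is the un-approximated
  multinomial removal process with cells `phi * pi_j` that the
  models' Poisson likelihood approximates.
* `model` — daily counts come from the removal models' own
  zero-inflated Poisson form `Poisson(lam*phi*pi_j) * z`, so that
  fitting the model to the data is exactly well-specified.

Realized removals feed back into the dynamics recursion under every
mechanism. Dates are emitted as real calendar records and re-ingested
through the standard loader, so every simulation also exercises the
I/O path.

The differences between the mechanisms are informative in themselves.
The marginal fit calibration is insensitive to the choice
(Freeman-Tukey Bayesian p-values average 0.50 and c-hat 0.99 when
refitting sequential-mechanism data), but abundance point estimates
are not. Refitting `sequential` data inflates abundance (its daily
availability re-draws slow the observed within-period depletion to
`phi*p` per day where the likelihood expects `p`). Refitting `model`
data exposes the flat-availability volume pull head-on — with only
Poisson day counts, the level information is so weak that posterior
medians sit well below truth (about −19% with 59% interval coverage
at the high-signal scenario). The `multinomial` process carries
finite-pool information (periods cannot yield more removals than were
available, and late-period catches reflect pool exhaustion) that
neither approximation retains, and refitting it recovers abundance
well — the post-validation study and the package-level checks
therefore use it.

Scenario presets (all values configurable): `core-like` (λ≈900,
per-period effective removal ≈0.4, drift replacing removals),
`edge-like` (λ≈300, ≈0.25) and `sparse` (λ≈100, ≈0.15) for the
random-walk model, and `infopm-core` (adults≈500, annual removal
rate ≈0.75, birth rate 0.7, adult survival 0.7, juvenile survival
0.25) for the age-structured model. Defaults: 3 years × 16 sampled
two-week periods (6–21, mid-March to October) × 14 active days,
constant effort, sinusoidal availability 0.35–0.70, suitability 0.85.
The presets are illustrative study conditions, not estimates of any
real population.

The post-validation study simulates replicates, refits the generating
model at a reduced profile, drops non-converged fits (all-parameter
R-hat < 1.1), and reports the median percent bias of posterior-median
superpopulation, the fraction of point estimates within threshold
percentages of truth, and 95% interval coverage; fit-calibration
p-values are computed for every attempted fit (they do not depend on
the convergence gate). Package-level checks run 20 replicates of the
high-signal scenario under the multinomial mechanism; at these
settings roughly a third to a half of replicates pass the strict
all-parameter convergence gate, and the converged fits show |median
bias| well under 10% with interval coverage above 0.95. The
age-structured recovery check simulates from the model mechanism
(adult expected abundance recovered within 20% median bias with
truth-centered informative priors).

What the generator does *not* emulate: spatial structure and
trap-to-trap heterogeneity, behavioral responses to trapping, effort
that varies within a period, age-structured observation of removals,
and density dependence. Passing tests therefore validate the
estimators under the models' own assumptions, not against field
reality.

## Numerical choices

* `1-(1-theta)^traps` via `expm1/log1p` (no underflow at large
  effort); effective rates likewise.
* abundance floors at `1e-6` after any subtraction.
* zero expected counts with positive observations yield `-inf`
  log-likelihood (rejected in sampling, flagged in WAIC input
  checks) rather than exceptions.
* removal allocation conserves totals exactly by construction
  (`r_juv = R - r_ad`).
* ties in the Bayesian p-value count half; the degenerate
  both-classes-empty catchable fraction is defined as 1.
* compiled and pure-python implementations of both joint densities
  are cross-checked to 1e-10 relative tolerance in the test suite.

## Known limitations

* The coordinate sampler, even with the structured moves, needs long
  chains for the age-structured model; the strict all-parameter
  R-hat gate fails a substantial share of desk-scale fits whose
  abundance estimates are nonetheless well calibrated.
* One availability parameter per period with a flat prior means the
  abundance level leans on prior volume; hierarchical sharing of
  availability across years is a natural extension, not implemented.
* No spatial information, covariates, trap-type effects, or density
  dependence; net migration absorbs what they would explain.
* The juvenile correction rests entirely on the vital-rate and
  emergence priors; with weak priors the adult/juvenile split is
  close to unidentified before the first in-study birth pulse.
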