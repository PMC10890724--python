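# Methods

This note documents the statistical model, the data-preparation rules, the
synthetic-cohort generator, and the numerical choices made in `vlsupp`, in
enough detail to reproduce or audit any number the package prints.

## The analysis problem

People living with HIV on antiretroviral therapy (ART) have viral loads (VL)
measured on a fixed schedule — weeks 12 and 24 after starting or switching
therapy, then every 24 weeks. The quantity of interest is the probability of
viral-load *suppression* (HIV-1 RNA < 50 copies/mL, strict inequality) at
weeks 12, 24, 48, 72 and 96, compared across three regimens: first-line
efavirenz-based ART (EFV) and second-line ritonavir-boosted atazanavir
(ATV/r) or dolutegravir (DTG) based ART. Because each person contributes up
to five binary outcomes, within-person correlation must be modelled, and
because second-line patients differ systematically from first-line patients
(younger, lower CD4 at switch), regimen comparisons benefit from
standardization to a common covariate distribution.

## Data preparation

Input is two tables: one row per person (baseline covariates, regimen, line,
baseline and end-of-follow-up dates) and one row per dated VL measurement.

* **Inclusion.** Persons aged >= 12 years at baseline with >= 24 weeks
  (exactly 168 days, inclusive) between baseline and end of follow-up.
* **Visit windows.** All date arithmetic is in integer days since the
  person's baseline. The scheduled week *w* covers days `7w ± 28` inclusive
  ("one month" is read as exactly four weeks, so the week-24 window is
  24 ± 4 weeks = days 140–196). Windows are disjoint with gaps; a
  measurement in a gap (e.g. day 245 = week 35) belongs to no visit.
  Measurements at day < 56 (the baseline sample) are likewise unassigned.
* **Selection.** If several measurements fall in one window, the one closest
  to the window centre `7w` is used; exact distance ties go to the earlier
  day (a deterministic choice; the tie is not otherwise identified).
* **Sandwich imputation.** A week with no in-window measurement is imputed
  only when the person has measurements strictly before the window start and
  strictly after the window end — in-window measurements of adjacent weeks
  and gap measurements both qualify; the baseline sample (day <= 0) never
  does — and the nearest such neighbour on each side agrees on the < 50
  dichotomy. Discordant neighbours leave the week missing, so imputation can
  never create a viral blip or its inverse. Imputed rows are flagged
  (`provenance = imputed`) and counted; `complete_case=True` drops them
  (the sensitivity analysis) and changes nothing else.
* **Covariate binning.** Age 12–19 / 20–29 / 30–39 / 40+ years; CD4
  < 200 / 200–349 / >= 350 cells/mm³.

A consequence of the nearest-neighbour sandwich rule worth knowing: at
realistic attendance (~60–85% per scheduled week), most missed middle visits
are flanked by the adjacent weeks' measurements, and since suppression
status is strongly persistent within person, a sizeable share of missed
visits is imputable (roughly 13% of analysis rows in the default synthetic
cohort). Imputed rows mechanically duplicate their neighbours' statuses;
they are *not* independent Bernoulli outcomes of the model, and fitting on
the full table inflates the apparent persistence (larger week effects and
random-intercept SD) relative to the complete-case fit. Parameter-recovery
tests therefore run on the complete-case table, whose rows are exactly
model-generated.

## The model

For observation *j* of person *i(j)*:

    y_j | beta, u  ~  Bernoulli( expit( x_j' beta + u_i(j) ) )
    u_i | sigma_u  ~  Normal(0, sigma_u^2)
    beta_p         ~  Normal(0, 2.5^2)        (each coefficient)
    sigma_u        ~  half-Normal(1)

`x_j` dummy-codes regimen, week, sex, age group and CD4 group against the
references EFV / week 12 / female / 12–19 / < 200, plus any selected two-way
interactions (products of main-effect dummies). The references are chosen so
regimen-versus-EFV contrasts by week read directly off the coefficients.
The priors are weakly informative defaults (configurable via
`coef_prior_scale`, `re_sd_prior`); with thousands of observations the
posterior is data-dominated and the exact weakly-informative scale is
immaterial, which the sampler-versus-oracle tests quantify.

### Sampling

The posterior is sampled by an exact Gibbs scheme with Pólya-Gamma (PG) data
augmentation: `omega_j ~ PG(1, eta_j)` renders the conditionals for `beta`
and `u` Gaussian. The PG(1, z) variates come from a self-contained
implementation of the Devroye alternating-series sampler (numba-compiled;
verified against the closed-form mean `tanh(z/2)/(2z)` and variance).
Two refinements matter for mixing:

* **Collapsed beta update.** `beta` is drawn with the person intercepts
  integrated out (a per-person Woodbury correction to the Gaussian
  precision), removing the strong beta–u coupling of naive alternation.
* **Interweaving for sigma_u.** After a slice-sampling update of `sigma_u`
  given the centered intercepts, `sigma_u` is re-drawn in the non-centered
  parametrization `u = sigma_u * v`, where its full conditional under PG
  augmentation is an exact zero-truncated Normal.

With these, fixed effects reach an effective sample size of roughly 40–100%
of the stored draws; `sigma_u` remains the slowest component at ~15–20%
efficiency, which the default chain lengths (4 chains x 2,500 sweeps,
1,000 warmup) absorb comfortably. Warmup is pure burn-in (Gibbs needs no
adaptation). Every kept draw stores the conditional pointwise log-likelihood
`log p(y_j | beta_s, u_s)` for the ELPD machinery.

Convergence is summarized by split-R-hat and bulk ESS (via ArviZ) per fixed
effect and for `sigma_u`; a fit is declared converged iff max R-hat < 1.01
and min ESS > 400. Zero-row inputs reproduce the prior exactly (used as a
test); `random_intercept=False` pins `sigma_u = 0` for plain logistic
regression (used by the brute-force oracle comparisons).

## Interaction selection

Model fit is compared by expected log pointwise predictive density (ELPD)
in WAIC form, computed from the conditional (observation-level) pointwise
log-likelihood:

    lpd_j = log mean_s exp loglik[s, j],   p_j = var_s loglik[s, j]
    elpd  = sum_j (lpd_j - p_j),           se = sqrt(n * var_j(lpd_j - p_j))

Conditioning on the sampled intercepts (rather than marginalizing them per
person) is the cheapest consistent choice and standard for hierarchical
models. Selection is two-step: (1) fit the no-interaction base model and
the base plus each candidate two-way interaction; a candidate is *eligible*
iff its paired ELPD gain strictly exceeds twice the standard error of the
difference; (2) fit every subset of the eligible interactions and keep the
subset with the highest ELPD, breaking exact ties toward fewer terms.
Candidate order cannot affect the result (candidates are canonicalized and
per-fit seeds derive from the subset's content). A non-convergent fit
aborts selection by default; the large-replication recovery tests disable
that gate and use shorter chains, since ELPD differences are averages over
draws and are insensitive to the moderate autocorrelation that trips the
strict ESS threshold.

## Marginal (population-averaged) estimates

The fitted model is conditional on `u`. Every reported effect integrates the
conditional probability over the *population* random-effect distribution,
per posterior draw `s`:

    p(eta, sigma_s) = ∫ expit(eta + u) dN(u; 0, sigma_s^2)

by Gauss–Hermite quadrature with the change of variables `u = sqrt(2) sigma z`
(31 nodes by default; measured accuracy ~2e-5 over eta in [-4, 4],
sigma <= 3, converging to < 1e-6 by 63→127 nodes; `sigma = 0` is
special-cased to the exact `expit(eta)`). Integrating over the population
distribution rather than the fitted person intercepts matches the
"sample-averaged" population reading and applies identically to
counterfactual regimens.

* **Marginal aOR** of profile A vs profile B: per draw, the odds ratio of
  the two marginalized probabilities (sharing that draw's `sigma_s`);
  summarized by the posterior median and central 95% credible interval.
  Marginal odds ratios are attenuated: strictly between 1 and the
  conditional OR whenever `sigma_u > 0` — an invariant under test.
* **Standardized predictions** (g-computation): for each week and each
  counterfactual regimen, the marginal probability is averaged over *every*
  person's observed sex/age/CD4 profile (implemented over unique covariate
  profiles with counts — algebraically identical to the per-person loop,
  which a test verifies), then summarized over draws.
* **Non-standardized predictions** average only over the persons actually
  contributing an observation in that (week, regimen) stratum.
* **Crude proportions** use a Beta(k+1, n−k+1) central 95% interval
  (uniform prior; within-person clustering deliberately ignored — these are
  descriptive).

Posterior point summaries are medians throughout (robust; the interval is
the 2.5–97.5% quantile pair).

## The synthetic-cohort generator

The generator emulates the cohort structure the analysis assumes, with every
knob exposed in `SimulationConfig`:

* 2,163 persons by default, split 1,049 / 872 / 242 across EFV / ATV/r /
  DTG; ~60% female; regimen-specific age- and CD4-group distributions
  mirroring a realistic first- vs second-line case mix (second-line switchers
  younger and with lower CD4).
* Baseline calendar dates drawn uniformly per regimen (EFV/ATV/r from
  2013–2019, DTG only from mid-2019), with follow-up administratively
  censored at database closure (Aug 2022) or 700 days, whichever is earlier.
  This reproduces the key regimen-dependent censoring pattern — late-week
  measurements are scarce for DTG because DTG starters are recent — through
  the actual mechanism rather than an ad-hoc dial. `censor_week` additionally
  caps the scheduled weeks per regimen (default 96 for all).
* Attendance: per regimen-and-week probability that a scheduled visit under
  follow-up yields a measurement (defaults ~0.6–0.85, lower at weeks 72/96).
  Visit dates get Normal(0, 7 days) jitter rounded to whole days; with
  probability 0.05 a visit instead shifts uniformly 29–56 days (either
  direction) to guarantee out-of-window measurements that exercise the
  imputation path. Loss to follow-up and death are off by default
  (`ltfu_prob`, `death_prob`) as they are rare in the emulated setting.
* Outcomes run the analysis model forward: one `u_i ~ N(0, sigma_u^2)` per
  person (default `sigma_u = 1`, a moderate within-person correlation chosen
  by us — the within-person correlation is exposed, not asserted), and a
  Bernoulli suppression indicator per attended week with probability
  `expit(x'beta + u_i)`. The default `true_beta` (logit scale, named by
  design column) encodes the qualitative pattern of interest: EFV rising to
  a high plateau by week 48, second-line plateauing lower via negative
  regimen-by-week interactions, DTG fastest at week 12, suppression
  increasing with age and CD4, lower in males. Suppressed outcomes emit an
  integer VL uniform on [0, 49] copies/mL, unsuppressed on [200, 100000];
  only the < 50 dichotomy matters downstream.

What the generator does **not** emulate: drug resistance, adherence
dynamics, mid-follow-up regimen switches, CD4 trajectories, calendar-time
confounding (e.g. pandemic-era effects), or informative missingness —
attendance is missing-completely-at-random given regimen and week. Passing
recovery tests therefore demonstrate that the inference machinery is
correct for data meeting the model's assumptions, not that those
assumptions hold in any particular clinic's records.

## Problem sizes and numerical choices

* Default pipeline fit: 4 chains x 2,500 sweeps (1,000 warmup). Selection
  fits: 4 x 1,250 (375 warmup) over all 10 covariate pairs.
* Recovery/selection replications in the test suite: 20 cohorts of 2,000
  persons, complete-case tables (~6,500 rows), three-candidate selection
  (the true regimen-by-week pair plus two decoys) with 2 x 700-sweep chains
  — sizes chosen to keep the full suite fast while leaving the eligibility
  margin large (ELPD gain ≈ 5 SE at this n).
* Gibbs initialization: `beta = 0`, `u = 0`, `sigma_u` at its prior scale;
  results are initialization-insensitive well within warmup.
* The degenerate empty-eligible-set case returns the base model; empty
  prediction strata are omitted with a warning; probabilities numerically
  at 0/1 inside odds ratios are clamped at 1e-12 with a warning.
* All randomness flows from explicit integer seeds (simulation seed;
  per-chain seeds spawned via `SeedSequence`; per-subset selection seeds
  derived from the subset's canonical name), so identical configs reproduce
  identical outputs byte-for-byte.

## Known limitations

* WAIC (not PSIS-LOO) is the ELPD estimator; for these sample sizes and
  this model family the two agree closely, but WAIC's penalty can be
  optimistic for highly influential observations.
* Marginal aORs are evaluated at a stated covariate profile (the reference
  levels, in the pipeline reports); with interactions absent between regimen
  and the profile covariates the conditional contrast is profile-invariant,
  but the marginalized contrast retains a mild profile dependence.
* The crude-proportion intervals ignore repeated measures; they are
  descriptive companions to the model-based estimates, not substitutes.
* `sigma_u` is time-constant per person; random slopes and serial
  correlation within person are out of scope.
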