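# Methods

## Study design being emulated

A population of urban family physicians transitions from traditional
fee-for-service (tFFS) to a rostering-enhanced fee-for-service model (eFFS)
in staggered fiscal years 2004–2011, with ~86% transitioning early
(2004–2006).  Outcomes are followed yearly over fiscal 2000–2013 (the
FPSC emergency-department outcome over 2003–2013, reflecting an ED coding
change before 2003).  Fiscal years run April–March and are labelled by
their starting calendar year; the package simulates no within-year timing.

Because the two-year attribution and UPC windows need the year before the
first analysis year, the simulator generates one burn-in claims year
(study_start − 1).  Analysis years then span the full study window and
physicians transitioning in 2004 retain the required four pre-transition
years.

## The synthetic data-generating process

**Population.**  Physicians carry sex, graduation year, foreign training,
a transition year drawn from the configured mix, optional exit year
(transfer to capitation, censoring follow-up), optional prolonged-absence
year, and a practice group of 3–5 members formed within each
transition-year cohort.  Patients are assigned permanently to one home
physician; panels are lognormal (default mean 300).  Patient covariates
(age, sex, income quintile, rurality, morbidity band) follow the marginals
of the emulated study population.

**Visit loyalty (UPC process).**  For patient *i* of physician *j* in year
*t*, the probability that a primary-care visit goes to the home physician
is a segmented linear trajectory on the percentage scale,

    p_ijt = clip( (β₀ + γ'x_i + u_j + β₁t + β₂·post_jt + β₃·tst_jt + δ·early_j) / 100 , 0.01, 1.0 ),

with independent physician random effects on all four segment terms and an
early-adopter baseline offset δ.  Clipping events are counted and logged.
Annual visit counts are gamma-Poisson (overdispersed) with means rising in
the morbidity band — defaults (2.5, 4.0, 6.5, 9.0) visits/year.  These
were chosen so that two-year fee-based attribution is reliable (2–4%
misattribution) while a few percent of patients still fall under the
<3-visit UPC exclusion.  Non-home visits go to a random group colleague
with probability 0.8 once the home physician has transitioned (encoding
within-group after-hours sharing, and making group-level UPC exceed
provider-level UPC), otherwise to a random other physician.

**Billing dialect.**  Eighteen symbolic core service categories plus four
non-core ones.  Comprehensive physicians bill 12 distinct core categories;
a configurable fraction bills only 5 (failing the 8-of-18 comprehensiveness
rule).  All core visits share one fee so that fee-sum attribution reduces
to visit-count attribution; fee realism is irrelevant to every downstream
quantity.  Occasional non-visit fee items are excluded from attribution
and outcomes by the `is_primary_care_visit` flag.

**Referrals (RI process).**  Each referral is generated from an existing
visit; the referring physician is the visit's physician.  Home and
non-home visits refer at different rates: the home-visit rate is set per
patient-year via the odds relation r_h/r_o = odds(q_jt)·(1−p_ijt)/p_ijt,
which makes the expected share of a panel's referrals made by the home
physician equal the planted physician-level concentration trajectory q_jt
*exactly*, independent of patient loyalty.  When the implied home rate
would exceed 1 both rates are scaled down, preserving the ratio.  A
configured share (default 0.30) of referrals is flagged diagnostic
radiology and excluded from the RI.

**FPSC emergency-department events.**  Per patient-year Bernoulli draws
with log-odds following the planted segmented trajectory plus covariate
effects and a physician random intercept; a background rate of non-FPSC ED
events is included.  Records exist only inside the ED window.

**Planted values.**  The four segment coefficients of each outcome default
to the published adjusted estimates (UPC −0.27/+0.39/−0.59 %/yr; RI
−0.0014/+0.29/−0.34; FPSC 0.018/−0.010/−0.011 log-odds), with
early-adopter baseline offsets +7.02 (UPC) and +9.17 (RI).  Baseline
intercepts are chosen so population-mean loyalty matches the published
unadjusted baseline UPC (~76%) and FPSC prevalence sits near 4%.
Covariate effects are deliberately modest (sign-matched to the published
tables, smaller in magnitude) so the percent-scale predictor stays well
inside (1, 100); the published covariate coefficients at realistic
covariate ranges would push loyalty past 100 and clip heavily.  The full
truth table is serialized beside every simulated dataset.

## Cohort construction

Attribution assigns each patient-year to the physician with the largest
primary-care fee total over {year−1, year}; fee ties go to the physician
with more window visits, then to the smallest physician id (deterministic
and testable; the source analysis states no rule).  Physician-years
require comprehensiveness (≥8 distinct core categories billed), panel ≥100
("fewer than 100" excludes 99 and keeps 100), and no prolonged absence;
years from the exit year onward are censored.  Physicians need ≥4 eligible
pre-transition and ≥2 eligible post-transition years; only eligible years
count.  Patients require valid coverage, being alive at fiscal year end,
attribution to an in-study physician, and ≥1 primary-care visit to that
physician within the two-year window.

## Outcomes

UPC: percent of window primary-care visits made to the attributed
physician; missing under 3 window visits.  "Main provider" is the
attributed physician — attribution and the UPC share one window, so the
two notions coincide except under fee/visit discordance.  Group UPC counts
visits to any member of the attributed physician's practice group
(post-transition years only).  RI: per physician-year, referrals pooled
over rostered patients (referral-weighted, not a mean of per-patient
percentages), non-radiology only, single fiscal year (the outcome is
reported per physician-year; no window is stated in the source, so this is
a documented assumption).  FPSC: 1 if the patient had ≥1 FPSC ED visit
that year, missing outside the ED window.

## Segmented mixed-effects regression

Fixed effects: intercept, time (years since study start), post, tst
(years since transition), plus patient and provider covariates with
reference levels male / income quintile 1 / urban / morbidity band 0 /
panel <500.  Random effects: independent per-physician deviations on
intercept, time, post and tst (diagonal covariance); on non-convergence
the fit walks down a documented ladder — {intercept, time}, then a random
intercept alone — trying lbfgs, bfgs and powell at each rung, and flags
(never silently accepts) a final non-convergence.  Linear outcomes use
REML; convergence demands finite standard errors below a sanity bound
(degenerate optimizer solutions can otherwise masquerade as converged).

**Transition-year coding.**  Outcomes are measured over two-year windows,
so the transition-year observation straddles the behavioral switch: its
window averages roughly half pre- and half post-transition behavior.  The
package therefore codes the transition year as the *last pre-period*
observation; `post` switches on in the following year and `tst` counts
years since the transition year, so the first post row has post = 1,
tst = 1.  β₂ then measures the level change at the first fully
post-transition window.  With the more common alternative (post = 1, tst
= 0 in the transition year itself), the half-mixed window sits inside the
post segment and attenuates the recovered change in slope by roughly 0.05
%/yr at default conditions — a measurement artifact, not a property of
the planted process.  The source analysis does not state its choice.

**Logistic fit.**  The binary FPSC model uses a physician random intercept
only and is estimated by Laplace-approximate posterior maximization
(`BinomialBayesMixedGLM.fit_map` with a deterministic start).  Its point
estimates track the marginal-likelihood MLE closely (verified against an
independent GLMM implementation during development), but the posterior
standard deviations understate cluster-level uncertainty; CIs from this
fit are labelled approximate.  The variational-Bayes alternative was
rejected: its fixed-effect posterior means are visibly biased on data of
this shape.  Full random-slope logistic fits are out of scope.

**Derived effects.**  Post-transition slope β₁+β₃; cumulative k-year
change k·(β₁+β₃); per-year odds ratios exp(β₁) and exp(β₁+β₃) with
delta-method CIs.  Predicted trajectories fix covariates at a mean/mode
profile (41-year-old urban female patient, income quintile 5, second
morbidity band, male Canadian-trained physician 25 years post-graduation,
panel 1000–1999).  Linearity diagnostics report unadjusted yearly means
with straight-line fits and R² for the overall population and each
transition-year cohort, without gating anything.

Time origin is fiscal 2000 = 0 (affects only the intercept — tested).
Income quintile is an unordered category with quintile 1 (highest income)
as reference.  No multiple-testing correction; Wald 95% CIs.

## What recovery tests do and do not show

The simulator reproduces the *structure* of the emulated study — staggered
adoption, clustered patients, two-year windows, eligibility filtering —
with planted linear trajectories.  Passing recovery tests show the
pipeline's bookkeeping and estimation are faithful; they do not show that
real claims follow segmented-linear dynamics, that real attribution error
is as benign as the simulated 2–4% (real virtual rostering misclassifies
up to ~15%), or that unmodelled phenomena (patient turnover between
providers, within-year timing, secular fee-schedule changes) are
ignorable.

Two measurement artifacts survive by design and are documented rather
than removed: attribution error grows as loyalty declines, slightly
attenuating slopes; and eligibility selection (≥1 visit to the attributed
physician) mildly truncates the low-loyalty tail.

## Problem sizes and replication

Default study conditions: 150 physicians, mean panel 300 (~45k patients),
14 fiscal years — about half a million eligible patient-year rows.  The
per-replicate Monte-Carlo standard error of a recovered change-in-slope
coefficient at this scale is ~0.05 %/yr (linear outcomes) and ~0.01
(FPSC log-odds), so recovery checks average estimates over a set of
replicate seeds sized so that the Monte-Carlo SEM of the averaged estimate
is roughly a third of the corresponding recovery tolerance; the acceptance
script derives all replicate seeds from its single `--seed` argument.  Unit and property tests run on smaller
configurations (6–16 physicians) where every rule is still exercised.
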