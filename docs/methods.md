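# Methods

## The estimand and the hybrid estimator

The quantity of interest is the mean quality-adjusted life years (QALY)
over the remaining lifetime of a group — survival time weighted by a
preference-based health utility anchored at 0 (death) and 1 (perfect
health) — estimated from a survey cohort with mortality follow-up that
ends administratively long before most participants die. Estimating a
*remaining-lifetime* mean from a few years of follow-up forces an
extrapolation, and fully parametric survival models tend to fit the early
follow-up well while misrepresenting the tail. The estimator therefore
splits the mean QALY at the end-of-follow-up horizon L:

**Follow-up part (0, L].** Let 0 < t₁ ≤ … ≤ t_l < L be the death times and
Ŝ(t) the weighted product-limit (Kaplan-Meier) survival estimate, with
t₀ = 0 and Ŝ(0) = 1. With Q̂(t_j) the weighted mean QALY accumulated by
those dying at t_j, and Q̂(L) by those alive at the end of follow-up,

    QALY(0, L] = Σⱼ Q̂(t_j)·[Ŝ(t_{j−1}) − Ŝ(t_j)] + Q̂(L)·Ŝ(t_l).

**Tail part (L, ∞).** A Weibull model S_p(t) = exp[−(t/λ)^β] is fitted to
the same follow-up data by weighted right-censored maximum likelihood.
Its implied total life expectancy is λ̂Γ(1 + 1/β̂); subtracting the
life-years already accounted for inside (0, L] — the restricted mean
∫₀ᴸ Ŝ(t) dt from the Kaplan-Meier curve — and valuing the difference at
the survivors' mean utility q̂(L) gives

    QALY(L, ∞) = q̂(L)·{ λ̂Γ(1 + 1/β̂) − ∫₀ᴸ Ŝ(t) dt }.

The parametric model supplies only the *excess* over the restricted mean,
so lack of tail fit inside the window cannot distort the follow-up part.

### Conventions and numerical choices

- **Constant-utility accrual.** Utility is measured once at baseline, so
  an individual's quality-adjusted time to t is utility × t. This makes
  Q̂(t_j) the weighted mean of utility·t_j among deaths at t_j, and is the
  only option when no repeated utility measurements exist. With utility
  identically 1 the whole estimator algebraically collapses to the hybrid
  life-expectancy estimate λ̂Γ(1 + 1/β̂) (asserted in the tests).
- **Survivor pool.** "Alive at the end of follow-up" is implemented as
  all administratively censored records (event = 0). Under a common
  censoring time at L this is exactly the at-risk set at L; under
  staggered entry against a common calendar end (the realistic design,
  and the generator's default) the literal at-risk-at-L set degenerates
  to the single longest-followed record, so the censored pool is the
  meaningful estimator of the survivors' utility distribution.
- **Ties** at a death time form one product-limit step; a censoring tied
  with a death stays at risk for that death (standard convention).
- **Times beyond L** are clamped to L with a warning (none arise in
  well-formed data).
- **Weibull optimisation** is over (log λ, log β) with Nelder-Mead,
  tolerance 1e-8, starting from β = 1 and the exponential MLE
  λ₀ = Σwᵢtᵢ/Σwᵢδᵢ. Weights are normalised to mean 1 first, which makes
  the fit invariant (to optimiser tolerance) under rescaling all weights.
  Non-convergence returns a flagged estimate with a warning, never
  silently. Fewer than two distinct event times is an estimation error.
- **Negative tails** (fitted Weibull mean below the restricted mean) are
  possible by construction; they are kept and warned about, since
  flooring at zero would bias group contrasts.
- **Standard errors** come from a nonparametric bootstrap over
  participants (weights resampled with their records; default B = 500),
  re-running the entire pipeline — including the propensity model in
  contrasts — per replicate. Degenerate resamples (no events, or no
  survivors) are skipped. A survey-design (linearisation) variance is out
  of scope because the package does not model strata/PSUs.
- **Time origin** is study entry; age is a covariate, not the time scale.

## Severity scoring and utility mapping

PHQ-9 totals (0-27, sum of nine items scored 0-3) are binned as
none/minimal 0-4, mild 5-9, moderate 10-14, moderately severe 15-19,
severe 20-27; analyses carry both this five-level labelling and a
four-level one that merges the top two bands (15-27), which is the
grouping used for group-level estimates because severe scores are rare in
elderly community samples. MDD is a total ≥ 10. Records with any missing
item have an undefined total and are excluded from severity analyses,
with a logged count — no imputation. If a table carries both items and a
precomputed total, disagreement is a blocking validation error.

Utilities come either from a precomputed `eq5d` column or from the four
CDC Healthy Days responses plus age through an additive mapping with a
pluggable coefficient table. The built-in coefficients
(u = 1 − 0.07·(genhlth−1) − 0.20·phys/30 − 0.15·ment/30 − 0.25·limit/30 −
0.001·(age−65), clipped to [0, 1]) are a documented stand-in that
reproduces the qualitative behaviour of published mappings — the perfect
health anchor at 1, monotone decline in every morbidity field, a mild age
gradient — not a fitted regression. The utility floor is configurable
because published EQ-5D value sets allow states worse than death.

## Propensity-balanced contrasts

QALY loss for a contrast (e.g. MDD 10-27 vs no MDD 0-9) is
loss = QALY_ref − QALY_exposed and percent loss = 100·loss/QALY_ref,
displayed as 1 decimal (years) and whole percent; internal arithmetic is
full precision. Group composition differences in age and sex are handled
with stabilised inverse-probability weights from a weighted logistic
model of exposure (exposed: p̄/ê; reference: (1−p̄)/(1−ê); scores trimmed
at 1e-6 with a logged count). IPW was chosen over matching or
stratification because the balance weights simply multiply the survey
weights and flow through the weighted Kaplan-Meier machinery unchanged.
Constant covariates are dropped, so a covariate-free cohort reduces to
the weighted exposed fraction. A contrast arm with too few events for the
Weibull tail yields a result flagged `estimable=False` rather than an
exception or a silent drop.

## The synthetic cohort generator

The generator emulates the structure of a 65+ national health-survey
cohort linked to a death registry: four collapsed severity categories
with prevalences 0.821/0.138/0.032/0.009; per-category baseline utilities
Beta-distributed (concentration 15) around means 0.875/0.680/0.482/0.353
rescaled to [floor, 1]; per-category Weibull death times with shape 1.3
(a mildly increasing hazard, appropriate for an elderly cohort) and
scales calibrated by root-finding so that the expected deaths per 100
person-years under the default censoring window equal
2.99/4.69/4.97/8.15; administrative censoring uniform on 1.5-6.5 years
(staggered survey entry against one calendar end — the per-wave follow-up
distribution is not published, so this window is an assumption recorded
in the spec echo); lognormal(0, 0.5) survey weights independent of
outcomes; ages truncated-normal (73.3 ± 5.7 on [65, 95]); 55.4% female.
PHQ-9 totals are uniform over the assigned category's score range — the
simplest distribution consistent with the binning — and item vectors are
drawn uniformly among the compositions of the total into nine parts ≤ 3.

Because utility and death time are conditionally independent given
category, the group mean QALY has the closed form u_c·λ_c·Γ(1 + 1/β_c),
making the generator an analytic oracle for recovery tests. Switches
exist for stress tests that void that closed form: a Gaussian-copula
utility-hazard correlation, outcome-linked weights, loss to follow-up,
and an age-tilted severity assignment (used to generate real confounding
for the propensity balance checks).

What the generator does **not** emulate: the survey's multistage design
(strata/PSUs, nonresponse adjustment), any real joint structure between
Healthy Days answers and EQ-5D beyond a monotone stand-in, competing
risks, and utility drift over time. Passing recovery tests therefore
demonstrates internal consistency of the estimator under the stated
sampling model, not agreement with any particular survey's published
estimates.

## Problem sizes used by the test suite

Exhaustive product-limit cross-checks enumerate every event pattern on
fixtures of up to 8 records. Weibull parameter recovery uses n = 5,000
with ~20% administrative censoring (5% tolerance, comfortably above the
~1-2% sampling error there). End-to-end recovery uses four
single-category cohorts of n = 20,000 (3% tolerance) plus a mixed cohort
for the severity gradient, and a null contrast at n = 8,000 with B = 200
bootstrap replicates; the replicate-mean consistency check uses 40
cohorts of n = 2,000 per category against 2 Monte-Carlo SEs. At the
calibrated mortality rates most of the remaining-lifetime QALY lies
beyond the censoring window, so single-cohort estimates carry a 2-3%
sampling SD even at n = 20,000 — the dominant uncertainty is the
extrapolation's shape parameter, which is also why the bootstrap SEs
reported for group estimates are not small.

## Known limitations

- The tail rests entirely on the Weibull family; no goodness-of-fit test
  guards the extrapolation, and the log-likelihood is exposed for users
  who want to compare candidate tails.
- Utilities are baseline-constant; declining health near death makes the
  follow-up part an overestimate in real data (regression-to-the-mean in
  mapped utilities works in the same direction).
- Propensity balancing covers measured covariates only (age and sex by
  default; the covariate list is extensible).
- Bootstrap SEs ignore the survey's design effect beyond the weights.
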