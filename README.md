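# qalypy

Estimating the mean **quality-adjusted life years (QALY) over the
remaining lifetime** by depressive-symptom severity, from survey cohorts
with limited mortality follow-up.

QALY weight each year of life by a health utility anchored at 0 (death)
and 1 (perfect health), so a year lived at utility 0.5 counts as half a
quality-adjusted year. The package is aimed at epidemiologists and
health-economics analysts working with cohorts like NHANES linked to
death-registry follow-up: participants are scored with the 9-item
Patient Health Questionnaire (PHQ-9; severity bands 0-4 / 5-9 / 10-14 /
15-27, major depressive disorder = total ≥ 10), utilities come from an
EQ-5D index or a pluggable Healthy Days mapping, and the burden of
depression is summarised as the QALY *loss* of an exposed severity group
against its reference group.

## The estimator

Most participants are alive when follow-up ends at horizon L, so the
remaining-lifetime mean is split into two parts:

- **Follow-up (0, L]**, from the weighted Kaplan-Meier curve Ŝ and the
  mean quality-adjusted time of deaths at each event time and of
  survivors at L:

      Σⱼ Q̂(tⱼ)·[Ŝ(tⱼ₋₁) − Ŝ(tⱼ)] + Q̂(L)·Ŝ(t_l),   t₀ = 0, Ŝ(0) = 1

- **Tail (L, ∞)**, by valuing the Weibull-extrapolated excess life
  expectancy at the survivors' mean utility q̂(L):

      q̂(L)·{ λ̂Γ(1 + 1/β̂) − ∫₀ᴸ Ŝ(t) dt },   S_p(t) = exp[−(t/λ)^β]

with λ̂, β̂ from weighted right-censored maximum likelihood. Group
contrasts (loss in years and as a percent of the reference QALY) are
balanced on age and sex with stabilised inverse-probability-of-exposure
weights that multiply the survey weights; standard errors come from a
bootstrap over participants that re-runs the whole pipeline. A
calibrated synthetic-cohort generator with an analytic ground truth
(u·λ·Γ(1 + 1/β) per category) makes every stage testable without any
restricted microdata. Details: [docs/methods.md](docs/methods.md).

## Worked example

```sh
qalypy simulate --n 20000 --seed 20110 --out demo
qalypy analyze --cohort demo/cohort.csv --bootstrap 50 --seed 1 --out demo_results
```

prints the per-severity summary

```
     severity phq_range     n  mean_utility  mortality_per_100py   qaly  qaly_se  qaly_followup  qaly_tail
 none_minimal       0-4 16346         0.875                2.958 17.338    0.837          5.179     12.159
         mild       5-9  2814         0.681                4.401  8.665    0.688          3.804      4.861
     moderate     10-14   663         0.482                4.932  6.829    1.240          2.657      4.171
modsev_severe     15-27   177         0.352                9.627  2.872    0.446          1.831      1.041
```

Reading the first row: 16,346 participants with none/minimal symptoms
had mean baseline utility 0.875 and 2.96 deaths per 100 person-years;
their estimated remaining-lifetime QALY is 17.3 years (SE 0.8), of which
5.2 quality-adjusted years accrue inside the ~6.5-year follow-up window
and 12.2 come from the Weibull tail. Utility, mortality and QALY move
monotonically with severity. `demo_results/contrasts.csv` holds the five
standard loss contrasts (MDD, moderate, moderately-severe/severe, mild,
any depression), e.g. MDD vs no MDD: 15.5 vs 5.5 QALY, a loss of 9.9
years (64%), with bootstrap SEs. `demo/truth.csv` carries the
generator's analytic per-category QALY for recovery checks, and
`qalypy validate --cohort <csv>` reports schema problems with row and
column coordinates.

The same machinery is available as a library — sklearn-style
(`HybridQalyEstimator`, `PropensityWeighter`, `HealthyDaysToEQ5D`) or as
functions (`fit_km`, `fit_weibull`, `total_qaly`, `run_contrast`, ...):

```python
from qalypy import HybridQalyEstimator, generate_cohort, default_spec

cohort = generate_cohort(default_spec(n=5000, seed=7))
est = HybridQalyEstimator(bootstrap=200, seed=7).fit(
    cohort.rename(columns={"eq5d": "utility"})[
        ["time", "event", "weight", "utility"]])
print(est.total_qaly_, est.se_, est.weibull_.scale, est.weibull_.shape)
```

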