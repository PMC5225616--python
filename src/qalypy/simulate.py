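"""Synthetic survey-cohort generator with known ground truth.

Emulates the structure of a national health-survey cohort of adults aged 65+
linked to death-registry follow-up: four collapsed depressive-symptom
severity categories with realistic prevalences, baseline EQ-5D-like
utilities that decline with severity, per-category Weibull times to death
with mortality rates that rise with severity, administrative right
censoring at a common calendar end (hence staggered follow-up windows),
and unequal survey weights.

Because utility and death time are drawn conditionally independent given
severity category (by default), the group mean remaining-lifetime QALY has
the closed form  u_c · λ_c · Γ(1 + 1/β_c), which makes the generator a
ground-truth oracle for estimator-recovery tests.

Default calibration targets (cohort of US adults 65+):

========  ==========  =============  ========================
category  prevalence  utility mean   mortality rate /100 PY
========  ==========  =============  ========================
0-4       0.821       0.875          2.99
5-9       0.138       0.680          4.69
10-14     0.032       0.482          4.97
15-27     0.009       0.353          8.15
========  ==========  =============  ========================

The Weibull scale per category is derived at spec-construction time by
root-finding so the expected events per person-year under the default
censoring window matches the target rate (shape fixed at 1.3, a mildly
increasing hazard appropriate for an elderly cohort).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .errors import ConfigurationError, InputError
from .phq9 import COLLAPSED_LABELS, COLLAPSED_RANGES

__all__ = [
    "COHORT_COLUMNS",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "true_group_qaly",
    "truth_table",
    "expected_mortality_rate",
    "calibrate_weibull_scale",
]

#: exact cohort CSV header, in order; the analyzer reads this schema
COHORT_COLUMNS = [
    "id", "age", "sex", "weight",
    "phq1", "phq2", "phq3", "phq4", "phq5", "phq6", "phq7", "phq8", "phq9",
    "phq_total", "genhlth", "physdays", "mentdays", "actdays", "eq5d",
    "n_comorbid", "income_fpl_ratio", "education", "married",
    "time", "event", "severity", "true_death_time",
]


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of the synthetic cohort generator.

    Per-category dictionaries are keyed by the four collapsed severity
    labels.  ``followup_window`` is the (min, max) administrative censoring
    time in years — staggered survey entry against a common calendar end.
    ``utility_hazard_correlation`` (default 0) switches on a Gaussian-copula
    dependence between utility and death time within category; nonzero
    values void the closed-form group truth.  ``informative_weights``
    couples survey weights to utility for stress tests.
    """

    n: int = 10_000
    seed: int = 20110
    category_prevalence: Dict[str, float] = field(default_factory=dict)
    utility_mean: Dict[str, float] = field(default_factory=dict)
    utility_concentration: Dict[str, float] = field(default_factory=dict)
    weibull_scale: Dict[str, float] = field(default_factory=dict)
    weibull_shape: Dict[str, float] = field(default_factory=dict)
    followup_window: Tuple[float, float] = (1.5, 6.5)
    age_range: Tuple[float, float] = (65.0, 95.0)
    age_mean: float = 73.3
    age_sd: float = 5.7
    prop_female: float = 0.554
    weight_distribution: Tuple[float, float] = (0.0, 0.5)  # lognormal (mu, sigma)
    utility_floor: float = 0.0
    utility_hazard_correlation: float = 0.0
    informative_weights: bool = False
    loss_to_followup_rate: float = 0.0
    age_severity_slope: float = 0.0  # log-odds of depression per year of age

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be nonnegative, got {self.n}")
        cats = set(COLLAPSED_LABELS)
        for name in ("category_prevalence", "utility_mean", "utility_concentration",
                     "weibull_scale", "weibull_shape"):
            d = getattr(self, name)
            if set(d) != cats:
                raise ConfigurationError(
                    f"{name} must be keyed by {sorted(cats)}, got {sorted(d)}"
                )
        total = sum(self.category_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category prevalences sum to {total}, not 1")
        for c in COLLAPSED_LABELS:
            if self.weibull_scale[c] <= 0 or self.weibull_shape[c] <= 0:
                raise ConfigurationError(f"Weibull parameters for {c} must be > 0")
            if not self.utility_floor < self.utility_mean[c] < 1.0:
                raise ConfigurationError(
                    f"utility_mean[{c}] must lie in ({self.utility_floor}, 1)"
                )
            if self.utility_concentration[c] <= 0:
                raise ConfigurationError(f"utility_concentration[{c}] must be > 0")
        lo, hi = self.followup_window
        if not 0 < lo <= hi:
            raise ConfigurationError(f"bad followup_window {self.followup_window}")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must be a probability")
        if not -1.0 < self.utility_hazard_correlation < 1.0:
            raise ConfigurationError("utility_hazard_correlation must be in (-1, 1)")
        if not 0.0 <= self.loss_to_followup_rate < 1.0:
            raise ConfigurationError("loss_to_followup_rate must be in [0, 1)")


def _weibull_sf(t: np.ndarray, scale: float, shape: float) -> np.ndarray:
    return np.exp(-np.power(np.asarray(t, dtype=float) / scale, shape))


def expected_mortality_rate(
    scale: float, shape: float, window: Tuple[float, float]
) -> float:
    """Expected deaths per 100 person-years under administrative censoring.

    Censoring time C is uniform on ``window``; the rate is
    100 · P(T ≤ C) / E[min(T, C)] for T ~ Weibull(scale, shape), both
    integrals evaluated by adaptive quadrature.
    """
    a, b = window
    cdf = lambda t: 1.0 - float(_weibull_sf(t, scale, shape))
    p_event = integrate.quad(cdf, a, b, limit=200)[0] / (b - a)
    # E[min(T,C)] = ∫ S(t)·P(C > t) dt ; P(C > t) = 1 below a, linear on [a,b]
    py_lo = integrate.quad(lambda t: float(_weibull_sf(t, scale, shape)), 0, a,
                           limit=200)[0]
    py_hi = integrate.quad(
        lambda t: float(_weibull_sf(t, scale, shape)) * (b - t) / (b - a), a, b,
        limit=200)[0]
    return 100.0 * p_event / (py_lo + py_hi)


def calibrate_weibull_scale(
    target_rate: float, shape: float, window: Tuple[float, float]
) -> float:
    """Scale λ such that the expected censored mortality rate hits the target.

    Solved by bracketing root-finding on :func:`expected_mortality_rate`,
    which is monotone decreasing in λ.
    """
    f = lambda lam: expected_mortality_rate(lam, shape, window) - target_rate
    return float(optimize.brentq(f, 0.5, 500.0, xtol=1e-8))


_PREVALENCE = {"none_minimal": 0.821, "mild": 0.138,
               "moderate": 0.032, "modsev_severe": 0.009}
_UTILITY_MEAN = {"none_minimal": 0.875, "mild": 0.680,
                 "moderate": 0.482, "modsev_severe": 0.353}
_TARGET_MORTALITY = {"none_minimal": 2.99, "mild": 4.69,
                     "moderate": 4.97, "modsev_severe": 8.15}
_DEFAULT_SHAPE = 1.3


@lru_cache(maxsize=1)
def _default_scales() -> Tuple[Tuple[str, float], ...]:
    window = (1.5, 6.5)
    return tuple(
        (c, calibrate_weibull_scale(_TARGET_MORTALITY[c], _DEFAULT_SHAPE, window))
        for c in COLLAPSED_LABELS
    )


def default_spec(n: int = 10_000, seed: int = 20110) -> CohortSpec:
    """The calibrated default cohort specification (see module docstring)."""
    spec = CohortSpec(
        n=n,
        seed=seed,
        category_prevalence=dict(_PREVALENCE),
        utility_mean=dict(_UTILITY_MEAN),
        utility_concentration={c: 15.0 for c in COLLAPSED_LABELS},
        weibull_scale=dict(_default_scales()),
        weibull_shape={c: _DEFAULT_SHAPE for c in COLLAPSED_LABELS},
    )
    spec.validate()
    return spec


@lru_cache(maxsize=1)
def _phq_item_pools() -> Dict[int, np.ndarray]:
    """All 4^9 PHQ-9 item vectors grouped by total score.

    Enables uniform sampling over the compositions of a given total into
    nine parts each in {0..3}.
    """
    vectors = np.indices((4,) * 9).reshape(9, -1).T.astype(np.uint8)
    totals = vectors.sum(axis=1).astype(int)
    return {t: np.flatnonzero(totals == t) for t in range(28)}


def _sample_phq_items(
    rng: np.random.Generator, totals: np.ndarray
) -> np.ndarray:
    """Draw an item vector uniformly among compositions for each total."""
    pools = _phq_item_pools()
    vectors = np.indices((4,) * 9).reshape(9, -1).T.astype(np.uint8)
    out = np.empty((len(totals), 9), dtype=np.uint8)
    for t in np.unique(totals):
        rows = np.flatnonzero(totals == t)
        pool = pools[int(t)]
        out[rows] = vectors[pool[rng.integers(len(pool), size=len(rows))]]
    return out


def _assign_categories(
    rng: np.random.Generator, spec: CohortSpec, age: np.ndarray
) -> np.ndarray:
    probs = np.array([spec.category_prevalence[c] for c in COLLAPSED_LABELS])
    p = np.tile(probs, (len(age), 1))
    if spec.age_severity_slope != 0.0:
        # tilt depressed-category mass with age (simple confounding switch)
        tilt = np.exp(spec.age_severity_slope * (age - spec.age_mean))
        p[:, 1:] *= tilt[:, None]
        p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(age))
    return (u[:, None] > cum).sum(axis=1).clip(0, len(COLLAPSED_LABELS) - 1)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort table (deterministic given spec.seed).

    Schema is :data:`COHORT_COLUMNS`; ``time`` = min(true death time,
    administrative censoring time), ``event`` = 1 iff death was observed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})

    lo_a, hi_a = spec.age_range
    a_std = (lo_a - spec.age_mean) / spec.age_sd
    b_std = (hi_a - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.ppf(rng.random(n), a_std, b_std,
                              loc=spec.age_mean, scale=spec.age_sd)
    sex = np.where(rng.random(n) < spec.prop_female, "female", "male")
    mu_w, sigma_w = spec.weight_distribution
    weight = rng.lognormal(mean=mu_w, sigma=sigma_w, size=n)

    cat_idx = _assign_categories(rng, spec, age)
    labels = np.array(COLLAPSED_LABELS)[cat_idx]

    # per-category utility (rescaled Beta) and Weibull death time, coupled
    # through a Gaussian copula when utility_hazard_correlation != 0
    rho = -spec.utility_hazard_correlation  # negative corr with hazard = positive with T
    z = rng.standard_normal((n, 2))
    z_u = z[:, 0]
    z_t = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1]
    p_u = stats.norm.cdf(z_u)
    p_t = stats.norm.cdf(z_t)

    utility = np.empty(n)
    death = np.empty(n)
    floor = spec.utility_floor
    for k, c in enumerate(COLLAPSED_LABELS):
        rows = cat_idx == k
        if not rows.any():
            continue
        m = (spec.utility_mean[c] - floor) / (1.0 - floor)
        kappa = spec.utility_concentration[c]
        a_beta, b_beta = m * kappa, (1.0 - m) * kappa
        utility[rows] = floor + (1.0 - floor) * stats.beta.ppf(
            p_u[rows], a_beta, b_beta
        )
        lam, beta = spec.weibull_scale[c], spec.weibull_shape[c]
        death[rows] = lam * np.power(-np.log1p(-p_t[rows]), 1.0 / beta)

    lo, hi = spec.followup_window
    censor = rng.uniform(lo, hi, size=n)
    if spec.loss_to_followup_rate > 0:
        lost = rng.random(n) < spec.loss_to_followup_rate
        dropout = rng.uniform(0.0, censor)
        censor = np.where(lost, dropout, censor)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    if spec.informative_weights:
        weight = weight * np.exp(0.5 * (1.0 - utility))  # outcome-linked weights

    # PHQ-9 total uniform on the collapsed category's score range
    ranges = np.array([COLLAPSED_RANGES[c] for c in COLLAPSED_LABELS])
    lo_t, hi_t = ranges[cat_idx, 0], ranges[cat_idx, 1]
    phq_total = rng.integers(lo_t, hi_t + 1)
    items = _sample_phq_items(rng, phq_total)

    # Healthy Days answers, monotone with utility (plausibility only: the
    # analyzer reads the eq5d column directly, so these are descriptive)
    morbidity = np.clip(1.0 - utility, 0.0, 1.0)
    genhlth = np.clip(np.rint(1 + 4 * morbidity + rng.normal(0, 0.5, n)), 1, 5)
    physdays = rng.binomial(30, np.clip(0.7 * morbidity, 0, 1))
    mentdays = rng.binomial(30, np.clip(0.6 * morbidity, 0, 1))
    actdays = rng.binomial(30, np.clip(0.5 * morbidity, 0, 1))

    n_comorbid = np.minimum(rng.poisson(2.2, size=n), 10)
    income = rng.lognormal(mean=1.0, sigma=0.6, size=n)
    education = (rng.random(n) < 0.453).astype(int)  # 1 = beyond high school
    married = (rng.random(n) < 0.607).astype(int)

    df = pd.DataFrame({
        "id": np.arange(n),
        "age": np.round(age, 1),
        "sex": sex,
        "weight": weight,
        **{f"phq{i+1}": items[:, i].astype(int) for i in range(9)},
        "phq_total": phq_total.astype(int),
        "genhlth": genhlth.astype(int),
        "physdays": physdays.astype(int),
        "mentdays": mentdays.astype(int),
        "actdays": actdays.astype(int),
        "eq5d": utility,
        "n_comorbid": n_comorbid.astype(int),
        "income_fpl_ratio": np.round(income, 3),
        "education": education,
        "married": married,
        "time": time,
        "event": event,
        "severity": labels,
        "true_death_time": death,
    })
    return df[COHORT_COLUMNS]


def true_group_qaly(spec: CohortSpec, category: str) -> float:
    """Analytic mean remaining-lifetime QALY for one severity category.

    Equals utility_mean · λ · Γ(1 + 1/β), valid because utility and death
    time are independent given category (requires
    ``utility_hazard_correlation == 0``).
    """
    if category not in spec.utility_mean:
        raise InputError(f"unknown category {category!r}")
    if spec.utility_hazard_correlation != 0.0:
        raise ConfigurationError(
            "closed-form group QALY requires utility_hazard_correlation == 0"
        )
    lam = spec.weibull_scale[category]
    beta = spec.weibull_shape[category]
    return spec.utility_mean[category] * lam * special.gamma(1.0 + 1.0 / beta)


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Per-category analytic truths, for recovery tests and the truth file."""
    rows = []
    for c in COLLAPSED_LABELS:
        lam, beta = spec.weibull_scale[c], spec.weibull_shape[c]
        rows.append({
            "severity": c,
            "prevalence": spec.category_prevalence[c],
            "utility_mean": spec.utility_mean[c],
            "weibull_scale": lam,
            "weibull_shape": beta,
            "true_mean_survival": lam * special.gamma(1.0 + 1.0 / beta),
            "true_qaly": true_group_qaly(spec, c),
        })
    return pd.DataFrame(rows)


def with_overrides(spec: CohortSpec, **kwargs) -> CohortSpec:
    """Copy a spec with selected fields replaced (validates the result)."""
    new = replace(spec, **kwargs)
    new.validate()
    return new
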