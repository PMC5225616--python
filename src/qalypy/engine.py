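"""Hybrid remaining-lifetime QALY estimator.

Mean quality-adjusted life years (QALY) over the remaining lifetime cannot
be read off a cohort with limited follow-up, because most participants are
still alive at the administrative end of follow-up L.  The estimator here
splits the quantity into two parts:

* **Follow-up part** (0, L]: a weighted Kaplan-Meier (product-limit)
  estimate of the survival function Ŝ(t) is combined with the mean QALY
  accrued by deaths at each event time t_j, Q̂(t_j), and by survivors at L,
  Q̂(L):

      Σ_j Q̂(t_j) · [Ŝ(t_{j-1}) − Ŝ(t_j)]  +  Q̂(L) · Ŝ(t_l),

  with t_0 = 0 and Ŝ(0) = 1.

* **Tail part** (L, ∞): survival is extrapolated parametrically with a
  Weibull model S_p(t) = exp[−(t/λ)^β] fitted by weighted right-censored
  maximum likelihood.  Total expected life-years are λ̂·Γ(1 + 1/β̂); the
  life-years already counted inside (0, L] are the restricted mean
  ∫₀ᴸ Ŝ(t) dt from the Kaplan-Meier curve; their difference, valued at the
  survivors' mean utility q̂(L), is the tail QALY:

      q̂(L) · { λ̂·Γ(1 + 1/β̂) − ∫₀ᴸ Ŝ_KM(t) dt }.

Utilities are measured once at baseline, so a participant's
quality-adjusted time to t is utility · t (constant-utility convention).
All quantities honour per-record analysis weights (survey design weights,
optionally multiplied by propensity balance weights), and the whole
estimate is invariant to rescaling all weights by a common factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "WeibullFit",
    "QalyEstimate",
    "records_from_frame",
    "fit_km",
    "restricted_life_years",
    "mean_qaly_at_death",
    "mean_qaly_at_horizon",
    "mean_utility_at_horizon",
    "followup_qaly",
    "fit_weibull",
    "weibull_mean",
    "tail_qaly",
    "total_qaly",
    "HybridQalyEstimator",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One participant: follow-up time (years), death indicator, analysis
    weight and baseline utility."""

    time: float
    event: bool
    weight: float = 1.0
    utility: float = 1.0

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise InputError(f"time must be > 0, got {self.time}")
        if self.weight <= 0:
            raise InputError(f"weight must be > 0, got {self.weight}")


RecordsLike = Union[pd.DataFrame, Sequence[SurvivalRecord]]


def _as_arrays(records: RecordsLike):
    """Coerce records to (time, event, weight, utility) float arrays."""
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise EstimationError("no records supplied")
        t = records["time"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=float).astype(bool)
        w = (records["weight"].to_numpy(dtype=float)
             if "weight" in records.columns else np.ones(len(records)))
        u = (records["utility"].to_numpy(dtype=float)
             if "utility" in records.columns
             else records["eq5d"].to_numpy(dtype=float) if "eq5d" in records.columns
             else np.ones(len(records)))
    else:
        records = list(records)
        if not records:
            raise EstimationError("no records supplied")
        t = np.array([r.time for r in records], dtype=float)
        e = np.array([r.event for r in records], dtype=bool)
        w = np.array([r.weight for r in records], dtype=float)
        u = np.array([r.utility for r in records], dtype=float)
    if np.any(t <= 0):
        raise InputError("all follow-up times must be > 0")
    if np.any(w <= 0):
        raise InputError("all weights must be > 0")
    return t, e, w, u


def records_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Project a cohort table onto the estimator's record columns."""
    out = pd.DataFrame({
        "time": df["time"].astype(float),
        "event": df["event"].astype(int),
        "weight": df["weight"].astype(float) if "weight" in df else 1.0,
        "utility": df["eq5d"].astype(float) if "eq5d" in df else 1.0,
    })
    return out


@dataclass(frozen=True)
class KMCurve:
    """Weighted product-limit survival curve.

    ``times`` are the distinct event (death) times in increasing order and
    ``survival`` the estimated S(t) immediately after each; S(0) = 1.
    """

    times: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup Ŝ(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class WeibullFit:
    """Weibull survival fit S(t) = exp[−(t/scale)^shape]."""

    scale: float  # λ, years
    shape: float  # β
    log_likelihood: float
    converged: bool
    n_events: int = 0


@dataclass(frozen=True)
class QalyEstimate:
    """Group-level mean remaining-lifetime QALY, decomposed."""

    followup_part: float
    tail_part: float
    total: float
    se: Optional[float] = None
    n: int = 0
    label: str = ""
    km: Optional[KMCurve] = field(default=None, repr=False)
    weibull: Optional[WeibullFit] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Kaplan-Meier follow-up part


def fit_km(records: RecordsLike) -> KMCurve:
    """Weighted product-limit estimator.

    At each distinct death time the curve multiplies by
    (1 − weighted deaths / weighted at-risk); records censored at time c
    leave the risk set after c (ties between a death and a censoring at the
    same time keep the censored record at risk for that death, the usual
    convention).
    """
    t, e, w, _ = _as_arrays(records)
    event_times = np.unique(t[e])
    surv = np.empty(len(event_times))
    s = 1.0
    for j, tj in enumerate(event_times):
        at_risk = w[t >= tj].sum()
        if at_risk <= 0:
            raise EstimationError(f"zero weighted at-risk set at time {tj}")
        deaths = w[e & (t == tj)].sum()
        s *= 1.0 - deaths / at_risk
        surv[j] = s
    return KMCurve(times=event_times, survival=surv)


def restricted_life_years(km: KMCurve, L: float) -> float:
    """Area under the Kaplan-Meier step function on (0, L].

    This is the restricted mean survival time to horizon L; it equals L
    when no deaths occurred.
    """
    if L < 0:
        raise InputError(f"horizon L must be nonnegative, got {L}")
    times = np.concatenate([[0.0], km.times[km.times < L], [L]])
    surv = np.concatenate([[1.0], km.survival[: len(times) - 2]])
    return float(np.sum(surv * np.diff(times)))


def mean_qaly_at_death(records: RecordsLike, t_j: float) -> float:
    """Q̂(t_j): weighted mean of utility·t_j among deaths at exactly t_j."""
    t, e, w, u = _as_arrays(records)
    sel = e & (t == t_j)
    if not sel.any():
        raise EstimationError(f"no deaths at time {t_j}")
    return float(np.average(u[sel] * t_j, weights=w[sel]))


def _survivor_mask(t: np.ndarray, e: np.ndarray, L: float) -> np.ndarray:
    # Alive at the end of follow-up: administratively censored records, plus
    # anyone followed beyond L.  Under common censoring at L this reduces to
    # the records with time >= L that did not die.
    return (~e) | (t > L)


def mean_qaly_at_horizon(records: RecordsLike, L: float) -> float:
    """Q̂(L): weighted mean of utility·L among those alive at end of follow-up."""
    t, e, w, u = _as_arrays(records)
    sel = _survivor_mask(t, e, L)
    if not sel.any():
        raise EstimationError(f"no survivors at the follow-up horizon L={L}")
    return float(np.average(u[sel] * L, weights=w[sel]))


def mean_utility_at_horizon(records: RecordsLike, L: float) -> float:
    """q̂(L): weighted mean utility over the survivors at end of follow-up."""
    t, e, w, u = _as_arrays(records)
    sel = _survivor_mask(t, e, L)
    if not sel.any():
        raise EstimationError(f"no survivors at the follow-up horizon L={L}")
    return float(np.average(u[sel], weights=w[sel]))


def _clamp_to_horizon(records: RecordsLike, L: float):
    t, e, w, u = _as_arrays(records)
    over = t > L
    if over.any():
        warnings.warn(
            f"{int(over.sum())} record(s) with time > L={L} clamped to L",
            stacklevel=3,
        )
        t = np.minimum(t, L)
    return t, e, w, u


def followup_qaly(records: RecordsLike, km: KMCurve, L: float) -> float:
    """Mean QALY accrued inside (0, L].

    Implements  Σ_j Q̂(t_j)·[Ŝ(t_{j-1}) − Ŝ(t_j)] + Q̂(L)·Ŝ(t_l)  with
    t_0 = 0, Ŝ(0) = 1.  The survivor term is skipped when Ŝ(t_l) = 0
    (everyone died under the fitted curve).
    """
    t, e, w, u = _clamp_to_horizon(records, L)
    if len(km.times) and L < km.times[-1]:
        raise InputError(f"L={L} is below the last event time {km.times[-1]}")
    total = 0.0
    s_prev = 1.0
    for tj, s_j in zip(km.times, km.survival):
        sel = e & (t == tj)
        q_tj = float(np.average(u[sel] * tj, weights=w[sel]))
        total += q_tj * (s_prev - s_j)
        s_prev = s_j
    s_last = km.survival[-1] if len(km.times) else 1.0
    if s_last > 0:
        sel = _survivor_mask(t, e, L)
        if not sel.any():
            raise EstimationError(
                f"positive survival Ŝ={s_last:.4f} at L={L} but no survivor records"
            )
        q_L = float(np.average(u[sel] * L, weights=w[sel]))
        total += q_L * s_last
    return total


# ---------------------------------------------------------------------------
# Weibull tail part


def _weibull_negloglik(params: np.ndarray, t, e, w) -> float:
    log_lam, log_beta = params
    lam, beta = np.exp(log_lam), np.exp(log_beta)
    z = t / lam
    log_h = np.log(beta / lam) + (beta - 1.0) * np.log(z)
    ll = np.sum(w * (e * log_h - np.power(z, beta)))
    return -ll


def fit_weibull(records: RecordsLike, tol: float = 1e-8) -> WeibullFit:
    """Weighted right-censored Weibull maximum likelihood.

    Maximises Σ w_i [δ_i·log h(t_i) − (t_i/λ)^β] over (log λ, log β) with
    h(t) = (β/λ)(t/λ)^{β−1}.  Starting values: β = 1 and the exponential
    MLE λ = total weighted person-time / weighted events.  Non-convergence
    yields a flagged (never silent) estimate.
    """
    t, e, w, _ = _as_arrays(records)
    n_events = int(e.sum())
    if len(np.unique(t[e])) < 2:
        raise EstimationError(
            f"Weibull fit requires >= 2 distinct event times, got {n_events} event(s)"
        )
    w = w / w.mean()  # likelihood scale-invariance under weight rescaling
    ew = w * e
    lam0 = np.sum(w * t) / np.sum(ew)
    x0 = np.array([np.log(lam0), 0.0])
    res = optimize.minimize(
        _weibull_negloglik, x0, args=(t, e.astype(float), w),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 10_000},
    )
    lam, beta = np.exp(res.x)
    if not res.success:
        warnings.warn(
            f"Weibull MLE did not converge ({res.message}); "
            f"returning flagged estimate λ={lam:.4g}, β={beta:.4g}",
            stacklevel=2,
        )
    logger.info(
        "fit=weibull lambda=%.6g beta=%.6g loglik=%.6g converged=%s n_events=%d",
        lam, beta, -res.fun, res.success, n_events,
    )
    return WeibullFit(
        scale=float(lam), shape=float(beta),
        log_likelihood=float(-res.fun), converged=bool(res.success),
        n_events=n_events,
    )


def weibull_mean(fit: WeibullFit) -> float:
    """Mean of the fitted Weibull: λ·Γ(1 + 1/β) (total expected life-years)."""
    return float(fit.scale * special.gamma(1.0 + 1.0 / fit.shape))


def tail_qaly(q_L: float, fit: WeibullFit, km: KMCurve, L: float) -> float:
    """QALY accrued beyond L: q̂(L)·{λ̂Γ(1+1/β̂) − restricted KM life-years}.

    A negative value (parametric mean below the restricted mean) is
    permitted and logged; flooring it silently would bias the total.
    """
    extra_years = weibull_mean(fit) - restricted_life_years(km, L)
    value = q_L * extra_years
    if value < 0:
        warnings.warn(
            f"negative tail QALY ({value:.4f} y): Weibull mean "
            f"{weibull_mean(fit):.3f} < restricted mean; retained unfloored",
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# Composite estimator


def _point_estimate(records: RecordsLike, L: float, label: str = "",
                    tol: float = 1e-8) -> QalyEstimate:
    t, e, w, u = _clamp_to_horizon(records, L)
    frame = pd.DataFrame({"time": t, "event": e.astype(int),
                          "weight": w, "utility": u})
    km = fit_km(frame)
    fu = followup_qaly(frame, km, L)
    wb = fit_weibull(frame, tol=tol)
    q_L = mean_utility_at_horizon(frame, L)
    tail = tail_qaly(q_L, wb, km, L)
    return QalyEstimate(
        followup_part=fu, tail_part=tail, total=fu + tail,
        n=len(t), label=label, km=km, weibull=wb,
    )


def total_qaly(
    records: RecordsLike,
    L: Optional[float] = None,
    *,
    bootstrap: int = 0,
    seed: Optional[int] = None,
    label: str = "",
    tol: float = 1e-8,
) -> QalyEstimate:
    """Mean remaining-lifetime QALY for one group (follow-up + tail).

    Parameters
    ----------
    records : DataFrame or sequence of SurvivalRecord
        The group's follow-up data (time, event, weight, utility).
    L : float, optional
        End-of-follow-up horizon; defaults to the maximum observed time.
    bootstrap : int
        Number of nonparametric bootstrap replicates (participants are
        resampled with their weights) for the standard error; 0 disables.
    seed : int, optional
        Bootstrap RNG seed.
    """
    t, e, w, u = _as_arrays(records)
    if L is None:
        L = float(t.max())
    est = _point_estimate(records, L, label=label, tol=tol)
    if bootstrap <= 0:
        return est
    rng = np.random.default_rng(seed)
    n = len(t)
    reps = []
    for _ in range(bootstrap):
        idx = rng.integers(n, size=n)
        frame = pd.DataFrame({"time": t[idx], "event": e[idx].astype(int),
                              "weight": w[idx], "utility": u[idx]})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reps.append(_point_estimate(frame, L, tol=tol).total)
        except EstimationError:
            continue  # degenerate resample (no events / no survivors)
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else None
    return QalyEstimate(
        followup_part=est.followup_part, tail_part=est.tail_part,
        total=est.total, se=se, n=est.n, label=label,
        km=est.km, weibull=est.weibull,
    )


class HybridQalyEstimator(BaseEstimator):
    """Scikit-learn style wrapper around the hybrid QALY estimator.

    ``fit(X)`` takes a DataFrame with columns ``time``, ``event`` and
    optionally ``weight`` and ``utility`` (or ``eq5d``), and exposes the
    fitted curve, the Weibull tail model and the decomposed estimate as
    trailing-underscore attributes.

    Parameters
    ----------
    L : float or None
        Follow-up horizon in years (None: max observed time).
    bootstrap : int
        Bootstrap replicates for the standard error (0 disables).
    seed : int or None
        Bootstrap RNG seed.
    tol : float
        Convergence tolerance of the Weibull optimiser.

    Attributes
    ----------
    km_ : KMCurve
    weibull_ : WeibullFit
    followup_qaly_, tail_qaly_, total_qaly_ : float
    se_ : float or None
    estimate_ : QalyEstimate
    """

    def __init__(self, L: Optional[float] = None, bootstrap: int = 0,
                 seed: Optional[int] = None, tol: float = 1e-8):
        self.L = L
        self.bootstrap = bootstrap
        self.seed = seed
        self.tol = tol

    def fit(self, X: RecordsLike, y=None) -> "HybridQalyEstimator":
        est = total_qaly(X, self.L, bootstrap=self.bootstrap,
                         seed=self.seed, tol=self.tol)
        self.estimate_ = est
        self.km_ = est.km
        self.weibull_ = est.weibull
        self.followup_qaly_ = est.followup_part
        self.tail_qaly_ = est.tail_part
        self.total_qaly_ = est.total
        self.se_ = est.se
        self.n_ = est.n
        return self
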