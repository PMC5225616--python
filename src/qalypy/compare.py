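"""Propensity-balanced QALY contrasts: loss and percent loss.

The burden of depression is summarised as the QALY *loss*: the difference
in mean remaining-lifetime QALY between a reference group (e.g. no major
depressive disorder, PHQ-9 0-9) and an exposed group (e.g. MDD, PHQ-9 10+),
and the loss as a percent of the reference QALY.  Because exposed and
reference participants differ systematically in characteristics such as
age and sex, groups are balanced with stabilised inverse-probability
weights from a logistic propensity model before estimation; the balance
weights multiply the survey design weights, so they compose naturally with
the weighted Kaplan-Meier machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .engine import total_qaly
from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "LossResult",
    "standard_contrasts",
    "estimate_propensity",
    "balance_weights",
    "qaly_loss",
    "run_contrast",
    "severity_summary",
    "PropensityWeighter",
]

_SCORE_TRIM = 1e-6


@dataclass(frozen=True)
class ContrastSpec:
    """Definition of one exposed-vs-reference comparison.

    ``exposed`` and ``reference`` are disjoint predicates over the PHQ-9
    total; records satisfying neither are excluded from the contrast.
    """

    name: str
    exposed: Callable[[int], bool]
    reference: Callable[[int], bool]
    exposed_label: str = ""
    reference_label: str = ""
    subgroup: Optional[str] = None  # optional column to stratify on

    def masks(self, phq_total: pd.Series) -> Tuple[pd.Series, pd.Series]:
        exp_m = phq_total.map(lambda t: pd.notna(t) and self.exposed(int(t)))
        ref_m = phq_total.map(lambda t: pd.notna(t) and self.reference(int(t)))
        if (exp_m & ref_m).any():
            raise InputError(f"contrast {self.name}: predicates overlap")
        return exp_m.astype(bool), ref_m.astype(bool)


def standard_contrasts() -> Dict[str, ContrastSpec]:
    """The five standard severity contrasts.

    MDD (10-27), moderate (10-14) and moderately-severe/severe (15-27) are
    each compared against no MDD (0-9); mild (5-9) and any depression
    (5-27) against none/minimal (0-4).
    """
    return {
        "mdd": ContrastSpec(
            "mdd", lambda t: t >= 10, lambda t: t <= 9,
            exposed_label="MDD (10-27)", reference_label="No MDD (0-9)"),
        "moderate": ContrastSpec(
            "moderate", lambda t: 10 <= t <= 14, lambda t: t <= 9,
            exposed_label="Moderate (10-14)", reference_label="No MDD (0-9)"),
        "modsev_severe": ContrastSpec(
            "modsev_severe", lambda t: t >= 15, lambda t: t <= 9,
            exposed_label="Moderately severe/severe (15-27)",
            reference_label="No MDD (0-9)"),
        "mild": ContrastSpec(
            "mild", lambda t: 5 <= t <= 9, lambda t: t <= 4,
            exposed_label="Mild (5-9)", reference_label="None/minimal (0-4)"),
        "any_depression": ContrastSpec(
            "any_depression", lambda t: t >= 5, lambda t: t <= 4,
            exposed_label="Mild or MDD (5-27)",
            reference_label="None/minimal (0-4)"),
    }


@dataclass(frozen=True)
class LossResult:
    """QALY loss for one contrast (full precision; see :meth:`rounded`)."""

    name: str
    qaly_reference: float
    qaly_exposed: float
    loss: float
    percent_loss: float
    se_reference: Optional[float] = None
    se_exposed: Optional[float] = None
    se_loss: Optional[float] = None
    n_reference: int = 0
    n_exposed: int = 0
    estimable: bool = True
    note: str = ""

    def rounded(self) -> Tuple[float, int]:
        """Display convention: loss to 1 decimal (years), whole percent."""
        return round(self.loss, 1), int(round(self.percent_loss))


def qaly_loss(qaly_reference: float, qaly_exposed: float,
              name: str = "") -> LossResult:
    """Loss (years) and percent loss of the exposed group vs the reference."""
    if qaly_reference <= 0:
        raise InputError(
            f"reference QALY must be positive, got {qaly_reference}"
        )
    loss = qaly_reference - qaly_exposed
    return LossResult(
        name=name,
        qaly_reference=qaly_reference,
        qaly_exposed=qaly_exposed,
        loss=loss,
        percent_loss=100.0 * loss / qaly_reference,
    )


def _design_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c not in df.columns:
            raise InputError(f"propensity covariate {c!r} missing from cohort")
        v = df[c]
        if v.dtype == object or str(v.dtype) == "category":
            x = (v.astype(str) == "female").astype(float).to_numpy() \
                if c == "sex" else pd.factorize(v)[0].astype(float)
        else:
            x = v.to_numpy(dtype=float)
        if np.std(x) > 0:  # drop constants: intercept already present
            cols.append(x)
    X = np.column_stack([np.ones(len(df))] + cols) if cols else \
        np.ones((len(df), 1))
    return X


def estimate_propensity(
    cohort: pd.DataFrame,
    exposure: pd.Series,
    covariates: Sequence[str] = ("age", "sex"),
    base_weights: Optional[pd.Series] = None,
) -> np.ndarray:
    """Fitted exposure probabilities from a weighted logistic model.

    Additive log-odds model of exposure on the covariates (constant
    covariates are dropped, so a covariate-free cohort yields the weighted
    exposed fraction for every record).  Survey weights enter as frequency
    weights.
    """
    y = exposure.to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("both exposure groups must be nonempty")
    X = _design_matrix(cohort, covariates)
    w = (base_weights.to_numpy(dtype=float) if base_weights is not None
         else np.ones(len(y)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
            fit = model.fit(maxiter=200)
        scores = np.asarray(fit.predict(X), dtype=float)
    except Exception as exc:  # statsmodels raises various separation errors
        raise EstimationError(
            f"propensity model failed (possible perfect separation): {exc}"
        ) from exc
    if not np.all(np.isfinite(scores)):
        raise EstimationError("propensity model produced non-finite scores")
    return scores


def balance_weights(
    scores: np.ndarray,
    exposure: np.ndarray,
    base_weights: np.ndarray,
) -> np.ndarray:
    """Stabilised inverse-probability weights, multiplied by survey weights.

    Exposed records get p̄/score and reference records (1−p̄)/(1−score),
    where p̄ is the weight-based exposed fraction; scores within 1e-6 of
    0 or 1 are trimmed to the threshold (count logged).
    """
    scores = np.asarray(scores, dtype=float)
    exposure = np.asarray(exposure, dtype=bool)
    base_weights = np.asarray(base_weights, dtype=float)
    n_trim = int(np.sum((scores < _SCORE_TRIM) | (scores > 1 - _SCORE_TRIM)))
    if n_trim:
        logger.warning("propensity_trim count=%d threshold=%g", n_trim, _SCORE_TRIM)
    scores = np.clip(scores, _SCORE_TRIM, 1 - _SCORE_TRIM)
    p_bar = float(np.average(exposure, weights=base_weights))
    stab = np.where(exposure, p_bar / scores, (1.0 - p_bar) / (1.0 - scores))
    return base_weights * stab


class PropensityWeighter(BaseEstimator):
    """Sklearn-style propensity balancer.

    ``fit(X, y)`` fits the logistic exposure model (y = exposure indicator)
    and computes stabilised IPW × survey weights; fitted attributes are
    ``propensity_`` and ``weights_``.
    """

    def __init__(self, covariates: Sequence[str] = ("age", "sex")):
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "PropensityWeighter":
        base = X["weight"] if "weight" in X.columns else \
            pd.Series(np.ones(len(X)), index=X.index)
        self.propensity_ = estimate_propensity(
            X, pd.Series(y, index=X.index), self.covariates, base)
        self.weights_ = balance_weights(
            self.propensity_, np.asarray(y, dtype=bool), base.to_numpy(float))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["weight"] = self.weights_
        return out


def _contrast_point(
    sub: pd.DataFrame, exp_m: np.ndarray, L: Optional[float],
    covariates: Sequence[str], use_propensity: bool,
) -> Tuple[float, float]:
    base_w = sub["weight"].to_numpy(dtype=float) if "weight" in sub.columns \
        else np.ones(len(sub))
    if use_propensity:
        scores = estimate_propensity(
            sub, pd.Series(exp_m, index=sub.index), covariates,
            pd.Series(base_w, index=sub.index))
        w = balance_weights(scores, exp_m, base_w)
    else:
        w = base_w
    frames = {}
    for arm, mask in (("exposed", exp_m), ("reference", ~exp_m)):
        g = sub.loc[mask].copy()
        g["weight"] = w[mask]
        frames[arm] = total_qaly(
            pd.DataFrame({
                "time": g["time"].astype(float),
                "event": g["event"].astype(int),
                "weight": g["weight"].astype(float),
                "utility": g["eq5d"].astype(float),
            }),
            L,
        ).total
    return frames["reference"], frames["exposed"]


def run_contrast(
    cohort: pd.DataFrame,
    contrast: ContrastSpec,
    L: Optional[float] = None,
    *,
    covariates: Sequence[str] = ("age", "sex"),
    use_propensity: bool = True,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> LossResult:
    """Full pipeline for one contrast: propensity → IPW → per-group QALY → loss.

    The bootstrap re-runs the entire pipeline (including the propensity
    model) per replicate, resampling participants with their weights.  A
    subgroup with too few events for the Weibull tail yields a result
    flagged ``estimable=False`` rather than an exception.
    """
    from .phq9 import phq_total_frame

    phq_total = phq_total_frame(cohort)
    exp_m, ref_m = contrast.masks(phq_total)
    sub = cohort.loc[exp_m | ref_m].reset_index(drop=True)
    exp_arr = exp_m.loc[exp_m | ref_m].reset_index(drop=True).to_numpy()
    if exp_arr.sum() == 0 or (~exp_arr).sum() == 0:
        raise EstimationError(
            f"contrast {contrast.name}: both groups must be nonempty")
    if L is None:
        L = float(sub["time"].max())

    try:
        q_ref, q_exp = _contrast_point(sub, exp_arr, L, covariates,
                                       use_propensity)
    except EstimationError as exc:
        return LossResult(
            name=contrast.name, qaly_reference=np.nan, qaly_exposed=np.nan,
            loss=np.nan, percent_loss=np.nan,
            n_reference=int((~exp_arr).sum()), n_exposed=int(exp_arr.sum()),
            estimable=False, note=str(exc),
        )

    se_ref = se_exp = se_loss = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        refs, exps, losses = [], [], []
        n = len(sub)
        for _ in range(bootstrap):
            idx = rng.integers(n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, x = _contrast_point(
                        sub.iloc[idx].reset_index(drop=True), exp_arr[idx],
                        L, covariates, use_propensity)
            except EstimationError:
                continue
            refs.append(r)
            exps.append(x)
            losses.append(r - x)
        if len(losses) > 1:
            se_ref = float(np.std(refs, ddof=1))
            se_exp = float(np.std(exps, ddof=1))
            se_loss = float(np.std(losses, ddof=1))

    core = qaly_loss(q_ref, q_exp, name=contrast.name)
    return LossResult(
        name=contrast.name,
        qaly_reference=q_ref, qaly_exposed=q_exp,
        loss=core.loss, percent_loss=core.percent_loss,
        se_reference=se_ref, se_exposed=se_exp, se_loss=se_loss,
        n_reference=int((~exp_arr).sum()), n_exposed=int(exp_arr.sum()),
    )


def severity_summary(
    cohort: pd.DataFrame,
    L: Optional[float] = None,
    *,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-collapsed-category table: n, mean utility, mortality rate, QALY.

    Mortality rate is weighted deaths per 100 weighted person-years of
    follow-up.  Estimates are crude (not age/sex standardised).
    """
    from .phq9 import COLLAPSED_RANGES, phq_total_frame

    phq_total = phq_total_frame(cohort)
    if L is None:
        L = float(cohort["time"].max())
    rows = []
    for cat, (lo, hi) in COLLAPSED_RANGES.items():
        sel = phq_total.between(lo, hi)
        g = cohort.loc[sel]
        if g.empty:
            continue
        w = g["weight"].to_numpy(dtype=float) if "weight" in g else \
            np.ones(len(g))
        mort = 100.0 * np.sum(w * g["event"].to_numpy(float)) / \
            np.sum(w * g["time"].to_numpy(float))
        est = total_qaly(
            pd.DataFrame({
                "time": g["time"].astype(float),
                "event": g["event"].astype(int),
                "weight": w,
                "utility": g["eq5d"].astype(float),
            }),
            L, bootstrap=bootstrap, seed=seed, label=cat,
        )
        rows.append({
            "severity": cat, "phq_range": f"{lo}-{hi}", "n": int(len(g)),
            "mean_utility": float(np.average(g["eq5d"], weights=w)),
            "mortality_per_100py": float(mort),
            "qaly": est.total, "qaly_se": est.se,
            "qaly_followup": est.followup_part, "qaly_tail": est.tail_part,
        })
    return pd.DataFrame(rows)
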