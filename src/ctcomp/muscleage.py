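"""Muscle-age estimation by inverse linear regression of SMA/BMI on age.

"Muscle age" answers: at what age does the reference population's average
BMI-adjusted skeletal muscle index (SMA/BMI) equal this subject's value?
The construction is:

1. In a healthy reference cohort, regress SMA/BMI on a constant and age by
   OLS, separately per sex, restricted to ages 35-65 (roughly the 5th-95th
   age percentiles of a healthy adult population):  s = a + b * age.
2. Invert the fitted line:  age_hat(s) = (s - a) / b.
3. Propagate coefficient uncertainty through the inverse by the delta
   method with a heteroscedasticity-consistent covariance Sigma of (a, b):

       Var(age_hat) = J Sigma J',   J = [-1/b, -(s - a)/b^2].

The subject's s is treated as fixed (no measurement-error term).  HC3 is
the default covariance flavor for its small-sample behavior; HC0-HC2 are
configurable.  Raw estimates far outside the reference support are clamped
for display (default [20, 90] years) with an explicit flag — a linear fit
extrapolated without bounds is misleading — while the raw value is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bodycomp import BodyCompositionResult, SubjectRecord, ValidationError

logger = logging.getLogger("ctcomp")

__all__ = [
    "FitError",
    "SingularityError",
    "NonInvertibleError",
    "MuscleAgeModel",
    "MuscleAgeEstimate",
    "fit_muscle_age_model",
    "estimate_muscle_age",
    "muscle_age_report",
]

DEFAULT_FIT_WINDOW = (35.0, 65.0)
DEFAULT_DISPLAY_CLAMP = (20.0, 90.0)
_HC_TYPES = ("HC0", "HC1", "HC2", "HC3")


class FitError(ValueError):
    """The reference cohort cannot support the requested fit."""


class SingularityError(FitError):
    """Zero age variance in the fit window: the design matrix is singular."""


class NonInvertibleError(ValueError):
    """The fitted slope is too close to zero to invert."""


@dataclass
class MuscleAgeModel:
    """Sex-specific linear model s = a + b*age with robust covariance."""

    sex: str
    a: float
    b: float
    cov: np.ndarray                      # 2x2 HC covariance of (a, b)
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW
    n_fit: int = 0
    display_clamp: tuple[float, float] = DEFAULT_DISPLAY_CLAMP
    hc_type: str = "HC3"
    mean_age: Optional[float] = None     # centroid of the fit sample
    mean_s: Optional[float] = None
    b_tol: float = 0.0                   # minimum |b| considered invertible

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValidationError("cov must be 2x2")
        if not np.allclose(self.cov, self.cov.T):
            raise ValidationError("cov must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValidationError("cov must be positive semi-definite")

    def predict(self, age: float) -> float:
        """Forward model: expected SMA/BMI at a given age."""
        return self.a + self.b * age

    def to_json(self, path=None) -> str:
        payload = {
            "sex": self.sex, "a": self.a, "b": self.b,
            "cov": self.cov.tolist(),
            "fit_window": list(self.fit_window),
            "n_fit": self.n_fit,
            "display_clamp": list(self.display_clamp),
            "hc_type": self.hc_type,
            "mean_age": self.mean_age, "mean_s": self.mean_s,
            "b_tol": self.b_tol,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MuscleAgeModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            sex=payload["sex"], a=payload["a"], b=payload["b"],
            cov=np.asarray(payload["cov"]),
            fit_window=tuple(payload["fit_window"]),
            n_fit=payload["n_fit"],
            display_clamp=tuple(payload["display_clamp"]),
            hc_type=payload["hc_type"],
            mean_age=payload.get("mean_age"), mean_s=payload.get("mean_s"),
            b_tol=payload.get("b_tol", 0.0),
        )


@dataclass
class MuscleAgeEstimate:
    """Inverse-regression age estimate with delta-method uncertainty."""

    muscle_age_years: float      # raw (s - a) / b
    se_years: float
    display_age_years: float     # clamped for reporting
    clamped: bool

    def as_dict(self) -> dict:
        return {
            "muscle_age_years": self.muscle_age_years,
            "se_years": self.se_years,
            "display_age_years": self.display_age_years,
            "clamped": self.clamped,
        }


def fit_muscle_age_model(
    cohort: pd.DataFrame,
    sex: str,
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    hc_type: str = "HC3",
    display_clamp: tuple[float, float] = DEFAULT_DISPLAY_CLAMP,
) -> MuscleAgeModel:
    """OLS of sma_over_bmi on (1, age) for one sex inside the fit window.

    The coefficient covariance is the requested heteroscedasticity-consistent
    estimator (default HC3).  Rows outside the window or of the other sex are
    excluded; the excluded count is logged.
    """
    if hc_type not in _HC_TYPES:
        raise ValidationError(f"hc_type must be one of {_HC_TYPES}")
    required = {"age", "sex", "sma_over_bmi"}
    if not required <= set(cohort.columns):
        raise ValidationError(f"cohort must have columns {sorted(required)}")

    of_sex = cohort[cohort["sex"] == sex]
    lo, hi = fit_window
    sub = of_sex[(of_sex["age"] >= lo) & (of_sex["age"] <= hi)]
    excluded = len(of_sex) - len(sub)
    if excluded:
        logger.info("muscle-age fit (%s): excluded %d rows outside [%g, %g]",
                    sex, excluded, lo, hi)
    if len(sub) < 3:
        raise FitError(
            f"need >= 3 rows of sex {sex!r} in age window [{lo}, {hi}], got {len(sub)}"
        )
    age = sub["age"].to_numpy(float)
    s = sub["sma_over_bmi"].to_numpy(float)
    if not (np.all(np.isfinite(age)) and np.all(np.isfinite(s))):
        raise ValidationError("ages and SMA/BMI must be finite")
    if np.ptp(age) == 0:
        raise SingularityError(f"zero age variance for sex {sex!r} in the fit window")

    X = sm.add_constant(age)
    fit = sm.OLS(s, X).fit(cov_type=hc_type)
    a, b = fit.params
    # invertibility floor scales with the data: a slope this many times
    # smaller than the empirical s-per-age scale is numerically flat
    sd_s, sd_age = np.std(s), np.std(age)
    b_tol = 1e-6 * (sd_s / sd_age if sd_age > 0 else 0.0)

    return MuscleAgeModel(
        sex=sex, a=float(a), b=float(b),
        cov=np.asarray(fit.cov_params()),
        fit_window=(lo, hi), n_fit=len(sub),
        display_clamp=display_clamp, hc_type=hc_type,
        mean_age=float(age.mean()), mean_s=float(s.mean()),
        b_tol=float(b_tol),
    )


def estimate_muscle_age(model: MuscleAgeModel, sma_over_bmi: float) -> MuscleAgeEstimate:
    """Invert the fitted line at one SMA/BMI value and attach a delta-method SE."""
    s = float(sma_over_bmi)
    if not np.isfinite(s):
        raise ValidationError("sma_over_bmi must be finite")
    if abs(model.b) <= max(model.b_tol, np.finfo(float).tiny):
        raise NonInvertibleError(
            f"slope {model.b} is below the invertibility tolerance {model.b_tol}"
        )
    age_hat = (s - model.a) / model.b
    jac = np.array([-1.0 / model.b, -(s - model.a) / model.b**2])
    var = float(jac @ model.cov @ jac)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = model.display_clamp
    display = min(max(age_hat, lo), hi)
    return MuscleAgeEstimate(
        muscle_age_years=float(age_hat),
        se_years=se,
        display_age_years=float(display),
        clamped=display != age_hat,
    )


def muscle_age_report(
    model: MuscleAgeModel,
    subject: SubjectRecord,
    result: BodyCompositionResult,
) -> dict:
    """JSON-serializable report fragment comparing muscle age to chronology."""
    if subject.sex != model.sex:
        raise ValidationError(
            f"no fitted model for sex {subject.sex!r} (model is for {model.sex!r})"
        )
    if result.sma_over_bmi is None:
        raise ValidationError("result lacks SMA/BMI (missing height/weight)")
    est = estimate_muscle_age(model, result.sma_over_bmi)
    chrono = subject.age_years
    comparison = None
    if chrono is not None:
        if est.muscle_age_years < chrono:
            comparison = "muscle age younger than chronological age"
        elif est.muscle_age_years > chrono:
            comparison = "muscle age older than chronological age"
        else:
            comparison = "muscle age equal to chronological age"
    return {
        "subject_id": subject.subject_id,
        "sex": subject.sex,
        "chronological_age_years": chrono,
        "sma_over_bmi": result.sma_over_bmi,
        "muscle_age_years": est.muscle_age_years,
        "muscle_age_se_years": est.se_years,
        "display_age_years": est.display_age_years,
        "clamped": est.clamped,
        "comparison": comparison,
    }
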