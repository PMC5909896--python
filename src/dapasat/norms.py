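"""Demographic norms for minSOA: prediction, z-scores, abnormality, refits.

Expected minSOA is modeled as a linear function of age (years), education
(US-equivalent years) and daily computer-use (8-point Likert).  The shipped
normative model is

    minSOA(ms) = 2680.88 + 6.36*Age - 33.56*Education - 53.07*ComputerUse

fit on a large normative cohort (n = 1617, ages 18-65).  Observed minSOAs
are standardized against this prediction with the residual SD; abnormality
is one-sided (only slow performance is abnormal), defaulting to the highest
5% (z > 1.645).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Demographics",
    "NormModel",
    "load_default_model",
    "predict_minsoa",
    "z_score",
    "is_abnormal",
    "fit_norms",
    "encode_computer_use",
    "score_noncompleter",
    "COMPUTER_USE_ANCHORS",
]

#: Verbatim anchors of the 8-point daily computer-use Likert scale.
COMPUTER_USE_ANCHORS = (
    "Never",
    "Less than 1 hour per week",
    "Less than 1 hour per day",
    "1–2 hours per day",
    "2–3 hours per day",
    "3–4 hours per day",
    "4–6 hours per day",
    "More than 6 hours per day",
)


@dataclass(frozen=True)
class Demographics:
    age: float
    education: float
    computer_use: int
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        if not (1 <= int(self.computer_use) <= 8):
            raise ValueError("computer_use must be a Likert integer in [1, 8]")
        if self.sex not in ("male", "female", "unspecified"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (18 <= self.age <= 100):
            warnings.warn(
                f"age {self.age} outside the normed range; "
                "predictions are extrapolations",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NormModel:
    intercept_ms: float
    coef_age_ms_per_year: float
    coef_edu_ms_per_year: float
    coef_cuse_ms_per_point: float
    residual_sd_ms: float
    provenance: str = "unspecified"
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.residual_sd_ms <= 0:
            raise ValueError("residual_sd_ms must be positive")

    def to_dict(self) -> dict:
        return {
            "intercept_ms": self.intercept_ms,
            "coef_age_ms_per_year": self.coef_age_ms_per_year,
            "coef_edu_ms_per_year": self.coef_edu_ms_per_year,
            "coef_cuse_ms_per_point": self.coef_cuse_ms_per_point,
            "residual_sd_ms": self.residual_sd_ms,
            "provenance": self.provenance,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormModel":
        return cls(**{k: d[k] for k in (
            "intercept_ms", "coef_age_ms_per_year", "coef_edu_ms_per_year",
            "coef_cuse_ms_per_point", "residual_sd_ms",
        )}, provenance=d.get("provenance", "unspecified"),
            r_squared=d.get("r_squared"))


def load_default_model() -> NormModel:
    """The shipped normative regression model.

    The residual SD is not part of the published equation; it is derived
    from the cohort minSOA SD (0.52 s) and the model R² (10.5%) as
    520·sqrt(1 − 0.105) ≈ 492 ms, and can be overridden.
    """
    text = resources.files("dapasat.data").joinpath("exp1a_norms.json").read_text()
    return NormModel.from_dict(json.loads(text))


def predict_minsoa(demo: Demographics, model: NormModel) -> float:
    """Expected minSOA in ms for a subject's demographics."""
    for name in ("age", "education", "computer_use"):
        v = getattr(demo, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing covariate {name!r}; no imputation is done")
    return (
        model.intercept_ms
        + model.coef_age_ms_per_year * demo.age
        + model.coef_edu_ms_per_year * demo.education
        + model.coef_cuse_ms_per_point * demo.computer_use
    )


def z_score(min_soa_ms: float, demo: Demographics, model: NormModel) -> float:
    """Residual-standardized minSOA; higher z means worse performance."""
    return (min_soa_ms - predict_minsoa(demo, model)) / model.residual_sd_ms


def is_abnormal(z: float, alpha: float = 0.05) -> bool:
    """One-sided abnormality flag: z in the upper alpha tail of N(0,1)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return bool(z > stats.norm.ppf(1.0 - alpha))


def fit_norms(cohort: pd.DataFrame, provenance: str = "refit") -> NormModel:
    """OLS refit of minSOA on age, education and computer-use.

    ``cohort`` needs columns ``age``, ``education_years``, ``computer_use``
    and ``min_soa_ms``.  The residual SD uses the OLS denominator (n − 4).
    """
    cols = ["age", "education_years", "computer_use", "min_soa_ms"]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    data = cohort[cols].dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete rows to fit norms")
    X = sm.add_constant(data[["age", "education_years", "computer_use"]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(data["min_soa_ms"].astype(float), X).fit()
    resid_sd = float(np.sqrt(fit.ssr / (len(data) - 4)))
    return NormModel(
        intercept_ms=float(fit.params["const"]),
        coef_age_ms_per_year=float(fit.params["age"]),
        coef_edu_ms_per_year=float(fit.params["education_years"]),
        coef_cuse_ms_per_point=float(fit.params["computer_use"]),
        residual_sd_ms=resid_sd,
        provenance=provenance,
        r_squared=float(fit.rsquared),
    )


def encode_computer_use(label_text: str) -> int:
    """Map a verbatim Likert anchor to its 1-8 code."""
    normalized = label_text.strip().replace("-", "–")
    for i, anchor in enumerate(COMPUTER_USE_ANCHORS, start=1):
        if normalized == anchor:
            return i
    raise ValueError(
        f"unrecognized computer-use label {label_text!r}; "
        f"expected one of {list(COMPUTER_USE_ANCHORS)}"
    )


def score_noncompleter(initial_soa_ms: int = 3500, *, completed: bool = False) -> dict:
    """Assigned minSOA for a subject who refused or failed training/testing.

    Such subjects receive the initial SOA as their minSOA, flagged as
    assigned rather than measured.
    """
    if completed:
        raise ValueError("score_noncompleter applies only to non-completers")
    return {"min_soa_ms": int(initial_soa_ms), "min_soa_assigned": True}
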