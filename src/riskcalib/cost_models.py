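"""Cost regressions: OLS on the risk score, OLS augmented with psychiatric
indicators, and gamma log-link / square-root sensitivity models.

The primary model mirrors payment practice: total annual cost regressed
linearly on the scalar risk score (ordinary least squares), because capitated
payment formulas are linear and additive. The augmented design SUPPLEMENTS
the score with the 47 psychiatric category indicators (it does not remove the
mental-health HCCs already inside the score). Sensitivity families address
cost skewness: a gamma GLM with log link, and OLS on the square root of cost
with a Duan-type smearing retransformation (for a square-root transform the
smearing correction is additive: E[y|x] = (Xb)^2 + mean(e^2)).

Healthcare costs are strongly heteroscedastic, so coefficient standard
errors and confidence intervals use the HC1 sandwich estimator.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla

from .claims_data import Cohort
from .psycms_grouper import PsyCMSCodeList, PsyCMSProfile, category_frame

GLM_MAXITER = 100
GLM_TOL = 1e-8
GAMMA_COST_FLOOR = 1.0  # dollars; gamma GLM requires strictly positive costs


class ModelFamily(str, enum.Enum):
    OLS_LINEAR = "OLS_LINEAR"
    OLS_SQRT = "OLS_SQRT"
    GLM_GAMMA_LOG = "GLM_GAMMA_LOG"


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


class ConvergenceError(RuntimeError):
    """Iteratively reweighted GLM fitting did not converge."""


@dataclass(frozen=True)
class ModelDesign:
    """Design: intercept, risk score, then psychiatric indicators in fixed order."""

    family: ModelFamily = ModelFamily.OLS_LINEAR
    psych_categories: tuple[str, ...] = ()

    @property
    def column_names(self) -> tuple[str, ...]:
        return ("intercept", "score") + self.psych_categories

    @classmethod
    def augmented(
        cls, codelist: PsyCMSCodeList, family: ModelFamily = ModelFamily.OLS_LINEAR
    ) -> "ModelDesign":
        return cls(family=family, psych_categories=codelist.category_ids)


@dataclass
class FittedModel:
    design: ModelDesign
    params: np.ndarray
    bse: np.ndarray  # HC1 robust standard errors
    conf_int: np.ndarray  # HC1 95% CI, shape (k, 2)
    n: int
    r_squared: float  # on the fitting scale
    r_squared_response: float  # on the dollar scale (same as r_squared for OLS_LINEAR)
    retransform_factor: float  # sqrt: additive smearing mean(e^2); gamma/linear: identity
    cohort_fingerprint: str
    n_floored: int = 0  # zero-cost records floored for the gamma family
    n_iterations: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "family": self.design.family.value,
            "psych_categories": list(self.design.psych_categories),
            "column_names": list(self.design.column_names),
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "conf_int": self.conf_int.tolist(),
            "n": self.n,
            "r_squared": self.r_squared,
            "r_squared_response": self.r_squared_response,
            "retransform_factor": self.retransform_factor,
            "cohort_fingerprint": self.cohort_fingerprint,
            "n_floored": self.n_floored,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            design=ModelDesign(
                family=ModelFamily(doc["family"]),
                psych_categories=tuple(doc["psych_categories"]),
            ),
            params=np.array(doc["params"]),
            bse=np.array(doc["bse"]),
            conf_int=np.array(doc["conf_int"]),
            n=doc["n"],
            r_squared=doc["r_squared"],
            r_squared_response=doc["r_squared_response"],
            retransform_factor=doc["retransform_factor"],
            cohort_fingerprint=doc["cohort_fingerprint"],
            n_floored=doc.get("n_floored", 0),
            n_iterations=doc.get("n_iterations", 0),
        )


@dataclass
class FitComparison:
    r_squared_base: float
    r_squared_augmented: float
    difference: float


def _fingerprint(y: np.ndarray) -> str:
    cents = np.round(np.asarray(y, dtype=float) * 100).astype(np.int64)
    return hashlib.sha256(cents.tobytes()).hexdigest()[:16]


def build_design_matrix(
    scores: np.ndarray,
    design: ModelDesign,
    psycms_profiles: Sequence[PsyCMSProfile] | None = None,
    codelist: PsyCMSCodeList | None = None,
) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("all risk scores must be finite")
    cols = [np.ones_like(scores), scores]
    if design.psych_categories:
        if psycms_profiles is None:
            raise ValueError("augmented design requires psychiatric profiles")
        if len(psycms_profiles) != len(scores):
            raise ValueError("psychiatric profiles must match the score vector length")
        for cat in design.psych_categories:
            cols.append(
                np.array([cat in p.categories for p in psycms_profiles], dtype=float)
            )
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify the offending columns via pivoted QR: the trailing pivots with
    # negligible R diagonal are linearly dependent on the earlier ones
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
    bad += [names[p] for p in piv[len(diag):]]
    raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {', '.join(bad)}")


def fit(
    cohort: Cohort,
    scores: np.ndarray,
    psycms_profiles: Sequence[PsyCMSProfile] | None,
    design: ModelDesign,
) -> FittedModel:
    """Fit a cost model for a cohort.

    OLS families are solved by least squares; the gamma GLM by iteratively
    reweighted least squares (rel. coefficient change < 1e-8, max 100
    iterations). r_squared is 1 - SSR/SST on the fitting scale;
    r_squared_response is always reported on the dollar scale.
    """
    y = cohort.total_costs()
    X = build_design_matrix(scores, design, psycms_profiles)
    names = design.column_names
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} does not exceed parameter count {X.shape[1]}")
    _check_rank(X, names)
    fingerprint = _fingerprint(y)

    n_floored = 0
    n_iterations = 0
    if design.family is ModelFamily.OLS_LINEAR:
        res = sm.OLS(y, X).fit()
        robust = res.get_robustcov_results(cov_type="HC1")
        yhat = res.fittedvalues
        r2 = float(res.rsquared)
        r2_resp = r2
        retransform = 1.0
    elif design.family is ModelFamily.OLS_SQRT:
        res = sm.OLS(np.sqrt(y), X).fit()
        robust = res.get_robustcov_results(cov_type="HC1")
        retransform = float(np.mean(res.resid**2))  # additive Duan smearing for sqrt
        yhat = res.fittedvalues**2 + retransform
        r2 = float(res.rsquared)
        r2_resp = _r2_response(y, yhat)
    elif design.family is ModelFamily.GLM_GAMMA_LOG:
        y_pos = np.maximum(y, GAMMA_COST_FLOOR)
        n_floored = int((y < GAMMA_COST_FLOOR).sum())
        model = sm.GLM(y_pos, X, family=sm.families.Gamma(link=sm.families.links.Log()))
        res = model.fit(maxiter=GLM_MAXITER, tol=GLM_TOL)
        if not res.converged:
            raise ConvergenceError(
                f"gamma GLM did not converge within {GLM_MAXITER} iterations"
            )
        n_iterations = int(res.fit_history["iteration"])
        robust = res
        yhat = res.mu
        r2 = _r2_response(y_pos, yhat)  # fitting scale for the GLM is the response scale
        r2_resp = r2
        retransform = 1.0
    else:  # pragma: no cover
        raise ValueError(f"unknown model family {design.family}")

    ci = np.asarray(robust.conf_int())
    return FittedModel(
        design=design,
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(robust.bse, dtype=float),
        conf_int=ci,
        n=len(y),
        r_squared=r2,
        r_squared_response=r2_resp,
        retransform_factor=retransform,
        cohort_fingerprint=fingerprint,
        n_floored=n_floored,
        n_iterations=n_iterations,
    )


def _r2_response(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssr / sst if sst > 0 else 1.0


@dataclass
class PredictionDiagnostics:
    n_negative: int = 0  # negative linear predictions are retained, not clipped


def predict(
    model: FittedModel,
    scores: np.ndarray,
    psycms_profiles: Sequence[PsyCMSProfile] | None = None,
    diagnostics: PredictionDiagnostics | None = None,
) -> np.ndarray:
    """Predicted dollar costs. Linear predictions may be negative (payment
    formulas are linear; clipping would distort decile membership)."""
    X = build_design_matrix(scores, model.design, psycms_profiles)
    if X.shape[1] != len(model.params):
        raise ValueError("regressors do not match the fitted design")
    eta = X @ model.params
    if model.design.family is ModelFamily.OLS_LINEAR:
        yhat = eta
        if diagnostics is not None:
            diagnostics.n_negative = int((yhat < 0).sum())
        return yhat
    if model.design.family is ModelFamily.OLS_SQRT:
        return eta**2 + model.retransform_factor
    if model.design.family is ModelFamily.GLM_GAMMA_LOG:
        return np.exp(eta)
    raise ValueError(f"unknown model family {model.design.family}")  # pragma: no cover


def compare_fit(model_base: FittedModel, model_augmented: FittedModel) -> FitComparison:
    """R-squared comparison of nested models fit on the identical cohort/family."""
    if model_base.cohort_fingerprint != model_augmented.cohort_fingerprint:
        raise ValueError("models were fit on different cohorts")
    if model_base.design.family is not model_augmented.design.family:
        raise ValueError("models use different families; R2 values are not comparable")
    return FitComparison(
        r_squared_base=model_base.r_squared,
        r_squared_augmented=model_augmented.r_squared,
        difference=model_augmented.r_squared - model_base.r_squared,
    )
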