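"""Gompertz mortality model and biological-age (PhenoAge-style) prediction.

A proportional-hazards Gompertz model is fitted by maximum likelihood on
a reference cohort of young adults: hazard

    h(t | age, x) = exp(b0 + b_age * age + sum_k b_k x_k) * exp(gamma t)

with administrative censoring.  The implied death probability over a
horizon tau is

    M = 1 - exp(-exp(lp) * (exp(gamma tau) - 1) / gamma).

An age-only submodel fitted on the same cohort is inverted in closed
form to translate a subject's predicted risk into the chronological age
at which that risk would be normal in the reference group — the
biological age.  Acceleration is the residual of biological age on
chronological age and sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools import numdiff

from .config import BIOMARKERS


@dataclass
class GompertzMortalityModel:
    """Fitted full and age-only Gompertz proportional-hazards models."""

    b0: float
    b_age: float
    b_biomarkers: np.ndarray
    gamma: float
    horizon: float
    biomarker_names: tuple
    b0_age_only: float
    b_age_age_only: float
    gamma_age_only: float
    log_likelihood: float
    standard_errors: Optional[np.ndarray] = None  # order: b0, b_age, b_k..., log gamma

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.b0, self.b_age], self.b_biomarkers, [self.gamma]])


def gompertz_loglik(
    params: np.ndarray, design: np.ndarray, time: np.ndarray, died: np.ndarray
) -> float:
    """Log-likelihood of the censored Gompertz PH model.

    ``params`` = [beta..., log gamma] with ``design`` including the
    intercept column.  Events contribute log h(t_i); everyone contributes
    minus the cumulative hazard exp(lp) (exp(gamma t_i) - 1) / gamma.
    """
    beta = params[:-1]
    gamma = math.exp(params[-1])
    lp = design @ beta
    cum = np.exp(lp) * np.expm1(gamma * time) / gamma
    return float(np.sum(died * (lp + gamma * time)) - cum.sum())


def _fit_ml(design: np.ndarray, time: np.ndarray, died: np.ndarray) -> tuple:
    scale = design.std(axis=0)
    scale[scale == 0] = 1.0
    center = design.mean(axis=0)
    center[0] = 0.0  # keep the intercept column as-is
    scale[0] = 1.0
    ds = (design - center) / scale

    def negloglik(p):
        return -gompertz_loglik(p, ds, time, died)

    def neggrad(p):
        beta = p[:-1]
        gamma = math.exp(p[-1])
        lp = ds @ beta
        cum = np.exp(lp) * np.expm1(gamma * time) / gamma
        g_beta = ds.T @ (died - cum)
        # d/dgamma of [died*gamma*t - exp(lp)(e^{gt}-1)/g], then chain * gamma
        dcum_dg = np.exp(lp) * (
            time * np.exp(gamma * time) / gamma - np.expm1(gamma * time) / gamma**2
        )
        g_loggamma = gamma * float(np.sum(died * time) - dcum_dg.sum())
        return -np.concatenate([g_beta, [g_loggamma]])

    p0 = np.zeros(ds.shape[1] + 1)
    p0[0] = math.log(max(died.mean(), 1e-3) / max(time.mean(), 1e-6))
    p0[-1] = math.log(0.05)
    bounds = [(None, None)] * ds.shape[1] + [(math.log(1e-4), math.log(5.0))]
    res = minimize(
        negloglik, p0, jac=neggrad, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success:
        grad = np.linalg.norm(numdiff.approx_fprime(res.x, negloglik))
        raise RuntimeError(f"Gompertz fit did not converge (|grad| = {grad:.3e})")
    beta_s = res.x[:-1]
    beta = beta_s / scale
    beta[0] = beta_s[0] - np.sum(beta_s[1:] * center[1:] / scale[1:])
    params = np.concatenate([beta, [res.x[-1]]])
    loglik = gompertz_loglik(params, design, time, died)
    try:
        hess = numdiff.approx_hess(
            params, lambda p: -gompertz_loglik(p, design, time, died)
        )
        se = np.sqrt(np.diag(np.linalg.inv(hess)))
    except np.linalg.LinAlgError:
        se = None
    return params, loglik, se


def fit_mortality_model(
    cohort: pd.DataFrame,
    biomarkers: Sequence[str] = BIOMARKERS,
    horizon: float = 10.0,
) -> GompertzMortalityModel:
    """Maximum-likelihood Gompertz PH fit (full and age-only).

    ``cohort`` needs chronological_age, follow_up, died and the biomarker
    columns, complete.  At least 30 events are required for a stable fit.
    """
    required = ["chronological_age", "follow_up", "died", *biomarkers]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"mortality cohort lacks columns: {missing}")
    sub = cohort[required]
    if sub.isna().any().any():
        raise ValueError("mortality cohort has missing values")
    died = sub["died"].to_numpy(dtype=float)
    if died.sum() == 0:
        raise ValueError("no events: Gompertz model unidentifiable")
    if died.sum() < 30:
        raise ValueError(f"only {int(died.sum())} events; need >= 30")
    time = sub["follow_up"].to_numpy(dtype=float)
    age = sub["chronological_age"].to_numpy(dtype=float)
    x = sub[list(biomarkers)].to_numpy(dtype=float)
    n = len(sub)
    design_full = np.column_stack([np.ones(n), age, x])
    params_full, ll, se = _fit_ml(design_full, time, died)
    design_age = np.column_stack([np.ones(n), age])
    params_age, _, _ = _fit_ml(design_age, time, died)
    if params_age[1] <= 0:
        raise ValueError("age-only model has non-positive age slope; inversion undefined")
    return GompertzMortalityModel(
        b0=params_full[0],
        b_age=params_full[1],
        b_biomarkers=params_full[2:-1],
        gamma=math.exp(params_full[-1]),
        horizon=horizon,
        biomarker_names=tuple(biomarkers),
        b0_age_only=params_age[0],
        b_age_age_only=params_age[1],
        gamma_age_only=math.exp(params_age[-1]),
        log_likelihood=ll,
        standard_errors=se,
    )


def predict_mortality(
    model: GompertzMortalityModel, age, biomarkers
) -> np.ndarray:
    """Death probability over the model horizon for given covariates.

    M = 1 - exp(-exp(lp) (exp(gamma tau) - 1) / gamma) with
    lp = b0 + b_age * age + sum_k b_k x_k.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    x = np.atleast_2d(np.asarray(biomarkers, dtype=float))
    lp = model.b0 + model.b_age * age + x @ model.b_biomarkers
    if not np.isfinite(lp).all():
        raise ValueError("non-finite linear predictor")
    cum = np.exp(lp) * np.expm1(model.gamma * model.horizon) / model.gamma
    return -np.expm1(-cum)


def invert_to_phenoage(model: GompertzMortalityModel, risk) -> np.ndarray:
    """Biological age: the age with the same risk in the age-only model.

    Solves M'(a) = risk in closed form:
    a = (ln(-gamma' ln(1 - risk) / (exp(gamma' tau) - 1)) - b0') / b_age'.
    """
    risk = np.atleast_1d(np.asarray(risk, dtype=float))
    if np.any(risk <= 0) or np.any(risk >= 1):
        raise ValueError("risk must lie strictly inside (0, 1)")
    g = model.gamma_age_only
    num = -g * np.log1p(-risk) / np.expm1(g * model.horizon)
    return (np.log(num) - model.b0_age_only) / model.b_age_age_only


def predict_phenoage(model: GompertzMortalityModel, age, biomarkers) -> np.ndarray:
    """Predict risk from the full model, then invert via the age-only model.

    Risks that saturate numerically at 0 or 1 are nudged to the nearest
    representable interior value so extreme subjects map to finite
    (very old / very young) biological ages.
    """
    risk = predict_mortality(model, age, biomarkers)
    risk = np.clip(risk, 1e-15, 1.0 - 1e-12)
    return invert_to_phenoage(model, risk)


def acceleration(
    phenoage_years, age_years, sex, ddof_check: float = 1e-8
) -> np.ndarray:
    """Age- and sex-adjusted biological-age acceleration (residual years)."""
    from .phenotypes import residualize

    age_years = np.asarray(age_years, dtype=float)
    if len(age_years) < 10:
        raise ValueError("acceleration adjustment needs >= 10 subjects")
    if age_years.std() == 0:
        raise ValueError("chronological age is constant; adjustment undefined")
    design = np.column_stack([age_years, np.asarray(sex, dtype=float)])
    return residualize(np.asarray(phenoage_years, dtype=float), design, rtol=ddof_check)
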