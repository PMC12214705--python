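"""Serial-parallel path model with percentile-bootstrap indirect effects.

Model-81 topology: the exposure X feeds a first-stage mediator M1, which
feeds two parallel second-stage mediators M2 and M3, all of which feed
the outcome Y, with a common covariate set in every equation:

    M1 ~ X + C
    M2 ~ X + M1 + C
    M3 ~ X + M1 + C
    Y  ~ X + M1 + M2 + M3 + C

Coefficient inference uses heteroscedasticity-consistent (HC3) standard
errors; indirect effects are products of path coefficients with
case-resampling percentile bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import build_design

EFFECT_NAMES = (
    "x_m1_y",
    "x_m2_y",
    "x_m3_y",
    "x_m1_m2_y",
    "x_m1_m3_y",
)


@dataclass
class PathModel81:
    """Fitted equations and the coefficients the effects are built from."""

    coefficients: dict            # path name -> value
    tables: dict                  # equation name -> coefficient DataFrame
    dof: dict                     # equation name -> residual dof
    n: int
    standardized: bool


@dataclass
class IndirectEffects:
    """Specific, total-indirect, direct and total effects of X on Y."""

    specific: dict                # effect name -> value
    total_indirect: float
    direct: float
    total: float

    def decomposition_gap(self) -> float:
        return self.total - self.direct - self.total_indirect


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        v = out[c].to_numpy(dtype=float)
        out[c] = (v - v.mean()) / v.std(ddof=1)
    return out


def _equation(y, design, names, label) -> tuple[np.ndarray, pd.DataFrame, int]:
    fit = sm.OLS(y, design).fit(cov_type="HC3")
    table = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se_hc3": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return fit.params, table, int(fit.df_resid)


def fit_path_model(
    data: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    standardized: bool = True,
) -> PathModel81:
    """Fit the four model-81 OLS equations with HC3 errors.

    ``data`` must hold columns X, M1, M2, M3, Y (complete cases).  With
    ``standardized`` every analysis variable is z-scored before fitting,
    so indirect effects read as standardized effects.
    """
    required = ["X", "M1", "M2", "M3", "Y"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns: {missing}")
    vals = data[required].astype(float)
    if vals.isna().any().any():
        raise ValueError("path model requires complete cases")
    if standardized:
        vals = _zscore_cols(vals)
    cov_design = (
        build_design(covariates)[:, 1:] if covariates is not None else
        np.empty((len(vals), 0))
    )
    n = len(vals)
    max_pred = 4 + cov_design.shape[1]
    if n <= max_pred + 2:
        raise ValueError(f"n={n} too small for {max_pred} predictors")
    x = vals["X"].to_numpy()
    m1 = vals["M1"].to_numpy()
    m2 = vals["M2"].to_numpy()
    m3 = vals["M3"].to_numpy()
    y = vals["Y"].to_numpy()
    cov_names = [f"c{j}" for j in range(cov_design.shape[1])]

    def _design(*cols):
        d = np.column_stack([np.ones(n), *cols, cov_design])
        if np.linalg.cond(d) > 1e8:
            raise ValueError("design condition number exceeds 1e8")
        return d

    eq = {}
    p1, t1, d1 = _equation(m1, _design(x), ["const", "X"] + cov_names, "M1")
    p2, t2, d2 = _equation(m2, _design(x, m1), ["const", "X", "M1"] + cov_names, "M2")
    p3, t3, d3 = _equation(m3, _design(x, m1), ["const", "X", "M1"] + cov_names, "M3")
    p4, t4, d4 = _equation(
        y, _design(x, m1, m2, m3), ["const", "X", "M1", "M2", "M3"] + cov_names, "Y"
    )
    coefficients = {
        "a1": p1[1],          # X -> M1
        "a2": p2[1],          # X -> M2
        "a3": p3[1],          # X -> M3
        "d21": p2[2],         # M1 -> M2
        "d31": p3[2],         # M1 -> M3
        "b1": p4[2],          # M1 -> Y
        "b2": p4[3],          # M2 -> Y
        "b3": p4[4],          # M3 -> Y
        "c_prime": p4[1],     # direct X -> Y
    }
    return PathModel81(
        coefficients=coefficients,
        tables={"M1": t1, "M2": t2, "M3": t3, "Y": t4},
        dof={"M1": d1, "M2": d2, "M3": d3, "Y": d4},
        n=n,
        standardized=standardized,
    )


def indirect_effects(model: PathModel81) -> IndirectEffects:
    """Products of path coefficients: three simple and two serial effects.

    The decomposition total = direct + sum(specific indirect) holds
    exactly on OLS coefficients fitted with a common covariate set.
    """
    c = model.coefficients
    specific = {
        "x_m1_y": c["a1"] * c["b1"],
        "x_m2_y": c["a2"] * c["b2"],
        "x_m3_y": c["a3"] * c["b3"],
        "x_m1_m2_y": c["a1"] * c["d21"] * c["b2"],
        "x_m1_m3_y": c["a1"] * c["d31"] * c["b3"],
    }
    total_indirect = sum(specific.values())
    direct = c["c_prime"]
    return IndirectEffects(
        specific=specific,
        total_indirect=total_indirect,
        direct=direct,
        total=direct + total_indirect,
    )


def _effects_from_arrays(x, m1, m2, m3, y, cov) -> np.ndarray:
    """Fast path: the nine path coefficients via four lstsq fits.

    Returns [five specific effects, total_indirect, direct, total].
    """
    n = len(x)
    ones = np.ones(n)

    def _beta(target, *cols):
        d = np.column_stack([ones, *cols, cov])
        beta, *_ = np.linalg.lstsq(d, target, rcond=None)
        return beta

    b_m1 = _beta(m1, x)
    b_m2 = _beta(m2, x, m1)
    b_m3 = _beta(m3, x, m1)
    b_y = _beta(y, x, m1, m2, m3)
    a1, a2, a3 = b_m1[1], b_m2[1], b_m3[1]
    d21, d31 = b_m2[2], b_m3[2]
    b1, b2, b3, c_prime = b_y[2], b_y[3], b_y[4], b_y[1]
    spec = np.array(
        [a1 * b1, a2 * b2, a3 * b3, a1 * d21 * b2, a1 * d31 * b3]
    )
    ti = spec.sum()
    return np.concatenate([spec, [ti, c_prime, c_prime + ti]])


def bootstrap_cis(
    data: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    standardized: bool = True,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for every specific and summary effect.

    Cases (rows) are resampled with replacement and all four equations
    refitted per resample; z-scoring, when requested, is done once on the
    original sample.  An effect is "robust" when its CI excludes 0.
    Degenerate resamples (any constant analysis column) are redrawn.
    """
    if n_boot < 500:
        import warnings

        warnings.warn("n_boot < 500 gives unstable percentile CIs", stacklevel=2)
    vals = data[["X", "M1", "M2", "M3", "Y"]].astype(float)
    if standardized:
        vals = _zscore_cols(vals)
    cov = (
        build_design(covariates)[:, 1:] if covariates is not None else
        np.empty((len(vals), 0))
    )
    x, m1, m2, m3, y = (vals[c].to_numpy() for c in ["X", "M1", "M2", "M3", "Y"])
    est = _effects_from_arrays(x, m1, m2, m3, y, cov)
    rng = np.random.default_rng(seed)
    n = len(x)
    draws = np.empty((n_boot, len(est)))
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        cols = (x[idx], m1[idx], m2[idx], m3[idx], y[idx])
        if any(c.std() == 0 for c in cols):
            redrawn += 1
            continue
        draws[b] = _effects_from_arrays(*cols, cov[idx])
        b += 1
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    names = list(EFFECT_NAMES) + ["total_indirect", "direct", "total"]
    return pd.DataFrame(
        {
            "effect": names,
            "estimate": est,
            "ci_low": lo,
            "ci_high": hi,
            "robust": (lo > 0) | (hi < 0),
            "redrawn_resamples": redrawn,
        }
    )
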