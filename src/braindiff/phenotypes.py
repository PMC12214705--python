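"""Pubertal indices, symptom change scores, and generic residualization.

Hormonal adrenarche/gonadarche are built within sex from salivary DHEA,
testosterone and estradiol after residualizing for saliva-quality and
(in girls) menstrual-cycle covariates; self-report indices average the
sex-specific Pubertal Development Scale item sets.  Change scores are
differences of within-wave z-scores across the nine DSM-oriented CBCL
scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GIRL_ADRENARCHE_ITEMS = ("skin", "body_hair")
GIRL_GONADARCHE_ITEMS = ("growth_spurt", "breast", "menarche")
BOY_ADRENARCHE_ITEMS = ("skin", "body_hair")
BOY_GONADARCHE_ITEMS = ("growth_spurt", "voice", "facial")

SALIVA_COVARIATES = (
    "saliva_quality_ok",
    "activity_level",
    "caffeine_12h_mg",
    "collection_delay_h",
)
MENARCHE_COVARIATES = ("age_menarche", "days_since_cycle", "cycle_regular")


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + numeric columns + dummy-coded object/categorical columns."""
    columns = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            for d in dummies.columns:
                columns.append(dummies[d].to_numpy(dtype=float))
        else:
            columns.append(col.to_numpy(dtype=float))
    return np.column_stack(columns)


def residualize(values, covariates, rtol: float = 1e-8) -> np.ndarray:
    """OLS residuals of ``values`` on ``covariates`` (with intercept).

    ``values`` may be a vector or matrix; ``covariates`` a DataFrame or
    array.  Residuals are verified orthogonal to the design.  A design
    that is not full column rank falls back to the pseudo-inverse with a
    warning.
    """
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if isinstance(covariates, pd.DataFrame):
        design = build_design(covariates)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.column_stack([np.ones(cov.shape[0]), cov])
    if y.shape[0] <= design.shape[1] - 1:
        raise ValueError(
            f"n={y.shape[0]} rows cannot be residualized on "
            f"{design.shape[1] - 1} covariates"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("covariate design not full rank; using pseudo-inverse", stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    centered = design[:, 1:] - design[:, 1:].mean(axis=0) if design.shape[1] > 1 else None
    if centered is not None and centered.size:
        norms = np.linalg.norm(centered, axis=0)
        ok = norms > 0
        if ok.any():
            rnorm = np.linalg.norm(resid, axis=0)
            in_norm = np.linalg.norm(y, axis=0)
            # columns whose residual vanished are orthogonal by convention
            check = rnorm > rtol * np.maximum(in_norm, 1.0)
            if check.any():
                dots = np.abs((centered[:, ok] / norms[ok]).T @ resid[:, check])
                cos = dots / rnorm[check][None, :]
                if cos.max() > rtol * 100:
                    raise AssertionError("residualization failed orthogonality check")
    return resid[:, 0] if squeeze else resid


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


@dataclass
class PubertalIndices:
    """Standardized adrenarche/gonadarche scores, hormonal and self-report."""

    table: pd.DataFrame  # columns: hormonal_adrenarche, hormonal_gonadarche,
    #          selfreport_adrenarche, selfreport_gonadarche


def hormonal_indices(
    panel: pd.DataFrame,
    sex: np.ndarray,
    saliva_covariates=SALIVA_COVARIATES,
    menarche_covariates=MENARCHE_COVARIATES,
    restandardize: bool = True,
) -> pd.DataFrame:
    """Hormonal adrenarche/gonadarche, residualized and z-scored within sex.

    Girls (sex = -1): adrenarche = mean(z-DHEA, z-testosterone),
    gonadarche = z-estradiol, with saliva plus menstrual-cycle covariates
    removed first.  Boys (sex = +1): adrenarche = z-DHEA, gonadarche =
    z-testosterone, saliva covariates only.  With ``restandardize`` the
    combined indices are z-scored again within sex so each has mean 0 /
    SD 1 before pooling; with ``restandardize=False`` the raw combination
    (e.g. the girls' two-hormone average) is returned.
    """
    sex = np.asarray(sex, dtype=float)
    n = len(panel)
    adren = np.full(n, np.nan)
    gonad = np.full(n, np.nan)
    for code in (1.0, -1.0):
        mask = sex == code
        if not mask.any():
            continue
        sub = panel.loc[mask]
        covs = [c for c in saliva_covariates if c in sub.columns]
        if code < 0:
            extra = [
                c
                for c in menarche_covariates
                if c in sub.columns and sub[c].notna().all()
            ]
            skipped = [c for c in menarche_covariates if c not in extra]
            if skipped:
                warnings.warn(
                    f"menarche covariates skipped (absent or incomplete): {skipped}",
                    stacklevel=2,
                )
            covs = covs + extra
        cov_df = sub[covs] if covs else None

        def _resid_z(col: str) -> np.ndarray:
            vals = sub[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing analyte {col!r} for sex code {code:+.0f}")
            if cov_df is not None:
                vals = residualize(vals, cov_df)
            return _zscore(vals)

        if code < 0:
            z_dhea = _resid_z("dhea")
            z_t = _resid_z("testosterone")
            combined = (z_dhea + z_t) / 2.0
            adren[mask] = _zscore(combined) if restandardize else combined
            gonad[mask] = _resid_z("estradiol")
        else:
            adren[mask] = _resid_z("dhea")
            gonad[mask] = _resid_z("testosterone")
    return pd.DataFrame(
        {"hormonal_adrenarche": adren, "hormonal_gonadarche": gonad},
        index=panel.index,
    )


def selfreport_indices(
    pds_items: pd.DataFrame,
    sex: np.ndarray,
    parent_items: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Self-reported adrenarche/gonadarche from the PDS item sets.

    Adrenarche averages skin changes and body-hair growth in both sexes;
    gonadarche averages growth spurt + breast development + menarche in
    girls and growth spurt + voice deepening + facial hair in boys.  A
    missing item drops out of the mean; when every item of a construct is
    missing, the parent-report fallback is used if supplied, otherwise
    the index is missing.
    """
    sex = np.asarray(sex, dtype=float)
    n = len(pds_items)

    def _mean_items(frame: pd.DataFrame, items, mask) -> np.ndarray:
        cols = [c for c in items if c in frame.columns]
        if not cols:
            return np.full(mask.sum(), np.nan)
        block = frame.loc[mask, cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(block, axis=1)

    adren = np.full(n, np.nan)
    gonad = np.full(n, np.nan)
    for code, a_items, g_items in (
        (-1.0, GIRL_ADRENARCHE_ITEMS, GIRL_GONADARCHE_ITEMS),
        (1.0, BOY_ADRENARCHE_ITEMS, BOY_GONADARCHE_ITEMS),
    ):
        mask = sex == code
        if not mask.any():
            continue
        adren[mask] = _mean_items(pds_items, a_items, mask)
        gonad[mask] = _mean_items(pds_items, g_items, mask)
        if parent_items is not None:
            pa = _mean_items(parent_items, a_items, mask)
            pg = _mean_items(parent_items, g_items, mask)
            a_slice = adren[mask]
            g_slice = gonad[mask]
            a_slice[np.isnan(a_slice)] = pa[np.isnan(a_slice)]
            g_slice[np.isnan(g_slice)] = pg[np.isnan(g_slice)]
            adren[mask] = a_slice
            gonad[mask] = g_slice
    return pd.DataFrame(
        {"selfreport_adrenarche": adren, "selfreport_gonadarche": gonad},
        index=pds_items.index,
    )


def change_scores(t2_scores: pd.DataFrame, t3_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-scale change: z-score within wave, difference z(T3) - z(T2).

    Requires the same subjects and scales at both waves.  A scale that is
    constant at either wave is dropped with a warning (its change score
    is undefined).
    """
    if list(t2_scores.columns) != list(t3_scores.columns):
        raise ValueError("T2 and T3 tables must share the same scales")
    if len(t2_scores) != len(t3_scores):
        raise ValueError("T2 and T3 tables must share the same subjects")
    out = {}
    for scale in t2_scores.columns:
        a = t2_scores[scale].to_numpy(dtype=float)
        b = t3_scores[scale].to_numpy(dtype=float)
        if np.nanstd(a) == 0 or np.nanstd(b) == 0:
            warnings.warn(f"scale {scale!r} constant at a wave; change score dropped",
                          stacklevel=2)
            continue
        out[f"delta_{scale}"] = _zscore(b) - _zscore(a)
    return pd.DataFrame(out, index=t2_scores.index)
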