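"""Sexual-differentiation template and regional similarity profiles.

The adult reference cohort yields an R x R matrix of sex-effect
t-statistics (masculine = positive); each adolescent's regional FC
profile is then scored by the Spearman similarity of their FC rows to
the template rows.  Regional maps can be aligned to the
sensorimotor-association axis with spin-permutation inference, and
phenotype-specific differentiation maps are built via partial Spearman
correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .phenotypes import build_design, residualize
from .simulate import ReferenceCohort

logger = logging.getLogger(__name__)


@dataclass
class SexDiffTemplate:
    """Edge-wise sex-effect t statistics from the reference cohort."""

    t: np.ndarray                 # (R, R) symmetric, diagonal NaN
    dof: int
    covariate_names: tuple

    @property
    def n_rois(self) -> int:
        return self.t.shape[0]


def fit_template(cohort: ReferenceCohort, covariates: pd.DataFrame | None = None) -> SexDiffTemplate:
    """Per-edge OLS of Fisher-z FC on sex (+ covariates); keep the sex t.

    Sex must be coded +1 male / -1 female, so positive template entries
    mark edges with stronger coupling in males.  Covariates default to
    the full cohort covariate table.  Collinear covariate columns are
    handled by the pseudo-inverse with a warning.
    """
    sex = np.asarray(cohort.sex, dtype=float)
    if len(np.unique(sex)) < 2:
        raise ValueError("template requires both sexes in the reference cohort")
    if covariates is None:
        covariates = cohort.covariates
    design_cov = build_design(covariates)  # includes intercept
    design = np.column_stack([sex, design_cov])
    n, p = design.shape
    if n <= p + 2:
        raise ValueError(f"n={n} subjects insufficient for {p} regressors")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        warnings.warn("collinear covariates in template design; pseudo-inverse used",
                      stacklevel=2)

    r = cohort.fc.shape[-1]
    iu = np.triu_indices(r, k=1)
    y = cohort.fc[:, iu[0], iu[1]]  # (n, E)
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    resid = y - design @ beta
    dof = n - rank
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    # variance of the sex coefficient: first row of (X^T X)^-1
    xtx_inv = pinv @ pinv.T
    se = np.sqrt(xtx_inv[0, 0] * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_edge = beta[0] / se
    t = np.full((r, r), np.nan)
    t[iu] = t_edge
    t[(iu[1], iu[0])] = t_edge
    return SexDiffTemplate(t=t, dof=dof, covariate_names=tuple(covariates.columns))


def _offdiag_rows(mat: np.ndarray) -> np.ndarray:
    """Extract each row's off-diagonal entries as an (R, R-1) array."""
    r = mat.shape[0]
    mask = ~np.eye(r, dtype=bool)
    rows = mat[mask].reshape(r, r - 1)
    return rows


def score_subject(fc_z: np.ndarray, template: SexDiffTemplate) -> np.ndarray:
    """Regional differentiation profile: per-row Spearman similarity.

    Entry i is the Spearman correlation between row i of the subject's
    Fisher-z FC matrix and row i of the template t matrix, over the R-1
    off-diagonal edges (average ranks for ties).  Positive values mark a
    more masculine regional coupling profile.  Rows with fewer than 4
    valid paired edges yield NaN.
    """
    fc_z = np.asarray(fc_z, dtype=float)
    r = template.n_rois
    if fc_z.shape != (r, r):
        raise ValueError(f"FC matrix is {fc_z.shape}, template expects {(r, r)}")
    fc_rows = _offdiag_rows(fc_z)
    t_rows = _offdiag_rows(template.t)
    profile = np.full(r, np.nan)
    for i in range(r):
        valid = np.isfinite(fc_rows[i]) & np.isfinite(t_rows[i])
        if valid.sum() < 4:
            logger.warning("parcel %d: <4 valid edge pairs; profile entry missing", i)
            continue
        profile[i] = spearmanr(fc_rows[i, valid], t_rows[i, valid]).statistic
    return profile


def score_cohort(fc_stack: np.ndarray, template: SexDiffTemplate) -> np.ndarray:
    """Vectorized profiles for a complete-data cohort stack (n, R, R).

    Equivalent to calling :func:`score_subject` per subject when no
    edges are missing; ranks are computed row-wise and correlated with
    the pre-ranked template rows.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    n, r, _ = fc_stack.shape
    t_rows = _offdiag_rows(template.t)
    if not np.isfinite(t_rows).all() or not np.isfinite(
        fc_stack[:, ~np.eye(r, dtype=bool)]
    ).all():
        return np.stack([score_subject(fc_stack[i], template) for i in range(n)])
    t_ranks = rankdata(t_rows, axis=1)
    t_c = t_ranks - t_ranks.mean(axis=1, keepdims=True)
    t_norm = np.linalg.norm(t_c, axis=1)
    mask = ~np.eye(r, dtype=bool)
    rows = fc_stack[:, mask].reshape(n, r, r - 1)
    ranks = rankdata(rows, axis=2)
    c = ranks - ranks.mean(axis=2, keepdims=True)
    norm = np.linalg.norm(c, axis=2)
    num = np.einsum("nrk,rk->nr", c, t_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / (norm * t_norm[None, :])


def align_to_axis(map_values: np.ndarray, axis_ranks: np.ndarray, spins) -> dict:
    """Spearman alignment of a regional map with the S-A axis plus spin p.

    Two-sided spin p-value: (#{|rho_null| >= |rho_obs|} + 1) / (n_spins + 1),
    the null rotating the map while the axis stays fixed.
    """
    from .spin import spin_pvalue

    map_values = np.asarray(map_values, dtype=float)
    if map_values.std() == 0:
        raise ValueError("regional map is constant; alignment undefined")
    if len(map_values) != len(axis_ranks):
        raise ValueError("map and axis_ranks lengths differ")
    return spin_pvalue(map_values, np.asarray(axis_ranks, dtype=float), spins)


def map_partial_correlations(
    profiles: np.ndarray,
    measures: pd.DataFrame,
    confounds: pd.DataFrame,
) -> pd.DataFrame:
    """One differentiation map per measure via partial Spearman correlation.

    All variables are rank-transformed, the ranks residualized on the
    confound design (dummy-coded categoricals), and Pearson correlations
    taken between the residualized profile column and each residualized
    measure, per parcel.  Returns a parcels x measures DataFrame.
    """
    profiles = np.asarray(profiles, dtype=float)
    n, r = profiles.shape
    if n < 10:
        raise ValueError("partial-correlation maps need >= 10 subjects")
    if len(measures) != n or len(confounds) != n:
        raise ValueError("measures/confounds must match the profile rows")
    prof_ranks = rankdata(profiles, axis=0)
    conf_ranks = confounds.copy()
    for c in conf_ranks.columns:
        if pd.api.types.is_numeric_dtype(conf_ranks[c]):
            conf_ranks[c] = rankdata(conf_ranks[c].to_numpy(dtype=float))
    prof_res = residualize(prof_ranks, conf_ranks)
    prof_res -= prof_res.mean(axis=0)
    prof_norm = np.linalg.norm(prof_res, axis=0)

    out = {}
    for name in measures.columns:
        vals = rankdata(measures[name].to_numpy(dtype=float))
        res = residualize(vals, conf_ranks)
        res -= res.mean()
        denom = np.linalg.norm(res) * prof_norm
        if np.linalg.norm(res) < 1e-10 * max(np.abs(vals).max(), 1.0):
            warnings.warn(
                f"measure {name!r} constant after residualization; map set missing",
                stacklevel=2,
            )
            out[name] = np.full(r, np.nan)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = (res @ prof_res) / denom
    return pd.DataFrame(out)
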