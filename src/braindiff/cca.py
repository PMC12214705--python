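"""Canonical correlation analysis with 10-fold cross-validation.

The discovery solver standardizes both sets and solves the whitened SVD
form of the generalized eigenproblem Sxx^-1 Sxy Syy^-1 Syx.  Cross
validation fits confound-residualization and the CCA on nine folds,
applies both (never refits) to the left-out fold, concatenates the
test-fold predicted variates, and summarizes them with a permutation
p-value, bootstrap loading intervals, projection onto new samples and a
standardized-contribution regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .phenotypes import build_design


@dataclass
class CcaModel:
    """Fitted canonical weights plus the training standardization."""

    wx: np.ndarray              # (px, L) weights on standardized X
    wy: np.ndarray              # (py, L)
    correlations: np.ndarray    # (L,) descending, in [0, 1]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    x_columns: Optional[tuple] = None
    y_columns: Optional[tuple] = None


@dataclass
class CVLatentResult:
    """Concatenated test-fold variates from k-fold cross-validation."""

    x_scores: np.ndarray        # (n, L) predicted X-set variates
    y_scores: np.ndarray
    r_cv: float                 # Pearson r of the first predicted pair
    fold_assignment: np.ndarray
    seed: int
    k: int
    permutation_p: Optional[float] = None
    loadings: Optional[pd.DataFrame] = None
    models: list = field(default_factory=list)


def _as_matrix(data) -> tuple[np.ndarray, Optional[tuple]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def _check_constant(arr: np.ndarray, cols, label: str) -> None:
    sd = arr.std(axis=0)
    if (sd == 0).any():
        idx = int(np.flatnonzero(sd == 0)[0])
        name = cols[idx] if cols else idx
        raise ValueError(f"constant column in {label}: {name!r}")


def _whitener(c: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root with eigenvalue clipping."""
    vals, vecs = np.linalg.eigh(c)
    keep = vals > eps * vals.max()
    inv_sqrt = np.zeros_like(vals)
    inv_sqrt[keep] = 1.0 / np.sqrt(vals[keep])
    return (vecs * inv_sqrt) @ vecs.T


def _cca_core(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CCA on already-standardized arrays; returns (wx, wy, correlations)."""
    n = xs.shape[0]
    cxx = xs.T @ xs / (n - 1)
    cyy = ys.T @ ys / (n - 1)
    cxy = xs.T @ ys / (n - 1)
    kx = _whitener(cxx)
    ky = _whitener(cyy)
    u, s, vt = np.linalg.svd(kx @ cxy @ ky)
    L = min(xs.shape[1], ys.shape[1])
    wx = kx @ u[:, :L]
    wy = ky @ vt[:L].T
    # deterministic sign: largest-|weight| element of each X vector positive
    for j in range(L):
        pivot = np.argmax(np.abs(wx[:, j]))
        if wx[pivot, j] < 0:
            wx[:, j] *= -1
            wy[:, j] *= -1
    return wx, wy, np.clip(s[:L], 0.0, 1.0)


def fit_cca(x, y) -> CcaModel:
    """Discovery CCA: maximally correlated variate pairs of two sets.

    Columns are standardized internally; the solution solves the whitened
    cross-covariance SVD, equivalent to the generalized eigenproblem
    Sxx^-1 Sxy Syy^-1 Syx.  When n <= px + py the within-set covariances
    are rank-regularized through the pseudo-inverse whitener (with a
    warning).
    """
    xa, x_cols = _as_matrix(x)
    ya, y_cols = _as_matrix(y)
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    _check_constant(xa, x_cols, "X")
    _check_constant(ya, y_cols, "Y")
    if xa.shape[0] <= xa.shape[1] + ya.shape[1]:
        warnings.warn(
            "n <= p_x + p_y: CCA is rank-regularized via the pseudo-inverse",
            stacklevel=2,
        )
    x_mean, x_sd = xa.mean(axis=0), xa.std(axis=0, ddof=1)
    y_mean, y_sd = ya.mean(axis=0), ya.std(axis=0, ddof=1)
    xs = (xa - x_mean) / x_sd
    ys = (ya - y_mean) / y_sd
    wx, wy, corr = _cca_core(xs, ys)
    return CcaModel(
        wx=wx, wy=wy, correlations=corr,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        x_columns=x_cols, y_columns=y_cols,
    )


def project_variate(model: CcaModel, x_new, side: str = "x") -> np.ndarray:
    """Apply training standardization and weights to new data (no refit)."""
    arr, cols = _as_matrix(x_new)
    ref_cols = model.x_columns if side == "x" else model.y_columns
    if cols is not None and ref_cols is not None:
        if tuple(cols) != tuple(ref_cols):
            missing = set(ref_cols) - set(cols)
            if missing:
                raise ValueError(f"missing columns in projection data: {sorted(missing)}")
            arr = pd.DataFrame(arr, columns=cols)[list(ref_cols)].to_numpy()
    mean, sd, w = (
        (model.x_mean, model.x_sd, model.wx)
        if side == "x"
        else (model.y_mean, model.y_sd, model.wy)
    )
    if arr.shape[1] != len(mean):
        raise ValueError("projection data has the wrong number of columns")
    return (arr - mean) / sd @ w


# ---------------------------------------------------------------------------
# confound residualization fitted on training rows only
# ---------------------------------------------------------------------------


class _ConfoundModel:
    def __init__(self, design: np.ndarray, train_idx: np.ndarray):
        self.design = design
        dtr = design[train_idx]
        rank = np.linalg.matrix_rank(dtr)
        if rank < dtr.shape[1]:
            warnings.warn(
                "confound design rank-deficient within a training fold; "
                "pseudo-inverse used",
                stacklevel=3,
            )
        self.pinv = np.linalg.pinv(dtr)
        self.train_idx = train_idx

    def apply(self, values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        beta = self.pinv @ values[self.train_idx]
        return values[idx] - self.design[idx] @ beta


def _fold_indices(n: int, k: int, seed: int) -> list:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def _cv_scores(
    xa: np.ndarray,
    ya: np.ndarray,
    conf_design: Optional[np.ndarray],
    folds: list,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Inner CV loop shared by the observed fit and every permutation."""
    n = xa.shape[0]
    x_scores = np.empty(n)
    y_scores = np.empty(n)
    ref_wx = None
    models = []
    all_idx = np.arange(n)
    for test in folds:
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        if conf_design is not None:
            cm = _ConfoundModel(conf_design, train)
            xtr, xte = cm.apply(xa, train), cm.apply(xa, test)
            cm_y = _ConfoundModel(conf_design, train)
            ytr, yte = cm_y.apply(ya, train), cm_y.apply(ya, test)
        else:
            xtr, xte = xa[train], xa[test]
            ytr, yte = ya[train], ya[test]
        x_mean, x_sd = xtr.mean(axis=0), xtr.std(axis=0, ddof=1)
        y_mean, y_sd = ytr.mean(axis=0), ytr.std(axis=0, ddof=1)
        x_sd[x_sd == 0] = 1.0
        y_sd[y_sd == 0] = 1.0
        wx, wy, _ = _cca_core((xtr - x_mean) / x_sd, (ytr - y_mean) / y_sd)
        if ref_wx is None:
            ref_wx = wx[:, 0]
        elif wx[:, 0] @ ref_wx < 0:  # align fold signs to the first fold
            wx[:, 0] *= -1
            wy[:, 0] *= -1
        x_scores[test] = (xte - x_mean) / x_sd @ wx[:, 0]
        y_scores[test] = (yte - y_mean) / y_sd @ wy[:, 0]
        models.append((wx, wy, x_mean, x_sd, y_mean, y_sd))
    return x_scores, y_scores, models


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def cross_validate_cca(
    x,
    y,
    confounds: Optional[pd.DataFrame] = None,
    k: int = 10,
    seed: int = 0,
) -> CVLatentResult:
    """k-fold cross-validated CCA with train-side confound removal.

    Confound regressions, standardization and canonical weights are all
    estimated on the training folds and applied unchanged to the test
    fold; the first predicted variate pair is concatenated over test
    folds (signs aligned across folds) and summarized by r_CV.
    """
    xa, _ = _as_matrix(x)
    ya, _ = _as_matrix(y)
    n = xa.shape[0]
    if k > n // 3:
        raise ValueError(f"k={k} too large for n={n} (need k <= n/3)")
    conf_design = build_design(confounds) if confounds is not None else None
    folds = _fold_indices(n, k, seed)
    x_scores, y_scores, models = _cv_scores(xa, ya, conf_design, folds)
    assignment = np.empty(n, dtype=int)
    for f, test in enumerate(folds):
        assignment[test] = f
    return CVLatentResult(
        x_scores=x_scores[:, None],
        y_scores=y_scores[:, None],
        r_cv=_pearson(x_scores, y_scores),
        fold_assignment=assignment,
        seed=seed,
        k=k,
        models=models,
    )


def permutation_pvalue(
    x,
    y,
    confounds: Optional[pd.DataFrame] = None,
    k: int = 10,
    seed: int = 0,
    n_perm: int = 1000,
    spins: Optional[np.ndarray] = None,
    observed: Optional[CVLatentResult] = None,
) -> tuple[float, float]:
    """Permutation p for the cross-validated canonical correlation.

    Each draw permutes the rows of the Y set against fixed X (or applies
    a spin row-permutation when parcels are the rows) and re-runs the
    entire cross-validation loop, confound residualization included.
    p = (#{|r_null| >= |r_obs|} + 1) / (n_perm + 1).  Returns (r_cv, p).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    xa, _ = _as_matrix(x)
    ya, _ = _as_matrix(y)
    n = xa.shape[0]
    conf_design = None
    if confounds is not None:
        conf_design = build_design(confounds)
    folds = _fold_indices(n, k, seed)
    if observed is not None:
        r_obs = observed.r_cv
    else:
        xs, ys_, _ = _cv_scores(xa, ya, conf_design, folds)
        r_obs = _pearson(xs, ys_)
    rng = np.random.default_rng(seed + 1)
    if spins is not None:
        perms = np.asarray(spins)
        if perms.shape[0] < n_perm:
            raise ValueError("not enough spin permutations supplied")
        draws = (perms[i] for i in range(n_perm))
    else:
        draws = (rng.permutation(n) for _ in range(n_perm))
    exceed = 0
    for perm in draws:
        xs, ys_, _ = _cv_scores(xa, ya[perm], conf_design, folds)
        if abs(_pearson(xs, ys_)) >= abs(r_obs):
            exceed += 1
    return r_obs, (exceed + 1) / (n_perm + 1)


def bootstrap_loadings(
    result: CVLatentResult,
    observed: pd.DataFrame,
    side: str = "y",
    confounds: Optional[pd.DataFrame] = None,
    n_boot: int = 2000,
    level: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for test-fold variate loadings.

    A loading is the correlation between an observed variable and the
    concatenated predicted variate of its set, confound-adjusted when
    confounds are given.  A variable is "robust" when its CI excludes 0.
    Degenerate resamples (constant variate) are redrawn and counted.
    """
    scores = (result.y_scores if side == "y" else result.x_scores)[:, 0]
    vals = observed.to_numpy(dtype=float)
    if confounds is not None:
        from .phenotypes import residualize

        vals = residualize(vals, confounds)
        scores = residualize(scores, confounds)
    n, p = vals.shape
    rng = np.random.default_rng(seed)
    est = np.array([_pearson(vals[:, j], scores) for j in range(p)])
    boots = np.empty((n_boot, p))
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        s = scores[idx]
        if s.std() == 0:
            redrawn += 1
            continue
        v = vals[idx]
        sc = s - s.mean()
        vc = v - v.mean(axis=0)
        denom = np.linalg.norm(sc) * np.linalg.norm(vc, axis=0)
        denom[denom == 0] = np.inf
        boots[b] = (sc @ vc) / denom
        b += 1
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "variable": list(observed.columns),
            "loading": est,
            "ci_low": np.minimum(lo, est),
            "ci_high": np.maximum(hi, est),
            "robust": (lo > 0) | (hi < 0),
            "redrawn_resamples": redrawn,
        }
    )


def standardized_contributions(
    variate: np.ndarray,
    observed_vars: pd.DataFrame,
    controls: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """OLS of the z-scored variate on z-scored predictors (+ controls).

    Returns per-predictor standardized coefficients with t statistics and
    95% confidence intervals, akin to standardized canonical
    coefficients.  Heavily collinear designs (condition number > 1e8) are
    rejected.
    """
    import statsmodels.api as sm

    y = np.asarray(variate, dtype=float)
    y = (y - y.mean()) / y.std(ddof=1)
    blocks = [(observed_vars[c].to_numpy(dtype=float)) for c in observed_vars.columns]
    names = list(observed_vars.columns)
    zx = np.column_stack([(b - b.mean()) / b.std(ddof=1) for b in blocks])
    design = zx
    if controls is not None:
        ctrl = build_design(controls)[:, 1:]
        ctrl = ctrl - ctrl.mean(axis=0)
        # constant controls carry no information; normalize the rest so
        # conditioning reflects collinearity, not units
        norms = np.linalg.norm(ctrl, axis=0)
        keep = norms > 0
        design = np.column_stack([zx, ctrl[:, keep] / norms[keep]])
    design_full = sm.add_constant(design)
    if np.linalg.cond(design_full) > 1e8:
        raise ValueError("predictor design condition number exceeds 1e8")
    if design_full.shape[0] <= design_full.shape[1]:
        raise ValueError("more predictors than observations")
    fit = sm.OLS(y, design_full).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = slice(1, 1 + len(names))
    return pd.DataFrame(
        {
            "predictor": names,
            "coefficient": fit.params[rows],
            "t": fit.tvalues[rows],
            "p": fit.pvalues[rows],
            "ci_low": ci[rows, 0],
            "ci_high": ci[rows, 1],
        }
    )
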