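"""PLS correlation across T1/T2 conditions with permutation and bootstrap.

The discovery model applies an SVD to the condition-wise correlation
matrix between the regional brain set and the behavioral set: the
correlation blocks (one behaviors x parcels block per condition) are
stacked row-wise, so the decomposition yields one brain salience vector
per latent variable, shared across conditions, and behavior saliences
that are condition-specific.  Inference uses row-permutation of the
behavioral set (one shared subject ordering across conditions) and
subject bootstrap ratios; the cross-validated variant re-derives test
fold scores from training-fold saliences before re-applying the SVD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cca import _fold_indices, _pearson
from .phenotypes import build_design


@dataclass
class PlsModel:
    """Saliences and singular values of the condition-wise correlation SVD."""

    brain_saliences: np.ndarray       # (R, L) unit-norm, shared across conditions
    behavior_saliences: np.ndarray    # (C, B, L) condition-wise
    singular_values: np.ndarray       # (L,) descending
    covariance_explained: np.ndarray  # (L,) fractions summing to 1
    n_conditions: int

    @property
    def n_latent(self) -> int:
        return len(self.singular_values)


@dataclass
class BootstrapPls:
    """Bootstrap reliability of the first latent variable."""

    bsr: np.ndarray                   # (R,) brain weight / bootstrap SD
    reliable: np.ndarray              # |BSR| > threshold
    threshold: float
    behavior_corr: np.ndarray         # (C, B) observed behavior-LV correlations
    behavior_ci: np.ndarray           # (C, B, 2)
    redrawn_resamples: int = 0


def _split_conditions(brain, n_conditions: int) -> list:
    """Split subjects x (R * C) into C blocks of subjects x R."""
    if isinstance(brain, (list, tuple)):
        blocks = [np.asarray(b, dtype=float) for b in brain]
    else:
        arr = np.asarray(brain, dtype=float)
        if arr.shape[1] % n_conditions:
            raise ValueError("brain column count is not divisible by n_conditions")
        r = arr.shape[1] // n_conditions
        blocks = [arr[:, c * r : (c + 1) * r] for c in range(n_conditions)]
    if len({b.shape for b in blocks}) != 1:
        raise ValueError("condition blocks must share subjects and parcel count")
    return blocks


def _corr_matrix(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Correlations between columns of y (B) and columns of x (R) -> (B, R)."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    ynorm = np.linalg.norm(yc, axis=0)
    xnorm = np.linalg.norm(xc, axis=0)
    denom = np.outer(ynorm, xnorm)
    denom[denom == 0] = np.inf
    return (yc.T @ xc) / denom


def _stacked_corr(blocks: list, behavior: np.ndarray) -> np.ndarray:
    return np.vstack([_corr_matrix(behavior, b) for b in blocks])


def fit_pls(brain, behavior, n_conditions: int = 2) -> PlsModel:
    """SVD of the stacked condition-wise brain-behavior correlations.

    ``brain`` is subjects x (R * n_conditions) (or a list of per-condition
    blocks); ``behavior`` subjects x B.  Covariance explained per latent
    variable is s_l^2 / sum(s^2).
    """
    blocks = _split_conditions(brain, n_conditions)
    y = np.asarray(behavior, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[1] == 0:
        raise ValueError("behavior set has no columns")
    if y.shape[0] != blocks[0].shape[0]:
        raise ValueError("brain and behavior must share subjects")
    for arr, label in ((y, "behavior"), *((b, "brain") for b in blocks)):
        if (arr.std(axis=0) == 0).any():
            raise ValueError(f"constant column in the {label} set")
    m = _stacked_corr(blocks, y)  # (C*B, R)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    L = len(s)
    b = y.shape[1]
    brain_sal = vt.T  # (R, L)
    behav_sal = u.reshape(len(blocks), b, L)
    for j in range(L):  # deterministic sign: top-|weight| parcel positive
        pivot = np.argmax(np.abs(brain_sal[:, j]))
        if brain_sal[pivot, j] < 0:
            brain_sal[:, j] *= -1
            behav_sal[:, :, j] *= -1
    total = (s**2).sum()
    return PlsModel(
        brain_saliences=brain_sal,
        behavior_saliences=behav_sal,
        singular_values=s,
        covariance_explained=s**2 / total,
        n_conditions=len(blocks),
    )


def lv_scores(model: PlsModel, brain, behavior, lv: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Brain and behavior latent-variable scores per condition (n, C)."""
    blocks = _split_conditions(brain, model.n_conditions)
    y = np.asarray(behavior, dtype=float)
    brain_scores = np.column_stack([b @ model.brain_saliences[:, lv] for b in blocks])
    behav_scores = np.column_stack(
        [y @ model.behavior_saliences[c, :, lv] for c in range(model.n_conditions)]
    )
    return brain_scores, behav_scores


def permutation_significance(
    brain,
    behavior,
    n_conditions: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[PlsModel, np.ndarray]:
    """Permutation p per latent variable for the discovery PLS.

    The null permutes behavioral rows with one shared subject ordering
    for every condition, preserving the T1/T2 interdependence of the
    brain data; p_l = (#{s_l_null >= s_l} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    blocks = _split_conditions(brain, n_conditions)
    y = np.asarray(behavior, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    model = fit_pls(blocks, y, n_conditions)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(model.n_latent)
    for _ in range(n_perm):
        perm = rng.permutation(y.shape[0])
        m = _stacked_corr(blocks, y[perm])
        s = np.linalg.svd(m, compute_uv=False)
        exceed += s[: model.n_latent] >= model.singular_values
    p = (exceed + 1) / (n_perm + 1)
    return model, p


def bootstrap_ratios(
    model: PlsModel,
    brain,
    behavior,
    n_boot: int = 2000,
    threshold: float = 2.75,
    seed: int = 0,
    lv: int = 0,
) -> BootstrapPls:
    """Subject-bootstrap reliability of the first LV's parcel weights.

    BSR = original salience / bootstrap SD; parcels with |BSR| above the
    threshold (2.75 ~ a 99% normal interval) are flagged reliable.
    Behavior-LV correlations get percentile 95% CIs.  Resamples with a
    constant behavior column are redrawn and counted.
    """
    blocks = _split_conditions(brain, model.n_conditions)
    y = np.asarray(behavior, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    v0 = model.brain_saliences[:, lv]
    brain_scores, _ = lv_scores(model, blocks, y, lv)
    behav_corr = np.stack(
        [
            np.array([_pearson(y[:, b], brain_scores[:, c]) for b in range(y.shape[1])])
            for c in range(model.n_conditions)
        ]
    )
    sal_draws = np.empty((n_boot, len(v0)))
    corr_draws = np.empty((n_boot, model.n_conditions, y.shape[1]))
    redrawn = 0
    b_done = 0
    while b_done < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if (yb.std(axis=0) == 0).any():
            redrawn += 1
            continue
        bb = [blk[idx] for blk in blocks]
        m = _stacked_corr(bb, yb)
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        v = vt[lv]
        if v @ v0 < 0:
            v = -v
        sal_draws[b_done] = v
        scores = np.column_stack([blk @ v for blk in bb])
        for c in range(model.n_conditions):
            for j in range(y.shape[1]):
                corr_draws[b_done, c, j] = _pearson(yb[:, j], scores[:, c])
        b_done += 1
    sd = sal_draws.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bsr = np.where(sd > 0, v0 / sd, np.inf * np.sign(v0))
    ci = np.stack(
        [
            np.quantile(corr_draws, 0.025, axis=0),
            np.quantile(corr_draws, 0.975, axis=0),
        ],
        axis=-1,
    )
    return BootstrapPls(
        bsr=bsr,
        reliable=np.abs(bsr) > threshold,
        threshold=threshold,
        behavior_corr=behav_corr,
        behavior_ci=ci,
        redrawn_resamples=redrawn,
    )


@dataclass
class CVPlsResult:
    """Test-fold PLS summary concatenated over cross-validation folds."""

    brain_scores: np.ndarray        # (n, C) predicted brain LV per condition
    behavior_scores: np.ndarray     # (n, C) predicted behavior LV per condition
    condition_corr: np.ndarray      # (C,) corr(brain LV, behavior LV) per condition
    condition_ci: np.ndarray        # (C, 2) bootstrap percentile CIs
    singular_value: float           # first singular value of the test-fold SVD
    shared_variance: float          # covariance-explained fraction of the first LV
    permutation_p: float
    cv_loadings: np.ndarray         # (C, R) corr of each parcel with its brain LV
    fold_assignment: np.ndarray
    seed: int


def cross_validate_pls(
    brain,
    behavior,
    confounds: Optional[pd.DataFrame] = None,
    n_conditions: int = 2,
    k: int = 10,
    n_perm: int = 1000,
    n_boot: int = 2000,
    seed: int = 0,
) -> CVPlsResult:
    """Four-step cross-validated PLS significance test.

    Per left-out fold: (1) test-fold parcel data in each condition is
    weighted by the training-fold brain salience; (2) test-fold behavior
    is weighted by the training-fold condition-wise behavior saliences;
    (3) the SVD is applied to the condition-wise correlation between the
    weighted parcel and behavior matrices concatenated over test folds;
    (4) the null permutes the behavioral rows with a single subject
    ordering shared by all conditions and re-runs the complete procedure
    — training saliences included — so the null statistic is exactly
    exchangeable with the observed one under independence.  Confound
    residualization, when requested, is fitted on training folds only.
    """
    blocks = _split_conditions(brain, n_conditions)
    y = np.asarray(behavior, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, r = blocks[0].shape
    b = y.shape[1]
    conf_design = build_design(confounds) if confounds is not None else None
    folds = _fold_indices(n, k, seed)
    assignment = np.empty(n, dtype=int)

    # per-fold caches fixed across permutations: indices, confound
    # projectors and residualized parcel data
    fold_cache = []
    all_idx = np.arange(n)
    for f, test in enumerate(folds):
        assignment[test] = f
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        if conf_design is not None:
            pinv = np.linalg.pinv(conf_design[train])
            beta_blk = [pinv @ blk[train] for blk in blocks]
            blk_tr = [
                blk[train] - conf_design[train] @ beta
                for blk, beta in zip(blocks, beta_blk)
            ]
            blk_te = [
                blk[test] - conf_design[test] @ beta
                for blk, beta in zip(blocks, beta_blk)
            ]
        else:
            pinv = None
            blk_tr = [blk[train] for blk in blocks]
            blk_te = [blk[test] for blk in blocks]
        fold_cache.append((train, test, pinv, blk_tr, blk_te))

    def _full_stat(y_in: np.ndarray, collect: bool = False):
        """One full run of steps (1)-(3) for a given behavior matrix."""
        z_weighted = [np.empty((n, b)) for _ in range(n_conditions)]
        w_all = [np.empty((n, r)) for _ in range(n_conditions)]
        artifacts = None
        if collect:
            artifacts = {
                "brain_scores": np.empty((n, n_conditions)),
                "behav_scores": np.empty((n, n_conditions)),
                "blocks_res": [np.empty((n, r)) for _ in range(n_conditions)],
            }
        ref_v = None
        for train, test, pinv, blk_tr, blk_te in fold_cache:
            if pinv is not None:
                beta_y = pinv @ y_in[train]
                ytr = y_in[train] - conf_design[train] @ beta_y
                yte = y_in[test] - conf_design[test] @ beta_y
            else:
                ytr, yte = y_in[train], y_in[test]
            m_train = _stacked_corr(blk_tr, ytr)
            u_full, _, vt = np.linalg.svd(m_train, full_matrices=False)
            v = vt[0]
            u = u_full[:, 0].reshape(n_conditions, b)
            if ref_v is None:
                ref_v = v
            elif v @ ref_v < 0:
                v, u = -v, -u
            for c in range(n_conditions):
                w_all[c][test] = blk_te[c] * v[None, :]
                z_weighted[c][test] = yte * u[c][None, :]
            if collect:
                for c in range(n_conditions):
                    artifacts["brain_scores"][test, c] = blk_te[c] @ v
                    artifacts["behav_scores"][test, c] = yte @ u[c]
                    artifacts["blocks_res"][c][test] = blk_te[c]
        m = np.vstack(
            [_corr_matrix(z_weighted[c], w_all[c]) for c in range(n_conditions)]
        )
        s = np.linalg.svd(m, compute_uv=False)
        return s, artifacts

    s_test, artifacts = _full_stat(y, collect=True)
    brain_scores = artifacts["brain_scores"]
    behav_scores = artifacts["behav_scores"]
    blocks_res = artifacts["blocks_res"]
    rng = np.random.default_rng(seed + 17)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)  # one shared ordering for every condition
        s_null, _ = _full_stat(y[perm])
        if s_null[0] >= s_test[0]:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    condition_corr = np.array(
        [_pearson(brain_scores[:, c], behav_scores[:, c]) for c in range(n_conditions)]
    )
    ci = np.empty((n_conditions, 2))
    rng_b = np.random.default_rng(seed + 31)
    draws = np.empty((n_boot, n_conditions))
    for bi in range(n_boot):
        idx = rng_b.integers(0, n, n)
        for c in range(n_conditions):
            draws[bi, c] = _pearson(brain_scores[idx, c], behav_scores[idx, c])
    ci[:, 0] = np.quantile(draws, 0.025, axis=0)
    ci[:, 1] = np.quantile(draws, 0.975, axis=0)

    cv_loadings = np.stack(
        [
            np.array([_pearson(blocks_res[c][:, j], brain_scores[:, c]) for j in range(r)])
            for c in range(n_conditions)
        ]
    )
    return CVPlsResult(
        brain_scores=brain_scores,
        behavior_scores=behav_scores,
        condition_corr=condition_corr,
        condition_ci=ci,
        singular_value=float(s_test[0]),
        shared_variance=float(s_test[0] ** 2 / (s_test**2).sum()),
        permutation_p=p,
        cv_loadings=cv_loadings,
        fold_assignment=assignment,
        seed=seed,
    )
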