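"""Functional-connectivity construction and motion quality control.

Covers the resting-state nuisance chain applied after minimal
preprocessing: framewise displacement, band-stop filtering of motion
regressors in the respiratory range, expansion to 24 motion terms,
nuisance regression, Pearson/Fisher-z coupling matrices, run averaging,
QC-FC diagnostics and motion-based subject exclusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

#: clip applied to |r| before the Fisher transform so atanh stays finite
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class MotionSummary:
    """Per-frame framewise displacement plus scalar summaries (mm)."""

    fd: np.ndarray
    mean_fd: float
    max_param_excursion: float

    def frac_frames_below(self, threshold: float) -> float:
        return float(np.mean(self.fd < threshold))


@dataclass
class FCMatrix:
    """R x R Fisher-z coupling matrix; the diagonal is masked (NaN)."""

    z: np.ndarray
    symmetric: bool = True

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> MotionSummary:
    """Power-style FD: sum of |backward differences|, rotations projected
    onto a sphere of ``head_radius_mm``.

    ``motion`` is frames x 6 (three translations in mm, three rotations
    in radians).  FD is undefined for the first frame and set to 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be frames x 6, got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    deltas = np.abs(np.diff(motion, axis=0))
    fd = deltas[:, :3].sum(axis=1) + head_radius_mm * deltas[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    excursion = np.abs(motion[:, :3]).max() if motion.size else 0.0
    excursion = max(excursion, head_radius_mm * np.abs(motion[:, 3:]).max())
    return MotionSummary(fd=fd, mean_fd=float(fd.mean()), max_param_excursion=float(excursion))


def filter_motion_regressors(
    motion: np.ndarray,
    tr_seconds: float,
    band_hz: tuple = (0.31, 0.43),
    order: int = 2,
) -> np.ndarray:
    """Band-stop the motion parameters over the respiratory band.

    A forward-backward (zero-phase) Butterworth band-stop; the default
    order meets the contract that in-band sinusoids are attenuated below
    10% amplitude while DC and far out-of-band content is preserved
    within 5%.
    """
    motion = np.asarray(motion, dtype=float)
    nyquist = 0.5 / tr_seconds
    lo, hi = band_hz
    if hi >= nyquist:
        raise ValueError(
            f"stop band {band_hz} reaches the Nyquist frequency "
            f"({nyquist:.4f} Hz at TR={tr_seconds}s)"
        )
    sos = signal.butter(order, band_hz, btype="bandstop", fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, motion, axis=0)


def expand_motion_terms(motion: np.ndarray) -> np.ndarray:
    """24 motion regressors: 6 parameters, their backward-difference
    derivatives (first row 0), and the squares of those 12."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be frames x 6, got {motion.shape}")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    base = np.hstack([motion, deriv])
    return np.hstack([base, base**2])


def regress_nuisance(
    ts: np.ndarray, nuisance: np.ndarray, rtol: float = 1e-8
) -> np.ndarray:
    """OLS-remove nuisance columns (plus an intercept) from each parcel series.

    Residuals are checked to be orthogonal to the centered nuisance set;
    a rank-deficient design falls back to the pseudo-inverse with a
    warning.
    """
    ts = np.asarray(ts, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != ts.shape[0]:
        raise ValueError("nuisance frame count does not match time series")
    design = np.column_stack([np.ones(ts.shape[0]), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank}/{design.shape[1]}); "
            "using pseudo-inverse",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    resid = ts - design @ beta
    centered = design[:, 1:] - design[:, 1:].mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    ok = norms > 0
    if ok.any():
        resid_norm = np.linalg.norm(resid, axis=0)
        in_norm = np.linalg.norm(ts, axis=0)
        # columns whose residual vanished are orthogonal by convention
        check = resid_norm > rtol * np.maximum(in_norm, 1.0)
        if check.any():
            dots = np.abs((centered[:, ok] / norms[ok]).T @ resid[:, check])
            cos = dots / resid_norm[check][None, :]
            if cos.max() > rtol * 100:
                raise AssertionError(
                    f"nuisance regression failed orthogonality check ({cos.max():.2e})"
                )
    return resid


def compute_fc(ts: np.ndarray, min_frames: int = 20) -> FCMatrix:
    """Pairwise Pearson correlations, Fisher z-transformed.

    |r| is clipped below 1 so atanh never diverges; parcels with zero
    variance get NaN edges (and are logged).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    if dead.any():
        logger.warning("zero-variance parcels: %s", np.flatnonzero(dead).tolist())
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(z, np.nan)
    return FCMatrix(z=z)


def average_fc(runs: Sequence[FCMatrix]) -> FCMatrix:
    """Element-wise mean across runs in z-space (NaN-aware per edge)."""
    if len(runs) == 0:
        raise ValueError("cannot average an empty list of runs")
    shapes = {run.z.shape for run in runs}
    if len(shapes) != 1:
        raise ValueError(f"runs have mismatched dimensions: {shapes}")
    stack = np.stack([run.z for run in runs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    np.fill_diagonal(mean, np.nan)
    return FCMatrix(z=mean)


@dataclass
class QcFcResult:
    """Edge-wise motion-artifact diagnostics."""

    edge_qcfc: np.ndarray          # (E,) correlation FD vs FC per edge
    median_qcfc: float
    median_abs_qcfc: float
    distance_rho: float            # Spearman of QC-FC vs inter-centroid distance
    null_median_width: float       # SD of medians under FD permutation


def _edge_upper(fc_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = fc_stack.shape[-1]
    iu = np.triu_indices(r, k=1)
    return fc_stack[:, iu[0], iu[1]], iu[0], iu[1]


def qcfc(
    fc_stack: np.ndarray,
    mean_fd: np.ndarray,
    geometry=None,
    n_null: int = 100,
    seed: int = 0,
) -> QcFcResult:
    """Correlate subject mean FD with every FC edge.

    Returns the edge-wise correlations, their median and median absolute
    value, the Spearman correlation of QC-FC with inter-centroid
    Euclidean distance (NaN without geometry), and the width of the
    median under FD shuffling as a null reference.
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    if fc_stack.shape[0] < 10:
        raise ValueError("QC-FC needs >= 10 subjects")
    if mean_fd.std() == 0:
        raise ValueError("mean FD is constant across subjects: QC-FC undefined")
    edges, ei, ej = _edge_upper(fc_stack)

    def _corr_with(v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        ec = edges - edges.mean(axis=0)
        denom = np.linalg.norm(vc) * np.linalg.norm(ec, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (vc @ ec) / denom

    corr = _corr_with(mean_fd)
    rng = np.random.default_rng(seed)
    null_medians = np.array(
        [np.nanmedian(_corr_with(rng.permutation(mean_fd))) for _ in range(n_null)]
    )
    if geometry is not None:
        dist = np.linalg.norm(
            geometry.centroid[ei] - geometry.centroid[ej], axis=1
        )
        valid = np.isfinite(corr)
        distance_rho = float(spearmanr(corr[valid], dist[valid]).statistic)
    else:
        distance_rho = float("nan")
    return QcFcResult(
        edge_qcfc=corr,
        median_qcfc=float(np.nanmedian(corr)),
        median_abs_qcfc=float(np.nanmedian(np.abs(corr))),
        distance_rho=distance_rho,
        null_median_width=float(null_medians.std()),
    )


def apply_motion_exclusion(
    summaries: dict,
    mean_fd_max: float = 0.20,
    frac_below: float = 0.80,
    max_motion_mm: float = 5.0,
) -> list:
    """Retain subjects passing all three (strict) motion criteria.

    mean FD strictly below ``mean_fd_max``; strictly more than
    ``frac_below`` of frames with FD below ``mean_fd_max``; maximum
    parameter excursion strictly below ``max_motion_mm``.  Subjects with
    a missing summary are excluded and logged.
    """
    retained = []
    for subject, summary in summaries.items():
        if summary is None:
            logger.warning("subject %s excluded: missing motion summary", subject)
            continue
        ok = (
            summary.mean_fd < mean_fd_max
            and summary.frac_frames_below(mean_fd_max) >= frac_below
            and summary.max_param_excursion < max_motion_mm
        )
        if ok:
            retained.append(subject)
    return retained
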