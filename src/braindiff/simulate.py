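"""Synthetic cohort generators with planted ground truth.

Every input the analysis pipeline needs is generated here: parcel
geometry on the sphere, an adult reference cohort with a planted
sex-by-gradient effect on functional connectivity, a longitudinal
adolescent cohort realizing the linear-Gaussian causal chain
PRS -> T1 brain differentiation -> T2 physiology -> rising internalizing
symptoms, a young-adult mortality cohort with Gompertz event times, and
genotype panels for polygenic scoring.  All generators are bitwise
deterministic for a fixed configuration seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    BIOMARKERS,
    BIOMARKER_MOMENTS,
    BIOMARKER_RANGES,
    CBCL_SCALES,
    HORMONE_MOMENTS_T1,
    HORMONE_MOMENTS_T2,
    INTERNALIZING_SCALES,
    SimulationConfig,
)

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

PRS_DISORDERS = ("anxiety", "depression", "adhd")


@dataclass
class ParcelGeometry:
    """Parcel centroids on the unit sphere, half per hemisphere."""

    parcel_id: np.ndarray      # (R,) 1..R
    hemisphere: np.ndarray     # (R,) 'L' / 'R'
    centroid: np.ndarray       # (R, 3), unit norm

    @property
    def n_rois(self) -> int:
        return len(self.parcel_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_id,
                "hemisphere": self.hemisphere,
                "x": self.centroid[:, 0],
                "y": self.centroid[:, 1],
                "z": self.centroid[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelGeometry":
        df = pd.read_csv(path, sep="\t")
        return cls(
            parcel_id=df["parcel_id"].to_numpy(),
            hemisphere=df["hemisphere"].to_numpy(),
            centroid=df[["x", "y", "z"]].to_numpy(dtype=float),
        )


@dataclass
class ReferenceCohort:
    """Adult cohort used to fit the sexual-differentiation template."""

    fc: np.ndarray          # (n, R, R) Fisher-z, diagonal NaN
    sex: np.ndarray         # (n,) +1 male / -1 female
    covariates: pd.DataFrame


@dataclass
class AdolescentCohort:
    """Longitudinal adolescent cohort carrying the planted causal chain."""

    fc_t1: np.ndarray       # (n, R, R)
    fc_t2: np.ndarray
    phenotypes: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def generate_parcel_geometry(n_rois: int, seed: int = 0) -> ParcelGeometry:
    """Quasi-uniform centroids, a Fibonacci layout per half-sphere.

    Left-hemisphere parcels occupy x < 0, right-hemisphere parcels x > 0;
    the seed rotates the azimuthal phase so distinct seeds give distinct
    (but equally uniform) layouts.
    """
    if n_rois % 2 != 0:
        raise ValueError("n_rois must be even: half the parcels per hemisphere")
    if n_rois < 8:
        raise ValueError("n_rois must be >= 8")
    half = n_rois // 2
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    i = np.arange(half)
    # |x| in (0, 1): distance from the mid-sagittal plane
    u = (i + 0.5) / half
    theta = i * _GOLDEN_ANGLE + phase
    r = np.sqrt(1.0 - u**2)
    right = np.column_stack([u, r * np.cos(theta), r * np.sin(theta)])
    left = right * np.array([-1.0, 1.0, 1.0])
    centroid = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half)
    return ParcelGeometry(
        parcel_id=np.arange(1, n_rois + 1),
        hemisphere=hemisphere,
        centroid=centroid,
    )


def resolve_axis_ranks(config: SimulationConfig, geometry: ParcelGeometry) -> np.ndarray:
    """Planted sensorimotor-association gradient as ranks 1..R.

    Defaults to the rank of the centroid z coordinate, a spatially smooth
    map so spin nulls face realistic spatial autocorrelation.
    """
    if config.axis_ranks is not None:
        return np.asarray(config.axis_ranks, dtype=float)
    from scipy.stats import rankdata

    return rankdata(geometry.centroid[:, 2], method="ordinal").astype(float)


def _unit_axis(axis_ranks: np.ndarray) -> np.ndarray:
    """Min-max normalize planted axis ranks to [0, 1]."""
    a = np.asarray(axis_ranks, dtype=float)
    lo, hi = a.min(), a.max()
    if hi == lo:
        raise ValueError("axis_ranks are constant")
    return (a - lo) / (hi - lo)


def _axis_edge_pattern(axis_unit: np.ndarray) -> np.ndarray:
    """Additive edge loading: pattern[i, j] = a_i + a_j, diag zero."""
    pattern = axis_unit[:, None] + axis_unit[None, :]
    np.fill_diagonal(pattern, 0.0)
    return pattern


def _axis_product_pattern(axis_unit: np.ndarray) -> np.ndarray:
    """Multiplicative edge loading: pattern[i, j] = a_i * a_j, diag zero.

    Under this form the within-row slope of an individual's FC deviation
    against the template row ordering scales with a_i, so per-region
    similarity profiles load along the planted axis — the property the
    additive form lacks (its a_i term is constant within a row and drops
    out of any row-wise correlation).
    """
    pattern = np.outer(axis_unit, axis_unit)
    np.fill_diagonal(pattern, 0.0)
    return pattern


def _mask_diagonal(fc: np.ndarray) -> np.ndarray:
    r = fc.shape[-1]
    idx = np.arange(r)
    fc[..., idx, idx] = np.nan
    return fc


def _symmetric_noise(rng, n, r, sd) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=(n, r, r))
    iu = np.triu_indices(r, k=1)
    out = np.zeros_like(noise)
    out[:, iu[0], iu[1]] = noise[:, iu[0], iu[1]]
    out += np.transpose(out, (0, 2, 1))
    return out


def _base_fc_mean(rng, r) -> np.ndarray:
    """A fixed mean connectome shared by all subjects.

    Edge means are iid around a positive coupling level so every row has
    (approximately) the same variance; heterogeneous row variances would
    distort per-region similarity profiles in region-dependent ways.
    """
    noise = rng.normal(0.0, 0.15, size=(r, r))
    base = 0.3 + (noise + noise.T) / math.sqrt(2.0)
    np.fill_diagonal(base, 0.0)
    return base


def generate_reference_cohort(
    config: SimulationConfig, geometry: ParcelGeometry
) -> ReferenceCohort:
    """Adults with a sex difference in FC planted along the gradient.

    The male-minus-female mean difference on edge (i, j) equals
    ``sex_effect_scale * (a_i + a_j)`` with ``a`` the unit-normalized
    axis, positive (masculine) on high-axis edges.
    """
    n = config.n_ref_adults
    n_cov = 13  # age, income, education, employment, race, handedness, 6 psych, fd + 2 cognition
    if n < 2 * (n_cov + 2):
        raise ValueError(
            f"n_ref_adults={n} too small: template regression would be "
            f"rank-deficient (need >= {2 * (n_cov + 2)})"
        )
    rng = np.random.default_rng([config.seed, 1])
    r = config.n_rois
    axis = _unit_axis(resolve_axis_ranks(config, geometry))
    pattern = _axis_edge_pattern(axis)
    sex = rng.permuted(np.where(np.arange(n) < n // 2, 1.0, -1.0))

    base = _base_fc_mean(np.random.default_rng([config.seed, 99]), r)
    fc = base[None, :, :] + 0.5 * config.sex_effect_scale * sex[:, None, None] * pattern[None, :, :]
    fc += _symmetric_noise(rng, n, r, config.noise_sd["fc"])
    fc = _mask_diagonal(fc)

    covariates = pd.DataFrame(
        {
            "age": rng.uniform(22.0, 36.0, n),
            "income": rng.lognormal(10.8, 0.6, n),
            "education": rng.normal(14.5, 2.2, n),
            "employment": rng.integers(0, 2, n),
            "race": rng.integers(0, 2, n),
            "handedness": (rng.random(n) < 0.1).astype(int),
            "asr_depression": rng.normal(0.0, 1.0, n),
            "asr_anxiety": rng.normal(0.0, 1.0, n),
            "asr_adhd": rng.normal(0.0, 1.0, n),
            "asr_antisocial": rng.normal(0.0, 1.0, n),
            "asr_somatic": rng.normal(0.0, 1.0, n),
            "asr_avoidant": rng.normal(0.0, 1.0, n),
            "mean_fd": rng.lognormal(-2.0, 0.4, n),
            "fluid_iq": rng.normal(100.0, 15.0, n),
            "crystallized_iq": rng.normal(100.0, 15.0, n),
        }
    )
    return ReferenceCohort(fc=fc, sex=sex, covariates=covariates)


# ---------------------------------------------------------------------------
# genotypes and polygenic scores
# ---------------------------------------------------------------------------

_ALLELES = np.array(["A", "C", "G", "T"])
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def generate_genotypes(
    n_subjects: int, maf: Sequence[float], seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Independent biallelic SNP dosages plus a weights panel.

    Returns (dosages in {0,1,2}, panel) where the panel holds per-SNP
    effect weight, risk allele, other allele and simulated MAF.  Linkage
    is deliberately not simulated (clumping is handled upstream of
    scoring in the real workflow).
    """
    maf = np.asarray(maf, dtype=float)
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf[None, :], size=(n_subjects, len(maf)))
    risk = rng.choice(_ALLELES, size=len(maf))
    other = np.array(
        [rng.choice([a for a in _ALLELES if a != rk]) for rk in risk]
    )
    panel = pd.DataFrame(
        {
            "snp": [f"rs{100 + i}" for i in range(len(maf))],
            "weight": rng.normal(0.0, 0.1, len(maf)),
            "risk_allele": risk,
            "other_allele": other,
            "maf": maf,
        }
    )
    return dosages.astype(float), panel


def score_prs(
    dosages: np.ndarray,
    weights: Sequence[float],
    risk_alleles: Optional[Sequence[str]] = None,
    other_alleles: Optional[Sequence[str]] = None,
    maf: Optional[Sequence[float]] = None,
    maf_threshold: float = 0.05,
    exclude_ambiguous: bool = True,
    exclude_indels: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Polygenic score: weighted sum of risk-allele dosages.

    SNPs are dropped when their MAF falls below ``maf_threshold``, when
    the risk/other pair is strand-ambiguous (A/T or G/C), or when either
    allele is longer than one base (insertion/deletion).  Returns
    (scores, retained_snp_indices).
    """
    dosages = np.asarray(dosages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != len(weights):
        raise ValueError(
            f"weight/SNP mismatch: {dosages.shape[1]} dosage columns vs "
            f"{len(weights)} weights"
        )
    keep = np.ones(len(weights), dtype=bool)
    if maf is not None:
        keep &= np.asarray(maf, dtype=float) >= maf_threshold
    if risk_alleles is not None and other_alleles is not None:
        ra = np.asarray(risk_alleles, dtype=object)
        oa = np.asarray(other_alleles, dtype=object)
        if exclude_indels:
            keep &= np.array([len(str(a)) == 1 and len(str(b)) == 1 for a, b in zip(ra, oa)])
        if exclude_ambiguous:
            keep &= np.array(
                [(str(a).upper(), str(b).upper()) not in _AMBIGUOUS for a, b in zip(ra, oa)]
            )
    retained = np.flatnonzero(keep)
    if retained.size == 0:
        raise ValueError("no SNPs retained after filtering: empty panel")
    scores = dosages[:, retained] @ weights[retained]
    return scores, retained


# ---------------------------------------------------------------------------
# adolescent cohort
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_latent_chain(config: SimulationConfig, rng) -> dict:
    """Realize the linear-Gaussian chain for one cohort draw.

    With g, h, q, d the configured path coefficients and s_* the layer
    noise SDs, the chain is

        brain   = g * PRS + N(0, s_brain)
        physio  = h * std(brain) + N(0, s_physio)
        symptom = q * std(physio) + d * PRS + N(0, s_symptom)

    where std() divides by the population SD, so each path coefficient is
    the model-implied correlation between consecutive standardized
    latents when the preceding input is standardized.
    """
    n = config.n_adolescents
    p = config.path_coefficients
    s = config.noise_sd
    for name, value in p.items():
        if not math.isfinite(value):
            raise ValueError(f"path coefficient {name!r} is not finite")

    # each disorder gets its own independent SNP panel (disorder GWAS hits
    # are distinct loci), so the non-target polygenic scores are genuine
    # null exposures for the planted chain
    prs = {}
    panels = {}
    dosage_store = {}
    for j, disorder in enumerate(PRS_DISORDERS):
        dosages, panel = generate_genotypes(
            n,
            config.maf,
            seed=int(
                np.random.default_rng([config.seed, 7, j]).integers(2**31)
            ),
        )
        panel["weight"] = np.random.default_rng([config.seed, 11 + j]).normal(
            0.0, 0.1, dosages.shape[1]
        )
        raw, _ = score_prs(
            dosages,
            panel["weight"],
            risk_alleles=panel["risk_allele"],
            other_alleles=panel["other_allele"],
            maf=panel["maf"],
        )
        prs[disorder] = _standardize(raw)
        panels[disorder] = panel
        dosage_store[disorder] = dosages
    dosages = dosage_store["anxiety"]
    panel = panels["anxiety"]

    x = prs["anxiety"]  # exposure of the planted chain
    brain = p["prs_to_brain"] * x + rng.normal(0.0, s["brain"], n)
    sd_brain = math.hypot(p["prs_to_brain"], s["brain"])
    physio = p["brain_to_physio"] * brain / sd_brain + rng.normal(0.0, s["physio"], n)
    sd_physio = math.hypot(p["brain_to_physio"], s["physio"])
    symptom = (
        p["physio_to_symptom"] * physio / sd_physio
        + p["direct"] * x
        + rng.normal(0.0, s["symptom"], n)
    )
    brain_t2 = config.fc_stability * brain + rng.normal(
        0.0, s["brain"] * math.sqrt(max(1.0 - config.fc_stability**2, 1e-12)), n
    )
    return {
        "dosages": dosages,
        "panel": panel,
        "prs": prs,
        "brain_t1": brain,
        "brain_t1_std": brain / sd_brain,
        "brain_t2": brain_t2,
        "physio": physio,
        "physio_std": physio / sd_physio,
        "symptom": symptom,
        "sd_brain": sd_brain,
        "sd_physio": sd_physio,
    }


def implied_chain_correlation(config: SimulationConfig) -> float:
    """Closed-form model-implied corr(PRS, symptom-change latent)."""
    p = config.path_coefficients
    s = config.noise_sd
    g, h, q, d = (
        p["prs_to_brain"],
        p["brain_to_physio"],
        p["physio_to_symptom"],
        p["direct"],
    )
    sd_b = math.hypot(g, s["brain"])
    sd_p = math.hypot(h, s["physio"])
    corr_x_pstd = (h * g / sd_b) / sd_p
    cov_xs = q * corr_x_pstd + d
    var_s = q**2 + d**2 + s["symptom"] ** 2 + 2 * q * d * corr_x_pstd
    return cov_xs / math.sqrt(var_s)


def _pds_item(latent: np.ndarray, rng, noise: float = 0.6) -> np.ndarray:
    """Map a latent maturation score onto a 1..4 ordinal PDS item."""
    raw = 2.0 + latent + rng.normal(0.0, noise, latent.shape)
    return np.clip(np.round(raw), 1, 4)


def generate_adolescent_cohort(
    config: SimulationConfig, geometry: ParcelGeometry
) -> AdolescentCohort:
    """Adolescents with FC at two timepoints and the full phenotype table.

    The planted chain lives in ``ground_truth``; every phenotype column
    the downstream analyses consume (hormones + saliva covariates,
    PDS items, nine CBCL scales at T2/T3, eight blood-chemistry
    biomarkers, BMI, deprivation, medical-history counts, PRS values,
    confounds) is populated.
    """
    n = config.n_adolescents
    r = config.n_rois
    rng = np.random.default_rng([config.seed, 2])
    axis = _unit_axis(resolve_axis_ranks(config, geometry))
    pattern = _axis_product_pattern(axis)

    chain = generate_latent_chain(config, rng)
    sex = rng.permuted(np.where(np.arange(n) < n // 2, 1.0, -1.0))
    female = sex < 0

    # --- FC at both waves: sex offset plus individual masculinization,
    # both loaded multiplicatively along the axis so that regional
    # similarity profiles differentiate most in high-axis regions ---
    base = _base_fc_mean(np.random.default_rng([config.seed, 99]), r)
    masc1 = 0.5 * config.sex_effect_scale * sex + config.brain_load * chain["brain_t1_std"]
    masc2 = 0.5 * config.sex_effect_scale * sex + config.brain_load * _standardize(
        chain["brain_t2"]
    )
    fc_t1 = base[None] + masc1[:, None, None] * pattern[None]
    fc_t1 += _symmetric_noise(rng, n, r, config.noise_sd["fc"])
    fc_t2 = base[None] + masc2[:, None, None] * pattern[None]
    fc_t2 += _symmetric_noise(rng, n, r, config.noise_sd["fc"])
    fc_t1 = _mask_diagonal(fc_t1)
    fc_t2 = _mask_diagonal(fc_t2)

    # --- confounds ---
    age_months_t1 = rng.normal(119.0, 7.0, n)
    pheno = {
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "sex": sex,
        "age_months_t1": age_months_t1,
        "age_months_t2": age_months_t1 + 24.0,
        "site": rng.integers(0, 3, n),
        "race": rng.integers(0, 3, n),
        "handedness": (rng.random(n) < 0.1).astype(int),
        "adopted": (rng.random(n) < 0.02).astype(int),
        "ambiguous_sex": (rng.random(n) < 0.01).astype(int),
        "mean_fd_t1": rng.lognormal(-1.9, 0.4, n),
        "mean_fd_t2": rng.lognormal(-2.0, 0.4, n),
    }
    for disorder in PRS_DISORDERS:
        pheno[f"prs_{disorder}"] = chain["prs"][disorder]

    # --- pubertal maturation latent (advances with physiology and age) ---
    physio_std = chain["physio_std"]
    age_z = _standardize(age_months_t1)
    s_h = config.noise_sd["hormone"]
    for wave, moments in (("t1", HORMONE_MOMENTS_T1), ("t2", HORMONE_MOMENTS_T2)):
        chain_part = physio_std if wave == "t2" else config.fc_stability * physio_std
        loading = math.sqrt(max(1.0 - s_h**2, 0.04))
        latent = loading * (0.6 * chain_part + 0.4 * age_z) + s_h * rng.normal(0, 1, n)
        pheno[f"puberty_latent_{wave}"] = latent
        for hormone, by_sex in moments.items():
            vals = np.full(n, np.nan)
            for code, label in ((1.0, "M"), (-1.0, "F")):
                if label not in by_sex:
                    continue
                mu, sd = by_sex[label]
                mask = sex == code
                draw = mu + sd * (0.6 * latent[mask] + 0.8 * rng.normal(0, 1, mask.sum()))
                vals[mask] = np.clip(draw, 0.05 * mu, None)
            pheno[f"{hormone}_{wave}"] = vals

    # saliva covariates (small planted effects on hormones would be
    # swamped at these noise levels; they exist so residualization is
    # exercised on realistic columns)
    pheno["saliva_quality_ok"] = (rng.random(n) < 0.94).astype(int)
    pheno["activity_level"] = rng.integers(0, 4, n)
    pheno["caffeine_12h_mg"] = np.round(rng.exponential(15.0, n), 1)
    pheno["collection_delay_h"] = np.round(rng.uniform(0.5, 10.0, n), 2)
    # menarche fields, girls only
    menarche_age = np.full(n, np.nan)
    days_since = np.full(n, np.nan)
    regular = np.full(n, np.nan)
    menarche_age[female] = rng.normal(11.8, 1.0, female.sum())
    days_since[female] = rng.integers(0, 35, female.sum()).astype(float)
    regular[female] = (rng.random(female.sum()) < 0.5).astype(float)
    pheno["age_menarche"] = menarche_age
    pheno["days_since_cycle"] = days_since
    pheno["cycle_regular"] = regular

    # --- PDS self-report items (1..4), sex-specific item sets ---
    for wave in ("t1", "t2"):
        latent = pheno[f"puberty_latent_{wave}"]
        for item in ("skin", "body_hair", "growth_spurt"):
            pheno[f"pds_{item}_{wave}"] = _pds_item(latent, rng)
        breast = np.full(n, np.nan)
        menarche_item = np.full(n, np.nan)
        voice = np.full(n, np.nan)
        facial = np.full(n, np.nan)
        breast[female] = _pds_item(latent[female], rng)
        menarche_item[female] = _pds_item(latent[female], rng)
        voice[~female] = _pds_item(latent[~female], rng)
        facial[~female] = _pds_item(latent[~female], rng)
        pheno[f"pds_breast_{wave}"] = breast
        pheno[f"pds_menarche_{wave}"] = menarche_item
        pheno[f"pds_voice_{wave}"] = voice
        pheno[f"pds_facial_{wave}"] = facial

    # --- blood chemistry at T2: shifted along the aging direction ---
    s_bio = config.noise_sd["biomarker"]
    load_bio = math.sqrt(max(1.0 - s_bio**2, 0.04))
    for k, marker in enumerate(BIOMARKERS):
        mu, sd, sign = BIOMARKER_MOMENTS[marker]
        lo, hi = BIOMARKER_RANGES[marker]
        draw = mu + sd * (sign * load_bio * physio_std + s_bio * rng.normal(0, 1, n))
        pheno[marker] = np.clip(draw, lo, hi)

    # --- physical health correlates ---
    pheno["bmi"] = np.clip(19.0 + 3.5 * (0.35 * physio_std + rng.normal(0, 1, n)), 12, 45)
    pheno["financial_deprivation"] = np.clip(
        np.round(rng.exponential(0.9, n) + 0.35 * np.maximum(physio_std, 0)), 0, 7
    )
    pheno["medical_history_count"] = rng.poisson(
        np.exp(0.2 + 0.25 * physio_std)
    ).astype(float)

    # --- CBCL DSM scales at T2 and T3 ---
    g_factor = rng.normal(0.0, 1.0, n)
    symptom = _standardize(chain["symptom"])
    z2_store = {}
    for scale, (m2, s2, m3, s3) in CBCL_SCALES.items():
        z2 = 0.6 * g_factor + 0.8 * rng.normal(0, 1, n)
        z2_store[scale] = z2
        pheno[f"cbcl_{scale}_t2"] = np.clip(m2 + s2 * z2, 0.0, None)
    for scale, (m2, s2, m3, s3) in CBCL_SCALES.items():
        z2 = z2_store[scale]
        if scale in INTERNALIZING_SCALES:
            z3 = 0.6 * z2 + 0.6 * symptom + 0.53 * rng.normal(0, 1, n)
        else:
            z3 = 0.6 * z2 + 0.8 * rng.normal(0, 1, n)
        pheno[f"cbcl_{scale}_t3"] = np.clip(m3 + s3 * z3, 0.0, None)

    phenotypes = pd.DataFrame(pheno)
    ground_truth = {
        "axis_unit": axis,
        "masc_t1": masc1,
        "masc_t2": masc2,
        "brain_t1": chain["brain_t1"],
        "brain_t2": chain["brain_t2"],
        "physio": chain["physio"],
        "symptom": chain["symptom"],
        "prs": chain["prs"],
        "panel": chain["panel"],
        "dosages": chain["dosages"],
        "path_coefficients": dict(config.path_coefficients),
        "implied_prs_symptom_corr": implied_chain_correlation(config),
    }
    return AdolescentCohort(
        fc_t1=fc_t1, fc_t2=fc_t2, phenotypes=phenotypes, ground_truth=ground_truth
    )


# ---------------------------------------------------------------------------
# mortality cohort
# ---------------------------------------------------------------------------


def generate_mortality_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Young adults with Gompertz event times.

    Hazard h(t) = exp(lp) * exp(gamma * t) with
    lp = b0 + b_age*age + sum_k b_k*x_k; event times are drawn by inverse
    transform and administratively censored at the configured horizon.
    """
    gz = config.gompertz
    if gz.horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_mortality
    lo, hi = config.mortality_age_range
    age = rng.uniform(lo, hi, n)
    x = np.empty((n, len(BIOMARKERS)))
    for k, marker in enumerate(BIOMARKERS):
        mu, sd, _ = BIOMARKER_MOMENTS[marker]
        rlo, rhi = BIOMARKER_RANGES[marker]
        x[:, k] = np.clip(rng.normal(mu, sd, n), rlo, rhi)
    lp = gz.b0 + gz.b_age * age + x @ np.asarray(gz.b_biomarkers)
    u = rng.uniform(0.0, 1.0, n)
    t_event = np.log1p(-gz.gamma * np.log(u) / np.exp(lp)) / gz.gamma
    died = t_event <= gz.horizon_years
    follow_up = np.minimum(t_event, gz.horizon_years)
    cohort = pd.DataFrame(x, columns=list(BIOMARKERS))
    cohort.insert(0, "chronological_age", age)
    cohort["follow_up"] = follow_up
    cohort["died"] = died
    return cohort


def gompertz_death_probability(
    lp: float, gamma: float, horizon: float, n_grid: int = 20001
) -> float:
    """Death probability by numerical integration of the hazard (oracle-free path).

    1 - exp(-int_0^tau h(t) dt) evaluated with the trapezoid rule; exists
    so that generated event fractions can be checked against the hazard
    the generator claims to draw from.
    """
    t = np.linspace(0.0, horizon, n_grid)
    h = np.exp(lp) * np.exp(gamma * t)
    return 1.0 - math.exp(-np.trapezoid(h, t))


# ---------------------------------------------------------------------------
# run-wise time series with a target coupling structure (fc_mode=timeseries)
# ---------------------------------------------------------------------------


def timeseries_from_fc(
    fc_z: np.ndarray, n_frames: int, rng, jitter: float = 1e-6
) -> np.ndarray:
    """Draw a frames x R Gaussian series whose population correlation is tanh(fc_z).

    The implied correlation matrix is eigenvalue-clipped to the nearest
    positive-definite matrix before the Cholesky factorization.
    """
    corr = np.tanh(np.nan_to_num(fc_z, nan=0.0))
    np.fill_diagonal(corr, 1.0)
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, jitter, None)
    corr_pd = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(corr_pd))
    corr_pd = corr_pd / np.outer(d, d)
    chol = np.linalg.cholesky(corr_pd)
    return rng.standard_normal((n_frames, corr.shape[0])) @ chol.T


def write_cohort_tables(
    out_dir,
    geometry: ParcelGeometry,
    adolescents: AdolescentCohort,
    mortality: pd.DataFrame,
    reference: Optional[ReferenceCohort] = None,
    write_fc: bool = False,
) -> list:
    """Persist cohort tables as TSV (+ ground-truth JSON); returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    geometry.to_tsv(out / "geometry.tsv")
    paths.append(out / "geometry.tsv")
    adolescents.phenotypes.to_csv(out / "adolescent_phenotypes.tsv", sep="\t", index=False)
    paths.append(out / "adolescent_phenotypes.tsv")
    mortality.to_csv(out / "mortality.tsv", sep="\t", index=False)
    paths.append(out / "mortality.tsv")
    gt = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in adolescents.ground_truth.items()
        if k not in ("panel", "dosages", "prs")
    }
    gt["prs"] = {k: v.tolist() for k, v in adolescents.ground_truth["prs"].items()}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    paths.append(out / "ground_truth.json")
    if write_fc and reference is not None:
        fc_dir = out / "reference_fc"
        fc_dir.mkdir(exist_ok=True)
        ids = [str(p) for p in geometry.parcel_id]
        for i in range(reference.fc.shape[0]):
            pd.DataFrame(reference.fc[i], index=ids, columns=ids).to_csv(
                fc_dir / f"sub-{i:04d}.tsv", sep="\t"
            )
        paths.append(fc_dir)
    return [str(p) for p in paths]
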