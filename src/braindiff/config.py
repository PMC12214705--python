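"""Simulation configuration for synthetic adolescent/adult cohorts.

The defaults encode the study conditions the pipeline is designed for:
a reference adult cohort used to estimate the sexual-differentiation
template, a longitudinal adolescent cohort carrying the planted causal
chain PRS -> T1 brain differentiation -> T2 physiology -> rising
internalizing symptoms, and a young-adult mortality cohort for the
Gompertz biological-age model.  Hormone and symptom-scale moments follow
the published cohort summary tables; blood-chemistry moments are typical
adolescent reference values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

#: The eight blood-chemistry biomarkers feeding the biological-age model.
BIOMARKERS = (
    "mcv", "rbc", "rdw", "wbc",
    "lymphocyte_pct", "monocyte_pct", "hba1c", "cholesterol",
)

#: (mean, sd, aging_sign) per biomarker. The sign is the direction in which
#: the marker moves with greater physiological wear-and-tear.
BIOMARKER_MOMENTS = {
    "mcv": (85.0, 5.0, +1.0),
    "rbc": (4.8, 0.4, -1.0),
    "rdw": (13.0, 1.0, +1.0),
    "wbc": (6.5, 1.5, +1.0),
    "lymphocyte_pct": (35.0, 8.0, -1.0),
    "monocyte_pct": (8.0, 2.0, +1.0),
    "hba1c": (5.2, 0.3, +1.0),
    "cholesterol": (160.0, 25.0, +1.0),
}

#: Hard physiological ranges used to clip generated biomarkers.
BIOMARKER_RANGES = {
    "mcv": (60.0, 110.0),
    "rbc": (3.0, 7.0),
    "rdw": (10.0, 20.0),
    "wbc": (2.0, 20.0),
    "lymphocyte_pct": (5.0, 70.0),
    "monocyte_pct": (1.0, 20.0),
    "hba1c": (4.0, 9.0),
    "cholesterol": (80.0, 300.0),
}

#: Nine DSM-oriented CBCL scales with (mean_T2, sd_T2, mean_T3, sd_T3).
CBCL_SCALES = {
    "depression": (0.11, 0.16, 0.13, 0.18),
    "anxiety": (0.18, 0.23, 0.21, 0.27),
    "somatic": (0.14, 0.19, 0.14, 0.19),
    "adhd": (0.30, 0.38, 0.30, 0.37),
    "odd": (0.25, 0.35, 0.25, 0.32),
    "cd": (0.05, 0.11, 0.05, 0.12),
    "sct": (0.13, 0.23, 0.13, 0.23),
    "ocd": (0.15, 0.20, 0.18, 0.23),
    "ptsd": (0.17, 0.20, 0.20, 0.24),
}

#: Scales carrying the planted symptom-change signal (internalizing).
INTERNALIZING_SCALES = ("depression", "anxiety", "somatic")

#: Salivary hormone moments at the T2 wave, (mean, sd) by sex.
#: Estradiol is assayed in girls only.
HORMONE_MOMENTS_T2 = {
    "dhea": {"F": (115.53, 67.74), "M": (84.44, 69.32)},
    "testosterone": {"F": (51.71, 21.31), "M": (54.63, 33.51)},
    "estradiol": {"F": (1.15, 0.63)},
}
HORMONE_MOMENTS_T1 = {
    "dhea": {"F": (77.20, 43.14), "M": (61.08, 41.62)},
    "testosterone": {"F": (37.26, 16.06), "M": (36.97, 23.58)},
    "estradiol": {"F": (1.01, 0.45)},
}


@dataclass
class GompertzConfig:
    """Planted parameters of the exponential-growth mortality model.

    Hazard: h(t) = exp(b0 + b_age*age + sum_k b_k*x_k) * exp(gamma*t),
    administratively censored at ``horizon_years``.
    """

    b0: float = -35.99
    b_age: float = 0.25
    b_biomarkers: tuple = (0.10, -1.25, 0.50, 0.3333, -0.0625, 0.25, 1.6667, 0.02)
    gamma: float = 0.50
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("Gompertz shape gamma must be > 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if len(self.b_biomarkers) != len(BIOMARKERS):
            raise ValueError("need one coefficient per biomarker")


def _default_paths() -> dict:
    return {
        "prs_to_brain": 0.5,
        "brain_to_physio": 0.5,
        "physio_to_symptom": 0.5,
        "direct": 0.0,
    }


def _default_noise() -> dict:
    return {
        "fc": 0.25,        # edge-level FC noise (Fisher-z units)
        "brain": 0.87,     # residual sd of the brain latent
        "physio": 0.87,    # residual sd of the physiology latent
        "symptom": 0.87,   # residual sd of the symptom-change latent
        "biomarker": 0.8,  # fraction of biomarker variance not tied to physiology
        "hormone": 0.8,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-cohort generators.

    ``axis_ranks`` is the planted sensorimotor-association gradient; when
    left ``None`` it is derived from parcel geometry (rank of the z
    coordinate), giving a spatially smooth map suitable for spin nulls.
    Ranks are min-max normalized to [0, 1] before entering any effect so
    that effect sizes do not scale with the parcel count.
    """

    n_ref_adults: int = 400
    n_adolescents: int = 500
    n_rois: int = 100
    n_frames: int = 120
    n_runs: int = 3
    tr_seconds: float = 0.8
    axis_ranks: Optional[np.ndarray] = None
    sex_effect_scale: float = 1.0
    brain_load: float = 0.5     # how strongly the brain latent shifts FC along the axis
    fc_stability: float = 0.8   # T1 -> T2 carry-over of the individual brain latent
    path_coefficients: dict = field(default_factory=_default_paths)
    noise_sd: dict = field(default_factory=_default_noise)
    maf: tuple = (0.12, 0.31, 0.44, 0.08, 0.25, 0.37, 0.19, 0.46, 0.29, 0.11, 0.33, 0.22)
    gompertz: GompertzConfig = field(default_factory=GompertzConfig)
    n_mortality: int = 5000
    mortality_age_range: tuple = (20.0, 40.0)
    fc_mode: str = "matrix"  # "matrix" | "timeseries"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.gompertz, dict):
            self.gompertz = GompertzConfig(**self.gompertz)
        if self.n_rois < 8:
            raise ValueError("n_rois must be >= 8")
        if self.n_rois % 2 != 0:
            raise ValueError("n_rois must be even (half per hemisphere)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd[{name!r}] must be > 0")
        for name, value in self.path_coefficients.items():
            if not math.isfinite(value):
                raise ValueError(f"path coefficient {name!r} is not finite")
        for f in self.maf:
            if not (0.05 < f < 0.5):
                raise ValueError("per-SNP MAF must lie in (0.05, 0.5)")
        if self.fc_mode not in ("matrix", "timeseries"):
            raise ValueError("fc_mode must be 'matrix' or 'timeseries'")
        if self.axis_ranks is not None:
            self.axis_ranks = np.asarray(self.axis_ranks, dtype=float)
            if self.axis_ranks.shape != (self.n_rois,):
                raise ValueError("axis_ranks must have length n_rois")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["axis_ranks"] is not None:
            out["axis_ranks"] = list(map(float, out["axis_ranks"]))
        return out
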