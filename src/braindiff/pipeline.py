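"""End-to-end orchestration of the five analyses on synthetic cohorts.

Stage order mirrors the analytic workflow: simulate -> template ->
biological-age validation -> Analysis 1 (physiology/psychopathology CCA)
-> Analysis 2 (brain PLS + axis alignment) -> Analysis 3 (serial
mediation) -> Analysis 4 (projection replication) -> Analysis 5
(parcel-level CCA over the 13 phenotype maps with spin inference).
Each stage persists machine-readable outputs and the run ends with a
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import cca, mediation, phenoage, phenotypes, pls, sexdiff, spin
from .config import CBCL_SCALES, BIOMARKERS, SimulationConfig
from .simulate import (
    generate_adolescent_cohort,
    generate_mortality_cohort,
    generate_parcel_geometry,
    generate_reference_cohort,
    resolve_axis_ranks,
    write_cohort_tables,
)

logger = logging.getLogger("braindiff.pipeline")

ALL_STAGES = (
    "simulate",
    "phenoage_validation",
    "analysis1",
    "analysis2",
    "analysis3",
    "analysis4",
    "analysis5",
)

CONFOUND_COLUMNS = (
    "age_months_t2",
    "handedness",
    "site",
    "race",
    "adopted",
    "ambiguous_sex",
    "mean_fd_t1",
    "mean_fd_t2",
)


@dataclass
class PipelineConfig:
    """Run-level settings; resampling defaults are desk-scale."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    k: int = 10
    n_perm: int = 1000
    n_boot: int = 2000
    n_spins: int = 1000
    bsr_threshold: float = 2.75
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class RunManifest:
    """What a pipeline run produced, written atomically at the end."""

    seed: int
    config_hash: str
    stage_seconds: dict
    outputs: dict
    results: dict


def _confounds(pheno: pd.DataFrame) -> pd.DataFrame:
    conf = pheno[list(CONFOUND_COLUMNS)].copy()
    conf["site"] = conf["site"].astype("category")
    conf["race"] = conf["race"].astype("category")
    return conf


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order; returns the manifest.

    A stage failure aborts the run with the stage name, after persisting
    the partial manifest.
    """
    logging.basicConfig(level=config.log_level, format="%(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.simulation.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    stage_seconds: dict = {}
    outputs: dict = {}
    results: dict = {}
    state: dict = {}

    def _persist_manifest() -> RunManifest:
        manifest = RunManifest(
            seed=config.seed,
            config_hash=cfg_hash,
            stage_seconds=stage_seconds,
            outputs=outputs,
            results=results,
        )
        tmp = out / "manifest.json.tmp"
        with open(tmp, "w") as fh:
            json.dump(manifest.__dict__, fh, indent=1, default=_json_default)
        tmp.replace(out / "manifest.json")
        return manifest

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = _time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            _STAGES[stage](config, state, out, outputs, results)
        except Exception:
            _persist_manifest()
            logger.error("stage %s failed", stage)
            raise
        stage_seconds[stage] = round(_time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.1fs", stage, stage_seconds[stage])
    manifest = _persist_manifest()
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config, state, out, outputs, results):
    sim = config.simulation
    geometry = generate_parcel_geometry(sim.n_rois, seed=sim.seed)
    reference = generate_reference_cohort(sim, geometry)
    adolescents = generate_adolescent_cohort(sim, geometry)
    mortality = generate_mortality_cohort(sim)
    state.update(
        geometry=geometry,
        reference=reference,
        adolescents=adolescents,
        mortality=mortality,
        axis=resolve_axis_ranks(sim, geometry),
    )
    outputs["simulate"] = write_cohort_tables(out, geometry, adolescents, mortality)

    template = sexdiff.fit_template(reference)
    profiles_t1 = sexdiff.score_cohort(adolescents.fc_t1, template)
    profiles_t2 = sexdiff.score_cohort(adolescents.fc_t2, template)
    # remove residual motion from the neural indices, per the control policy
    pheno = adolescents.phenotypes
    fd = pheno[["mean_fd_t1", "mean_fd_t2"]]
    profiles_t1 = phenotypes.residualize(profiles_t1, fd)
    profiles_t2 = phenotypes.residualize(profiles_t2, fd)
    state.update(template=template, profiles_t1=profiles_t1, profiles_t2=profiles_t2)
    np.savetxt(out / "template_t.tsv", template.t, delimiter="\t")
    outputs["simulate"].append(str(out / "template_t.tsv"))


def _stage_phenoage_validation(config, state, out, outputs, results):
    sim = config.simulation
    model = phenoage.fit_mortality_model(
        state["mortality"], horizon=sim.gompertz.horizon_years
    )
    pheno = state["adolescents"].phenotypes
    pa = phenoage.predict_phenoage(
        model,
        pheno["age_months_t2"].to_numpy() / 12.0,
        pheno[list(BIOMARKERS)].to_numpy(),
    )
    state["model_gompertz"] = model
    state["phenoage"] = pa
    train_pa = phenoage.predict_phenoage(
        model,
        state["mortality"]["chronological_age"].to_numpy(),
        state["mortality"][list(BIOMARKERS)].to_numpy(),
    )
    health = pheno[["bmi", "financial_deprivation", "medical_history_count"]]
    conf = pheno[["sex", "age_months_t2"]]
    cv = cca.cross_validate_cca(
        pd.DataFrame({"phenoage": pa}), health, confounds=conf,
        k=config.k, seed=config.seed,
    )
    r_cv, p = cca.permutation_pvalue(
        pd.DataFrame({"phenoage": pa}), health, confounds=conf,
        k=config.k, seed=config.seed, n_perm=config.n_perm, observed=cv,
    )
    results["phenoage_validation"] = {
        "r_cv": r_cv,
        "p": p,
        "train_mean_phenoage_minus_age": float(
            np.mean(train_pa) - state["mortality"]["chronological_age"].mean()
        ),
        "gamma": model.gamma,
    }
    with open(out / "phenoage_validation.json", "w") as fh:
        json.dump(results["phenoage_validation"], fh, indent=1, default=_json_default)
    outputs["phenoage_validation"] = [str(out / "phenoage_validation.json")]


def _build_analysis1_sets(config, state):
    pheno = state["adolescents"].phenotypes
    hormonal = phenotypes.hormonal_indices(
        pheno.rename(
            columns={"dhea_t2": "dhea", "testosterone_t2": "testosterone", "estradiol_t2": "estradiol"}
        ),
        pheno["sex"].to_numpy(),
    )
    pds_cols = {
        f"pds_{item}_t2": item
        for item in ("skin", "body_hair", "growth_spurt", "breast", "menarche", "voice", "facial")
    }
    selfrep = phenotypes.selfreport_indices(
        pheno[list(pds_cols)].rename(columns=pds_cols), pheno["sex"].to_numpy()
    )
    t2 = pheno[[f"cbcl_{s}_t2" for s in CBCL_SCALES]].rename(
        columns=lambda c: c.replace("cbcl_", "").replace("_t2", "")
    )
    t3 = pheno[[f"cbcl_{s}_t3" for s in CBCL_SCALES]].rename(
        columns=lambda c: c.replace("cbcl_", "").replace("_t3", "")
    )
    deltas = phenotypes.change_scores(t2, t3)
    psych = pd.concat(
        [t2.add_prefix("t2_"), deltas], axis=1
    )
    physio = pd.DataFrame(
        {
            "sex": pheno["sex"],
            "phenoage": state["phenoage"],
            "hormonal_adrenarche": hormonal["hormonal_adrenarche"],
            "hormonal_gonadarche": hormonal["hormonal_gonadarche"],
            "selfreport_adrenarche": selfrep["selfreport_adrenarche"],
            "selfreport_gonadarche": selfrep["selfreport_gonadarche"],
        }
    )
    return psych, physio


def _stage_analysis1(config, state, out, outputs, results):
    psych, physio = _build_analysis1_sets(config, state)
    state["psych_set"] = psych
    state["physio_set"] = physio
    conf = _confounds(state["adolescents"].phenotypes)
    cv = cca.cross_validate_cca(psych, physio, confounds=conf, k=config.k, seed=config.seed)
    r_cv, p = cca.permutation_pvalue(
        psych, physio, confounds=conf, k=config.k, seed=config.seed,
        n_perm=config.n_perm, observed=cv,
    )
    loadings = cca.bootstrap_loadings(
        cv, psych, side="x", confounds=conf, n_boot=config.n_boot, seed=config.seed
    )
    contrib = cca.standardized_contributions(
        cv.y_scores[:, 0],
        physio[["sex", "phenoage", "hormonal_gonadarche", "selfreport_gonadarche"]],
        controls=conf,
    )
    state["cca1"] = cv
    results["analysis1"] = {"r_cv": r_cv, "p": p}
    loadings.to_csv(out / "analysis1_loadings.tsv", sep="\t", index=False)
    contrib.to_csv(out / "analysis1_contributions.tsv", sep="\t", index=False)
    outputs["analysis1"] = [
        str(out / "analysis1_loadings.tsv"),
        str(out / "analysis1_contributions.tsv"),
    ]


def _stage_analysis2(config, state, out, outputs, results):
    cv1 = state["cca1"]
    behavior = pd.DataFrame(
        {
            "psychopathology_variate": cv1.x_scores[:, 0],
            "physiology_variate": cv1.y_scores[:, 0],
        }
    )
    brain = np.hstack([state["profiles_t1"], state["profiles_t2"]])
    conf = _confounds(state["adolescents"].phenotypes)
    model, p_disc = pls.permutation_significance(
        brain, behavior.to_numpy(), n_conditions=2,
        n_perm=config.n_perm, seed=config.seed,
    )
    boot = pls.bootstrap_ratios(
        model, brain, behavior.to_numpy(), n_boot=config.n_boot,
        threshold=config.bsr_threshold, seed=config.seed,
    )
    cv = pls.cross_validate_pls(
        brain, behavior.to_numpy(), confounds=conf, n_conditions=2,
        k=config.k, n_perm=config.n_perm, n_boot=config.n_boot, seed=config.seed,
    )
    spins = spin.generate_spins(state["geometry"], config.n_spins, seed=config.seed)
    state["spins"] = spins
    loading_map = cv.cv_loadings.mean(axis=0)
    align = sexdiff.align_to_axis(loading_map, state["axis"], spins)
    state["pls_cv"] = cv
    state["pls_loading_map"] = loading_map
    results["analysis2"] = {
        "p_discovery": float(p_disc[0]),
        "shared_variance_discovery": float(model.covariance_explained[0]),
        "p_cv": cv.permutation_p,
        "shared_variance_cv": cv.shared_variance,
        "condition_corr": cv.condition_corr.tolist(),
        "n_reliable_parcels": int(boot.reliable.sum()),
        "axis_rho": align["stat_obs"],
        "axis_p_spin": align["p"],
    }
    pd.DataFrame(
        {
            "parcel_id": state["geometry"].parcel_id,
            "weight": model.brain_saliences[:, 0],
            "bsr": boot.bsr,
            "cv_loading": loading_map,
        }
    ).to_csv(out / "analysis2_parcels.tsv", sep="\t", index=False)
    outputs["analysis2"] = [str(out / "analysis2_parcels.tsv")]


def _mediation_frame(state, prs_column: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    pheno = state["adolescents"].phenotypes
    cv1 = state["cca1"]
    pls_cv = state["pls_cv"]
    data = pd.DataFrame(
        {
            "X": pheno[prs_column].to_numpy(),
            "M1": pls_cv.brain_scores[:, 0],
            "M2": cv1.y_scores[:, 0],
            "M3": pls_cv.brain_scores[:, 1],
            "Y": cv1.x_scores[:, 0],
        }
    )
    conf = _confounds(pheno).copy()
    # pre-adjustment: T1 pubertal hormone levels and self-reported indices
    t1_cols = pheno[["dhea_t1", "testosterone_t1"]].copy()
    t1_cols["selfreport_adren_t1"] = pheno[["pds_skin_t1", "pds_body_hair_t1"]].mean(axis=1)
    adjust = pd.concat([conf, t1_cols], axis=1)
    adjusted = pd.DataFrame(
        phenotypes.residualize(data.to_numpy(), adjust), columns=data.columns
    )
    return adjusted, conf


def _stage_analysis3(config, state, out, outputs, results):
    payload = {}
    for arm, prs_col in (("anxiety", "prs_anxiety"), ("adhd", "prs_adhd")):
        data, _ = _mediation_frame(state, prs_col)
        model = mediation.fit_path_model(data)
        effects = mediation.indirect_effects(model)
        cis = mediation.bootstrap_cis(
            data, n_boot=config.n_boot, seed=config.seed
        )
        serial = cis[cis["effect"] == "x_m1_m2_y"].iloc[0]
        payload[arm] = {
            "serial_indirect": float(serial["estimate"]),
            "ci_low": float(serial["ci_low"]),
            "ci_high": float(serial["ci_high"]),
            "robust": bool(serial["robust"]),
            "decomposition_gap": effects.decomposition_gap(),
        }
        cis.to_csv(out / f"analysis3_{arm}.tsv", sep="\t", index=False)
    results["analysis3"] = payload
    outputs["analysis3"] = [
        str(out / "analysis3_anxiety.tsv"),
        str(out / "analysis3_adhd.tsv"),
    ]


def _stage_analysis4(config, state, out, outputs, results):
    """Split-sample projection: fit on a discovery half, project weights
    onto the held-out half and correlate the projected variates there."""
    psych, physio = state["psych_set"], state["physio_set"]
    n = len(psych)
    rng = np.random.default_rng(config.seed + 4)
    order = rng.permutation(n)
    disc, repl = order[: n // 2], order[n // 2 :]
    model = cca.fit_cca(psych.iloc[disc], physio.iloc[disc])
    x_proj = cca.project_variate(model, psych.iloc[repl], side="x")[:, 0]
    y_proj = cca.project_variate(model, physio.iloc[repl], side="y")[:, 0]
    r = cca._pearson(x_proj, y_proj)
    results["analysis4"] = {"projection_r": float(r), "n_replication": int(len(repl))}
    with open(out / "analysis4.json", "w") as fh:
        json.dump(results["analysis4"], fh, indent=1)
    outputs["analysis4"] = [str(out / "analysis4.json")]


def _stage_analysis5(config, state, out, outputs, results):
    pheno = state["adolescents"].phenotypes
    psych, physio = state["psych_set"], state["physio_set"]
    measures = pd.concat(
        [
            psych[[c for c in psych.columns if c.startswith("t2_")]],
            pheno[["bmi", "financial_deprivation"]],
            physio[["selfreport_adrenarche", "selfreport_gonadarche"]],
        ],
        axis=1,
    )
    conf = _confounds(pheno)[["age_months_t2", "handedness", "race", "site", "mean_fd_t2"]].copy()
    conf["sex"] = pheno["sex"]
    maps = sexdiff.map_partial_correlations(state["profiles_t2"], measures, conf)
    # overlap of the 13 differentiation maps with the brain LV map from
    # the PLS stage, across parcels, with spatially constrained nulls
    lv_map = pd.DataFrame({"brain_lv": state["pls_loading_map"]})
    r_parcels = maps.shape[0]
    cv = cca.cross_validate_cca(
        maps, lv_map, k=min(config.k, r_parcels // 3), seed=config.seed,
    )
    spins = state["spins"]
    r_cv, p_spin = cca.permutation_pvalue(
        maps, lv_map, k=min(config.k, r_parcels // 3), seed=config.seed,
        n_perm=min(config.n_perm, spins.n_perm), spins=spins.perms, observed=cv,
    )
    results["analysis5"] = {
        "n_maps": int(maps.shape[1]),
        "r_cv": r_cv,
        "p_spin": p_spin,
    }
    maps.insert(0, "parcel_id", state["geometry"].parcel_id)
    maps.to_csv(out / "analysis5_maps.tsv", sep="\t", index=False)
    outputs["analysis5"] = [str(out / "analysis5_maps.tsv")]


_STAGES = {
    "simulate": _stage_simulate,
    "phenoage_validation": _stage_phenoage_validation,
    "analysis1": _stage_analysis1,
    "analysis2": _stage_analysis2,
    "analysis3": _stage_analysis3,
    "analysis4": _stage_analysis4,
    "analysis5": _stage_analysis5,
}
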