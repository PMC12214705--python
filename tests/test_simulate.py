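"""Synthetic-cohort generators: contracts, planted moments, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import braindiff as bd
from braindiff.simulate import (
    _unit_axis,
    generate_genotypes,
    generate_latent_chain,
    gompertz_death_probability,
    timeseries_from_fc,
)


class TestParcelGeometry:
    def test_dimension_contract(self):
        geo = bd.generate_parcel_geometry(8, seed=1)
        assert (geo.hemisphere == "L").sum() == 4
        assert (geo.hemisphere == "R").sum() == 4
        assert np.allclose(np.linalg.norm(geo.centroid, axis=1), 1.0, atol=1e-9)
        assert len(set(geo.parcel_id)) == 8

    def test_determinism(self):
        a = bd.generate_parcel_geometry(8, seed=1)
        b = bd.generate_parcel_geometry(8, seed=1)
        assert np.array_equal(a.centroid, b.centroid)
        assert np.array_equal(a.hemisphere, b.hemisphere)

    def test_no_duplicate_centroids(self):
        geo = bd.generate_parcel_geometry(100, seed=7)
        # brute-force pairwise angular distances
        cos = np.clip(geo.centroid @ geo.centroid.T, -1, 1)
        ang = np.arccos(cos)
        np.fill_diagonal(ang, np.inf)
        assert ang.min() > 0

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            bd.generate_parcel_geometry(9, seed=0)

    def test_hemispheres_separated(self):
        geo = bd.generate_parcel_geometry(30, seed=3)
        assert (geo.centroid[geo.hemisphere == "L", 0] < 0).all()
        assert (geo.centroid[geo.hemisphere == "R", 0] > 0).all()

    def test_tsv_round_trip(self, tmp_path, small_geometry):
        path = tmp_path / "geometry.tsv"
        small_geometry.to_tsv(path)
        back = bd.ParcelGeometry.from_tsv(path)
        assert np.allclose(back.centroid, small_geometry.centroid)


class TestReferenceCohort:
    def test_null_sex_effect_edge_rejection_rate(self, small_geometry):
        """Without a planted effect, edge-wise sex t-tests reject ~5%."""
        cfg = bd.SimulationConfig(
            n_rois=20, n_ref_adults=200, sex_effect_scale=0.0, seed=3
        )
        cohort = bd.generate_reference_cohort(cfg, small_geometry)
        iu = np.triu_indices(20, k=1)
        edges = cohort.fc[:, iu[0], iu[1]]
        male, female = cohort.sex > 0, cohort.sex < 0
        t, p = stats.ttest_ind(edges[male], edges[female], axis=0)
        rate = (p < 0.05).mean()
        # 190 edges, binomial CI around 0.05
        assert 0.01 < rate < 0.10

    def test_planted_sex_difference_sign_and_size(self):
        """Male-minus-female mean on the top-axis edge matches the
        configured scale within Monte-Carlo error."""
        geo = bd.generate_parcel_geometry(20, seed=5)
        cfg = bd.SimulationConfig(
            n_rois=20, n_ref_adults=400, sex_effect_scale=1.0, seed=5
        )
        cohort = bd.generate_reference_cohort(cfg, geo)
        axis = _unit_axis(bd.resolve_axis_ranks(cfg, geo))
        i, j = np.argsort(axis)[-2:]
        diff = (
            cohort.fc[cohort.sex > 0, i, j].mean()
            - cohort.fc[cohort.sex < 0, i, j].mean()
        )
        expected = cfg.sex_effect_scale * (axis[i] + axis[j])
        assert diff > 0
        assert abs(diff - expected) < 4 * cfg.noise_sd["fc"] / math.sqrt(100)

    def test_determinism(self, small_config, small_geometry):
        a = bd.generate_reference_cohort(small_config, small_geometry)
        b = bd.generate_reference_cohort(small_config, small_geometry)
        assert np.array_equal(a.fc, b.fc, equal_nan=True)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_too_small_cohort_rejected(self, small_geometry):
        cfg = bd.SimulationConfig(n_rois=20, n_ref_adults=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            bd.generate_reference_cohort(cfg, small_geometry)

    def test_fc_symmetric_diagonal_masked(self, reference_cohort):
        fc = reference_cohort.fc
        assert np.isnan(fc[:, np.arange(20), np.arange(20)]).all()
        assert np.allclose(
            np.nan_to_num(fc), np.nan_to_num(np.transpose(fc, (0, 2, 1)))
        )


class TestAdolescentCohort:
    def test_null_chain_prs_uncorrelated_with_change(self, small_geometry):
        cfg = bd.SimulationConfig(
            n_rois=20,
            n_adolescents=400,
            path_coefficients={
                "prs_to_brain": 0.0,
                "brain_to_physio": 0.0,
                "physio_to_symptom": 0.0,
                "direct": 0.0,
            },
            seed=21,
        )
        cohort = bd.generate_adolescent_cohort(cfg, small_geometry)
        prs = cohort.phenotypes["prs_anxiety"].to_numpy()
        symptom = cohort.ground_truth["symptom"]
        r = np.corrcoef(prs, symptom)[0, 1]
        assert abs(r) < 3 / math.sqrt(len(prs))

    def test_path_algebra_closed_form(self, small_geometry):
        """Sample corr(PRS, symptom latent) matches the product formula of
        the standardized linear-Gaussian chain."""
        paths = {
            "prs_to_brain": 0.5,
            "brain_to_physio": 0.5,
            "physio_to_symptom": 0.5,
            "direct": 0.0,
        }
        cfg = bd.SimulationConfig(
            n_rois=20, n_adolescents=2000, path_coefficients=paths, seed=9
        )
        cohort = bd.generate_adolescent_cohort(cfg, small_geometry)
        prs = cohort.phenotypes["prs_anxiety"].to_numpy()
        symptom = cohort.ground_truth["symptom"]
        # independent hand computation of the implied correlation
        g = h = q = 0.5
        s_b = cfg.noise_sd["brain"]
        s_p = cfg.noise_sd["physio"]
        s_s = cfg.noise_sd["symptom"]
        corr_x_p = (h * g / math.hypot(g, s_b)) / math.hypot(h, s_p)
        implied = q * corr_x_p / math.sqrt(q**2 + s_s**2)
        observed = np.corrcoef(prs, symptom)[0, 1]
        assert implied == pytest.approx(
            bd.implied_chain_correlation(cfg), abs=1e-12
        )
        assert observed == pytest.approx(implied, abs=3 / math.sqrt(2000) + 0.02)

    def test_determinism(self, small_config, small_geometry):
        a = bd.generate_adolescent_cohort(small_config, small_geometry)
        b = bd.generate_adolescent_cohort(small_config, small_geometry)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.fc_t1, b.fc_t1, equal_nan=True)

    def test_non_finite_path_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="not finite"):
            bd.SimulationConfig(
                n_rois=20,
                path_coefficients={
                    "prs_to_brain": float("nan"),
                    "brain_to_physio": 0.5,
                    "physio_to_symptom": 0.5,
                    "direct": 0.0,
                },
            )

    def test_phenotype_table_contracts(self, adolescent_cohort):
        pheno = adolescent_cohort.phenotypes
        girls = pheno["sex"] < 0
        boys = pheno["sex"] > 0
        # estradiol assayed only in girls
        assert pheno.loc[girls, "estradiol_t2"].notna().all()
        assert pheno.loc[boys, "estradiol_t2"].isna().all()
        # CBCL scales are non-negative at both waves
        cbcl = [c for c in pheno.columns if c.startswith("cbcl_")]
        assert len(cbcl) == 18
        assert (pheno[cbcl] >= 0).all().all()
        # biomarkers stay inside physiological ranges
        for marker, (lo, hi) in bd.config.BIOMARKER_RANGES.items():
            assert pheno[marker].between(lo, hi).all()

    def test_confound_categories_have_levels(self, adolescent_cohort):
        pheno = adolescent_cohort.phenotypes
        assert pheno["site"].nunique() >= 2
        assert pheno["race"].nunique() >= 2


class TestMortalityCohort:
    def test_death_fraction_monotone_in_age(self, small_geometry):
        """With b_age > 0 and no biomarker effects, the death fraction
        rises across age quintiles."""
        gz = dict(
            b0=-7.0, b_age=0.15, b_biomarkers=(0.0,) * 8, gamma=0.1,
            horizon_years=10.0,
        )
        cfg = bd.SimulationConfig(n_rois=20, n_mortality=20000, gompertz=gz, seed=2)
        cohort = bd.generate_mortality_cohort(cfg)
        q = pd.qcut(cohort["chronological_age"], 5, labels=False)
        frac = cohort.groupby(q)["died"].mean().to_numpy()
        assert (np.diff(frac) > 0).all()

    def test_death_fraction_matches_quadrature(self):
        """Empirical death fractions on a 2-age grid match 1-exp(-int h)."""
        gz = dict(
            b0=-4.0, b_age=0.08, b_biomarkers=(0.0,) * 8, gamma=0.2,
            horizon_years=8.0,
        )
        cfg = bd.SimulationConfig(
            n_rois=20, n_mortality=40000, gompertz=gz,
            mortality_age_range=(25.0, 35.0), seed=4,
        )
        cohort = bd.generate_mortality_cohort(cfg)
        for lo, hi in ((25, 30), (30, 35)):
            band = cohort[
                cohort["chronological_age"].between(lo, hi, inclusive="left")
            ]
            mean_lp = -4.0 + 0.08 * band["chronological_age"].mean()
            expected = gompertz_death_probability(mean_lp, 0.2, 8.0)
            # Jensen gap is second order over a 5-year band
            assert band["died"].mean() == pytest.approx(expected, abs=0.02)

    def test_gamma_to_zero_matches_exponential(self):
        """For vanishing shape the survival law collapses to exponential."""
        gz = dict(
            b0=-2.0, b_age=0.0, b_biomarkers=(0.0,) * 8, gamma=1e-8,
            horizon_years=5.0,
        )
        cfg = bd.SimulationConfig(n_rois=20, n_mortality=50000, gompertz=gz, seed=6)
        cohort = bd.generate_mortality_cohort(cfg)
        expected = 1.0 - math.exp(-math.exp(-2.0) * 5.0)
        assert cohort["died"].mean() == pytest.approx(expected, abs=0.01)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            bd.GompertzConfig(horizon_years=-1.0)

    def test_follow_up_positive(self, small_config):
        cohort = bd.generate_mortality_cohort(small_config)
        assert (cohort["follow_up"] > 0).all()
        assert cohort["chronological_age"].between(20, 40).all()


class TestPrsScoring:
    def test_all_zero_dosages_score_zero(self):
        scores, kept = bd.score_prs(np.zeros((4, 3)), [0.1, -0.2, 0.5])
        assert np.array_equal(scores, np.zeros(4))
        assert len(kept) == 3

    def test_hand_computed_score(self):
        scores, _ = bd.score_prs(np.array([[2.0, 1.0, 0.0]]), [0.1, -0.2, 0.5])
        assert scores[0] == pytest.approx(0.1 * 2 - 0.2 * 1 + 0.5 * 0, abs=1e-12)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_weight_scaling_linearity(self, factor):
        dosages = np.array([[2.0, 1.0, 0.0], [0.0, 2.0, 1.0]])
        weights = np.array([0.1, -0.2, 0.5])
        base, _ = bd.score_prs(dosages, weights)
        scaled, _ = bd.score_prs(dosages, weights * factor)
        assert np.allclose(scaled, base * factor, atol=1e-9)

    def test_maf_and_allele_filters(self):
        dosages = np.ones((2, 4))
        weights = [1.0, 1.0, 1.0, 1.0]
        scores, kept = bd.score_prs(
            dosages,
            weights,
            risk_alleles=["A", "A", "AT", "G"],
            other_alleles=["G", "T", "A", "C"],
            maf=[0.2, 0.3, 0.3, 0.04],
        )
        # SNP 1 is ambiguous (A/T), SNP 2 an indel, SNP 3 below MAF
        assert list(kept) == [0]
        assert scores[0] == pytest.approx(1.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty panel"):
            bd.score_prs(np.ones((2, 1)), [1.0], maf=[0.01])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bd.score_prs(np.ones((2, 3)), [1.0, 2.0])

    def test_generated_dosages_integral_and_common(self):
        dosages, panel = generate_genotypes(500, [0.1, 0.3, 0.45], seed=8)
        assert np.array_equal(dosages, np.round(dosages))
        maf_hat = dosages.mean(axis=0) / 2.0
        assert np.allclose(maf_hat, [0.1, 0.3, 0.45], atol=0.06)


class TestTimeseriesMode:
    def test_timeseries_reproduce_target_correlation(self, rng):
        z = np.arctanh(np.array([[np.nan, 0.5, 0.1],
                                 [0.5, np.nan, -0.3],
                                 [0.1, -0.3, np.nan]]))
        ts = timeseries_from_fc(z, 40000, rng)
        got = np.corrcoef(ts, rowvar=False)
        assert got[0, 1] == pytest.approx(0.5, abs=0.02)
        assert got[1, 2] == pytest.approx(-0.3, abs=0.02)
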