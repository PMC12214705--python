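"""Canonical correlation: oracle equivalence, cross-validation, inference."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import braindiff as bd
from braindiff.cca import _pearson


def _eigen_oracle(x, y):
    """Largest canonical correlation via the generalized eigenproblem."""
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    ys = (y - y.mean(0)) / y.std(0, ddof=1)
    n = len(xs)
    sxx = xs.T @ xs / (n - 1)
    syy = ys.T @ ys / (n - 1)
    sxy = xs.T @ ys / (n - 1)
    m = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    vals = np.sort(np.linalg.eigvals(m).real)[::-1]
    return np.sqrt(np.clip(vals, 0, 1))


class TestFitCca:
    def test_identical_single_columns(self, rng):
        x = rng.normal(size=(50, 1))
        model = bd.fit_cca(x, x.copy())
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_large_sample_near_zero(self, rng):
        x = rng.normal(size=(10000, 1))
        y = rng.normal(size=(10000, 1))
        model = bd.fit_cca(x, y)
        assert model.correlations[0] < 0.05

    def test_matches_eigen_oracle_on_2x2(self, rng):
        x = rng.normal(size=(80, 2))
        y = 0.4 * x + rng.normal(size=(80, 2))
        model = bd.fit_cca(x, y)
        oracle = _eigen_oracle(x, y)
        assert np.allclose(model.correlations, oracle[:2], atol=1e-8)

    def test_matches_sklearn_on_small_instance(self, rng):
        """Independent cross-check against the NIPALS implementation."""
        from sklearn.cross_decomposition import CCA as SkCCA

        x = rng.normal(size=(120, 3))
        y = 0.5 * x[:, :2] + rng.normal(size=(120, 2))
        model = bd.fit_cca(x, y)
        sk = SkCCA(n_components=1, max_iter=2000).fit(x, y)
        xs, ys = sk.transform(x, y)
        r_sk = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert model.correlations[0] == pytest.approx(r_sk, abs=1e-6)

    def test_constant_column_rejected_by_name(self, rng):
        x = pd.DataFrame({"good": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.raises(ValueError, match="flat"):
            bd.fit_cca(x, pd.DataFrame({"y": rng.normal(size=30)}))

    def test_small_n_warns_and_regularizes(self, rng):
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=(10, 6))
        with pytest.warns(UserWarning, match="regularized"):
            model = bd.fit_cca(x, y)
        assert np.all(model.correlations <= 1.0)

    def test_within_set_variates_uncorrelated(self, rng):
        x = rng.normal(size=(200, 4))
        y = rng.normal(size=(200, 3)) + 0.3 * x[:, :3]
        model = bd.fit_cca(x, y)
        scores = bd.project_variate(model, x)
        c = np.corrcoef(scores, rowvar=False)
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-8


class TestCrossValidation:
    def test_planted_latent_recovered(self, rng):
        n = 500
        latent = rng.normal(size=n)
        x = np.column_stack([latent + rng.normal(size=n) * 1.2 for _ in range(3)])
        y = np.column_stack([latent + rng.normal(size=n) * 1.2 for _ in range(3)])
        res = bd.cross_validate_cca(x, y, k=10, seed=0)
        assert 0.35 < res.r_cv < 0.85

    def test_null_distribution_centered(self):
        r_cvs = []
        for rep in range(40):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=(90, 2))
            y = rng.normal(size=(90, 2))
            r_cvs.append(bd.cross_validate_cca(x, y, k=5, seed=rep).r_cv)
        assert abs(np.mean(r_cvs)) < 0.06

    def test_seed_reproducibility(self, rng):
        x = rng.normal(size=(60, 2))
        y = rng.normal(size=(60, 2))
        a = bd.cross_validate_cca(x, y, k=5, seed=3)
        b = bd.cross_validate_cca(x, y, k=5, seed=3)
        assert a.r_cv == b.r_cv
        assert np.array_equal(a.fold_assignment, b.fold_assignment)

    def test_every_subject_in_one_test_fold(self, rng):
        x = rng.normal(size=(63, 2))
        y = rng.normal(size=(63, 2))
        res = bd.cross_validate_cca(x, y, k=7, seed=1)
        counts = np.bincount(res.fold_assignment, minlength=7)
        assert counts.sum() == 63
        assert (counts > 0).all()

    def test_confound_residualization_removes_shared_driver(self, rng):
        """A latent carried entirely by a confound disappears after
        train-fitted residualization."""
        n = 400
        confound = rng.normal(size=n)
        x = np.column_stack([confound + rng.normal(size=n) * 0.3 for _ in range(2)])
        y = np.column_stack([confound + rng.normal(size=n) * 0.3 for _ in range(2)])
        naked = bd.cross_validate_cca(x, y, k=5, seed=0)
        adjusted = bd.cross_validate_cca(
            x, y, confounds=pd.DataFrame({"c": confound}), k=5, seed=0
        )
        assert naked.r_cv > 0.8
        assert abs(adjusted.r_cv) < 0.25

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k="):
            bd.cross_validate_cca(
                rng.normal(size=(12, 2)), rng.normal(size=(12, 2)), k=10
            )


class TestPermutationP:
    def test_formula_when_observed_exceeds_all_nulls(self, rng):
        n = 300
        latent = rng.normal(size=n)
        x = (latent + rng.normal(size=n) * 0.3)[:, None]
        y = (latent + rng.normal(size=n) * 0.3)[:, None]
        r, p = bd.permutation_pvalue(x, y, k=5, seed=0, n_perm=999)
        assert p == pytest.approx(1.0 / 1000.0)
        assert r > 0.8

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=(80, 1))
        y = rng.normal(size=(80, 1))
        _, p1 = bd.permutation_pvalue(x, y, k=5, seed=2, n_perm=199)
        _, p2 = bd.permutation_pvalue(x, -y, k=5, seed=2, n_perm=199)
        assert p1 == p2

    def test_small_n_perm_warns(self, rng):
        x = rng.normal(size=(60, 1))
        y = rng.normal(size=(60, 1))
        with pytest.warns(UserWarning, match="unstable"):
            bd.permutation_pvalue(x, y, k=5, seed=0, n_perm=50)


class TestBootstrapLoadings:
    def test_variable_identical_to_variate(self, rng):
        scores = rng.normal(size=120)
        res = bd.CVLatentResult(
            x_scores=scores[:, None], y_scores=scores[:, None], r_cv=1.0,
            fold_assignment=np.zeros(120, dtype=int), seed=0, k=10,
        )
        table = bd.bootstrap_loadings(
            res, pd.DataFrame({"same": scores}), n_boot=300, seed=0
        )
        assert table["loading"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert table["ci_low"].iloc[0] > 0.99

    def test_independent_variable_ci_straddles_zero(self, rng):
        scores = rng.normal(size=150)
        other = rng.normal(size=150)
        res = bd.CVLatentResult(
            x_scores=scores[:, None], y_scores=scores[:, None], r_cv=1.0,
            fold_assignment=np.zeros(150, dtype=int), seed=0, k=10,
        )
        table = bd.bootstrap_loadings(
            res, pd.DataFrame({"noise": other}), n_boot=400, seed=1
        )
        assert table["ci_low"].iloc[0] < 0 < table["ci_high"].iloc[0]

    def test_ci_endpoints_ordered(self, rng):
        scores = rng.normal(size=100)
        obs = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        res = bd.CVLatentResult(
            x_scores=scores[:, None], y_scores=scores[:, None], r_cv=0.0,
            fold_assignment=np.zeros(100, dtype=int), seed=0, k=10,
        )
        table = bd.bootstrap_loadings(res, obs, n_boot=200, seed=2)
        assert (table["ci_low"] <= table["loading"]).all()
        assert (table["loading"] <= table["ci_high"]).all()


class TestProjection:
    def test_training_data_reproduces_training_variates(self, rng):
        x = rng.normal(size=(90, 3))
        y = 0.5 * x[:, :2] + rng.normal(size=(90, 2))
        model = bd.fit_cca(x, y)
        xs = (x - model.x_mean) / model.x_sd
        expected = xs @ model.wx
        assert np.allclose(bd.project_variate(model, x), expected, atol=1e-10)

    def test_duplicated_subject_duplicates_score(self, rng):
        x = rng.normal(size=(50, 2))
        y = rng.normal(size=(50, 2)) + 0.4 * x
        model = bd.fit_cca(x, y)
        doubled = np.vstack([x[:1], x[:1]])
        scores = bd.project_variate(model, doubled)
        assert scores[0, 0] == scores[1, 0]

    def test_three_subject_hand_product(self):
        model = bd.CcaModel(
            wx=np.array([[2.0], [-1.0]]),
            wy=np.array([[1.0]]),
            correlations=np.array([0.5]),
            x_mean=np.array([1.0, 0.0]),
            x_sd=np.array([2.0, 1.0]),
            y_mean=np.array([0.0]),
            y_sd=np.array([1.0]),
        )
        x_new = np.array([[3.0, 1.0], [1.0, 0.0], [5.0, -2.0]])
        expected = ((x_new - [1.0, 0.0]) / [2.0, 1.0]) @ np.array([[2.0], [-1.0]])
        assert np.allclose(bd.project_variate(model, x_new), expected, atol=1e-12)

    def test_missing_column_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = pd.DataFrame(rng.normal(size=(40, 1)), columns=["y"])
        model = bd.fit_cca(x, y)
        with pytest.raises(ValueError, match="missing columns"):
            bd.project_variate(model, x[["a"]])


class TestStandardizedContributions:
    def test_orthonormal_predictors_equal_simple_correlations(self, rng):
        n = 400
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # zero-mean orthogonal set
        predictors = pd.DataFrame(q * math.sqrt(n - 1), columns=list("abc"))
        variate = (
            0.5 * predictors["a"] + 0.2 * predictors["b"] + rng.normal(size=n)
        ).to_numpy()
        table = bd.standardized_contributions(variate, predictors)
        vz = (variate - variate.mean()) / variate.std(ddof=1)
        for _, row in table.iterrows():
            simple = _pearson(predictors[row["predictor"]].to_numpy(), vz)
            assert row["coefficient"] == pytest.approx(simple, abs=1e-10)

    def test_predictor_duplicated_in_controls_near_zero(self, rng):
        n = 300
        a = rng.normal(size=n)
        variate = a + rng.normal(size=n) * 0.5
        # the predictor's only content beyond the control is independent noise
        predictors = pd.DataFrame({"a": a + rng.normal(size=n) * 0.5})
        controls = pd.DataFrame({"a_ctrl": a})
        table = bd.standardized_contributions(variate, predictors, controls)
        assert abs(table["coefficient"].iloc[0]) < 0.15
        naked = bd.standardized_contributions(variate, predictors)
        assert naked["coefficient"].iloc[0] > 0.5  # signal without the control

    def test_six_row_hand_normal_equations(self):
        variate = np.array([1.0, 2.0, 0.5, 3.0, 2.5, 1.5])
        pred = pd.DataFrame({"p": [0.2, 0.5, 0.1, 0.9, 0.8, 0.4]})
        vz = (variate - variate.mean()) / variate.std(ddof=1)
        pz = (pred["p"] - pred["p"].mean()) / pred["p"].std(ddof=1)
        design = np.column_stack([np.ones(6), pz])
        beta = np.linalg.solve(design.T @ design, design.T @ vz)
        table = bd.standardized_contributions(variate, pred)
        assert table["coefficient"].iloc[0] == pytest.approx(beta[1], abs=1e-10)
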