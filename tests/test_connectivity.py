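"""Motion handling, nuisance regression and FC construction."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import braindiff as bd
from braindiff.connectivity import FISHER_CLIP, MotionSummary


def _amp_at(x, freq, tr):
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), tr)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        fd = bd.framewise_displacement(np.zeros((10, 6)))
        assert np.array_equal(fd.fd, np.zeros(10))
        assert fd.mean_fd == 0.0

    def test_hand_computed_value(self):
        motion = np.zeros((2, 6))
        motion[1] = [0.1, 0.2, 0.2, 0.002, 0.0, 0.0]
        fd = bd.framewise_displacement(motion)
        assert fd.fd[0] == 0.0
        assert fd.fd[1] == pytest.approx(0.5 + 50 * 0.002, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=10, allow_nan=False))
    def test_linearity(self, factor):
        rng = np.random.default_rng(1)
        motion = rng.normal(0, 0.1, (20, 6))
        base = bd.framewise_displacement(motion)
        scaled = bd.framewise_displacement(motion * factor)
        assert np.allclose(scaled.fd, base.fd * factor, rtol=1e-9)

    def test_wrong_columns_rejected(self):
        with pytest.raises(ValueError, match="frames x 6"):
            bd.framewise_displacement(np.zeros((10, 5)))


class TestMotionBandstop:
    TR = 0.8

    def test_respiratory_band_attenuated(self):
        t = np.arange(300) * self.TR
        motion = np.tile(np.sin(2 * np.pi * 0.37 * t)[:, None], (1, 6))
        out = bd.filter_motion_regressors(motion, self.TR)
        ratio = _amp_at(out[:, 0], 0.37, self.TR) / _amp_at(motion[:, 0], 0.37, self.TR)
        assert ratio < 0.10

    def test_out_of_band_preserved(self):
        t = np.arange(300) * self.TR
        motion = np.tile(np.sin(2 * np.pi * 0.05 * t)[:, None], (1, 6))
        out = bd.filter_motion_regressors(motion, self.TR)
        ratio = _amp_at(out[:, 0], 0.05, self.TR) / _amp_at(motion[:, 0], 0.05, self.TR)
        assert abs(ratio - 1.0) < 0.05

    def test_dc_passthrough(self):
        out = bd.filter_motion_regressors(np.full((120, 6), 3.7), self.TR)
        assert np.abs(out - 3.7).max() < 1e-6

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bd.filter_motion_regressors(np.zeros((100, 6)), tr_seconds=2.0)


class TestMotionExpansion:
    def test_24_columns(self, rng):
        out = bd.expand_motion_terms(rng.normal(size=(50, 6)))
        assert out.shape == (50, 24)

    def test_constant_params_zero_derivatives(self):
        out = bd.expand_motion_terms(np.full((30, 6), 2.0))
        assert np.array_equal(out[:, 6:12], np.zeros((30, 6)))

    def test_squares_nonnegative_and_correct(self, rng):
        motion = rng.normal(size=(40, 6))
        out = bd.expand_motion_terms(motion)
        assert (out[:, 12:] >= 0).all()
        assert np.allclose(out[:, 12:18], motion**2)
        assert np.allclose(out[:, 6:12][0], 0.0)


class TestNuisanceRegression:
    def test_column_in_nuisance_removed(self, rng):
        nuis = rng.normal(size=(60, 3))
        resid = bd.regress_nuisance(nuis[:, [0]].copy(), nuis)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_signal_unchanged(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ts = np.sin(3 * t)[:, None]
        nuis = np.cos(3 * t)[:, None]
        resid = bd.regress_nuisance(ts, nuis)
        assert np.abs(resid - ts).max() < 1e-10

    def test_matches_normal_equations_oracle(self):
        ts = np.array([[1.0], [2.0], [1.5], [3.0], [2.5]])
        nuis = np.array([[0.2], [0.4], [0.1], [0.9], [0.6]])
        design = np.column_stack([np.ones(5), nuis[:, 0]])
        beta = np.linalg.solve(design.T @ design, design.T @ ts[:, 0])
        expected = ts[:, 0] - design @ beta
        resid = bd.regress_nuisance(ts, nuis)
        assert np.allclose(resid[:, 0], expected, atol=1e-12)

    def test_rank_deficient_warns(self, rng):
        nuis = rng.normal(size=(40, 2))
        nuis = np.column_stack([nuis, nuis[:, 0]])
        with pytest.warns(UserWarning, match="rank deficient"):
            bd.regress_nuisance(rng.normal(size=(40, 2)), nuis)

    def test_frame_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="frame count"):
            bd.regress_nuisance(rng.normal(size=(40, 2)), rng.normal(size=(39, 2)))


class TestComputeFc:
    def test_identical_columns_clipped(self, rng):
        col = rng.normal(size=30)
        ts = np.column_stack([col, col, rng.normal(size=30)])
        fc = bd.compute_fc(ts)
        assert fc.z[0, 1] == pytest.approx(np.arctanh(FISHER_CLIP), abs=1e-12)

    def test_half_correlation_closed_form(self):
        # construct two series with sample correlation exactly 0.5
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        y = 0.5 * a + math.sqrt(1 - 0.25) * b
        fc = bd.compute_fc(np.column_stack([a, y, rng.normal(size=200)]))
        assert fc.z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_orthogonal_sinusoids_near_zero(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        fc = bd.compute_fc(np.column_stack([np.sin(5 * t), np.cos(5 * t), np.sin(9 * t)]))
        assert abs(fc.z[0, 1]) < 0.05

    def test_diagonal_masked_and_symmetric(self, rng):
        fc = bd.compute_fc(rng.normal(size=(50, 6)))
        assert np.isnan(np.diag(fc.z)).all()
        assert np.allclose(np.nan_to_num(fc.z), np.nan_to_num(fc.z.T), atol=1e-12)

    def test_zero_variance_roi_flagged_missing(self, rng):
        ts = rng.normal(size=(40, 4))
        ts[:, 2] = 1.0
        fc = bd.compute_fc(ts)
        assert np.isnan(fc.z[2]).all()
        assert np.isnan(fc.z[:, 2]).all()
        assert np.isfinite(fc.z[0, 1])

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="frames"):
            bd.compute_fc(rng.normal(size=(10, 4)))


class TestAverageFc:
    def test_identical_runs(self, rng):
        fc = bd.compute_fc(rng.normal(size=(40, 5)))
        avg = bd.average_fc([fc, fc, fc])
        assert np.allclose(np.nan_to_num(avg.z), np.nan_to_num(fc.z), atol=1e-12)

    def test_opposite_runs_cancel(self, rng):
        fc = bd.compute_fc(rng.normal(size=(40, 5)))
        neg = bd.FCMatrix(z=-fc.z)
        avg = bd.average_fc([fc, neg])
        off = ~np.eye(5, dtype=bool)
        assert np.abs(avg.z[off]).max() < 1e-12

    def test_three_matrix_hand_mean(self):
        mats = []
        vals = [0.1, 0.5, -0.3]
        for v in vals:
            z = np.full((3, 3), v)
            np.fill_diagonal(z, np.nan)
            mats.append(bd.FCMatrix(z=z))
        avg = bd.average_fc(mats)
        assert avg.z[0, 1] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bd.average_fc([])

    def test_missing_edges_averaged_over_available(self):
        z1 = np.full((3, 3), 0.4)
        np.fill_diagonal(z1, np.nan)
        z2 = z1.copy()
        z2[0, 1] = z2[1, 0] = np.nan
        z2[0, 2] = z2[2, 0] = 0.8
        avg = bd.average_fc([bd.FCMatrix(z=z1), bd.FCMatrix(z=z2)])
        assert avg.z[0, 1] == pytest.approx(0.4)      # one run only
        assert avg.z[0, 2] == pytest.approx(0.6)      # mean of two


class TestQcFc:
    def _null_stack(self, rng, n=200, r=12):
        fc = rng.normal(0.3, 0.2, size=(n, r, r))
        fc = (fc + np.transpose(fc, (0, 2, 1))) / 2
        fd = rng.lognormal(-2, 0.4, n)
        return fc, fd

    def test_null_median_near_zero(self, rng):
        fc, fd = self._null_stack(rng)
        res = bd.qcfc(fc, fd)
        assert abs(res.median_qcfc) < 0.02

    def test_planted_edge_detected(self, rng):
        fc, fd = self._null_stack(rng)
        fc[:, 3, 7] = fc[:, 7, 3] = 5.0 * fd + rng.normal(0, 0.1, len(fd))
        res = bd.qcfc(fc, fd)
        iu = np.triu_indices(12, k=1)
        edge_pos = np.flatnonzero((iu[0] == 3) & (iu[1] == 7))[0]
        assert res.edge_qcfc[edge_pos] > 0.9

    def test_shuffled_fd_null_width(self, rng):
        """The planted-free median lies within the permutation null width."""
        fc, fd = self._null_stack(rng)
        res = bd.qcfc(fc, fd, n_null=200, seed=1)
        assert abs(res.median_qcfc) < 4 * res.null_median_width + 1e-3

    def test_constant_fd_rejected(self, rng):
        fc, _ = self._null_stack(rng)
        with pytest.raises(ValueError, match="constant"):
            bd.qcfc(fc, np.full(200, 0.1))

    def test_distance_dependence_with_geometry(self, rng, small_geometry):
        fc = rng.normal(0.3, 0.2, size=(60, 20, 20))
        fc = (fc + np.transpose(fc, (0, 2, 1))) / 2
        fd = rng.lognormal(-2, 0.4, 60)
        res = bd.qcfc(fc, fd, geometry=small_geometry)
        assert -1.0 <= res.distance_rho <= 1.0


class TestMotionExclusion:
    def _summary(self, mean_fd, frac, max_mm, n=100):
        fd = np.full(n, mean_fd)
        k = int(round((1 - frac) * n))
        if k:
            fd[:k] = 0.5  # frames above threshold
            fd[k:] = (mean_fd * n - 0.5 * k) / (n - k)
        return MotionSummary(fd=fd, mean_fd=float(fd.mean()), max_param_excursion=max_mm)

    def test_high_mean_fd_excluded(self):
        subjects = {"a": self._summary(0.25, 1.0, 1.0)}
        assert bd.apply_motion_exclusion(subjects) == []

    def test_all_criteria_met_retained(self):
        subjects = {"a": self._summary(0.10, 0.85, 2.0)}
        assert bd.apply_motion_exclusion(subjects) == ["a"]

    def test_boundary_mean_fd_is_strict(self):
        fd = np.full(100, 0.1999999)
        fd_exact = np.full(100, 0.20)
        keep = MotionSummary(fd=fd, mean_fd=0.1999999, max_param_excursion=1.0)
        drop = MotionSummary(fd=fd_exact, mean_fd=0.20, max_param_excursion=1.0)
        assert bd.apply_motion_exclusion({"k": keep, "d": drop}) == ["k"]

    def test_missing_summary_excluded(self):
        subjects = {"a": None, "b": self._summary(0.1, 0.9, 1.0)}
        assert bd.apply_motion_exclusion(subjects) == ["b"]

    def test_max_motion_strict(self):
        subjects = {"a": self._summary(0.1, 0.9, 5.0), "b": self._summary(0.1, 0.9, 4.99)}
        assert bd.apply_motion_exclusion(subjects) == ["b"]
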