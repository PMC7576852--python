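"""UCM decomposition: mean-free fluctuations, Jacobian regression,
null/row-space variance projections, IMA, epoch averaging."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from liftucm.ucm import (
    CycleFluctuations,
    UcmSeries,
    epoch_average,
    estimate_jacobian,
    gev,
    ima,
    mean_free,
    ngev,
    null_row_bases,
    ucm_series,
)

J_AXIS = np.array([[1.0, 0, 0], [0, 1.0, 0]])


class TestMeanFree:
    def test_simple_column(self):
        out = mean_free(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out[:, 0], [-1, 0, 1])

    def test_constant_column_all_zero(self):
        assert np.allclose(mean_free(np.full((5, 2), 3.3)), 0.0)

    def test_column_means_vanish(self, rng):
        out = mean_free(rng.standard_normal((20, 4)))
        assert np.max(np.abs(out.mean(axis=0))) < 1e-12

    def test_too_few_repetitions(self):
        with pytest.raises(ValueError, match="insufficient repetitions"):
            mean_free(np.ones((2, 3)))


class TestEstimateJacobian:
    def test_noiseless_system_recovered_exactly(self, rng):
        j0 = rng.standard_normal((2, 3))
        dh = mean_free(rng.standard_normal((20, 3)))
        dd = dh @ j0.T
        jac = estimate_jacobian(CycleFluctuations(dh, dd))
        assert np.max(np.abs(jac.J - j0)) < 1e-10
        assert np.allclose(jac.adj_r2, 1.0)

    def test_noisy_fit_equals_normal_equations_oracle(self, rng):
        j0 = rng.standard_normal((2, 3))
        dh = mean_free(rng.standard_normal((20, 3)))
        dd = dh @ j0.T + 0.1 * rng.standard_normal((20, 2))
        dd = dd - dd.mean(axis=0)
        jac = estimate_jacobian(CycleFluctuations(dh, dd))
        oracle = (np.linalg.inv(dh.T @ dh) @ dh.T @ dd).T
        assert np.max(np.abs(jac.J - oracle)) < 1e-9

    def test_rank_deficient_dh_raises(self, rng):
        dh = mean_free(rng.standard_normal((10, 3)))
        dh[:, 2] = 0.0
        with pytest.raises(ValueError, match="degenerate fluctuations"):
            estimate_jacobian(CycleFluctuations(dh, dh[:, :2]))


class TestVarianceProjections:
    def test_identity_covariance(self):
        assert gev(J_AXIS, np.eye(3)) == pytest.approx(1.0)
        assert ngev(J_AXIS, np.eye(3)) == pytest.approx(1.0)

    def test_axis_aligned_cases(self):
        assert gev(J_AXIS, np.diag([1.0, 1.0, 4.0])) == pytest.approx(4.0)
        assert ngev(J_AXIS, np.diag([3.0, 5.0, 4.0])) == pytest.approx(4.0)

    def test_trace_conservation(self, rng):
        for _ in range(50):
            j = rng.standard_normal((2, 4))
            a = rng.standard_normal((4, 4))
            c = a @ a.T
            total = 2 * gev(j, c, n=4, d=2) + 2 * ngev(j, c, d=2)
            assert total == pytest.approx(np.trace(c), abs=1e-9)

    def test_invariance_to_basis_rotation_within_subspaces(self, rng):
        # projecting onto any orthonormal basis of the same subspace gives
        # the same trace; compare against an explicitly rotated basis
        j = rng.standard_normal((2, 5))
        a = rng.standard_normal((5, 5))
        c = a @ a.T
        N, R = null_row_bases(j)
        q_null = ortho_group.rvs(N.shape[1], random_state=1)
        q_row = ortho_group.rvs(R.shape[1], random_state=2)
        g_rot = np.trace((N @ q_null).T @ c @ (N @ q_null)) / N.shape[1]
        n_rot = np.trace((R @ q_row).T @ c @ (R @ q_row)) / R.shape[1]
        assert g_rot == pytest.approx(gev(j, c, n=5, d=2), abs=1e-9)
        assert n_rot == pytest.approx(ngev(j, c, d=2), abs=1e-9)

    def test_monte_carlo_projection_oracle(self, rng):
        j = rng.standard_normal((2, 3))
        a = rng.standard_normal((3, 3))
        c = a @ a.T
        samples = rng.multivariate_normal(np.zeros(3), c, size=200_000)
        N, R = null_row_bases(j)
        g_mc = (samples @ N).var(axis=0, ddof=1).mean()
        n_mc = (samples @ R).var(axis=0, ddof=1).mean()
        assert abs(g_mc - gev(j, c)) / gev(j, c) < 0.02
        assert abs(n_mc - ngev(j, c)) / ngev(j, c) < 0.02

    def test_rank_deficient_jacobian_raises(self):
        j = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate Jacobian"):
            gev(j, np.eye(3))


class TestIma:
    def test_equal_variances_give_zero(self):
        assert ima(0.7, 0.7) == pytest.approx(0.0)

    def test_closed_form(self):
        assert ima(4.0, 1.0) == pytest.approx(np.log(4.0))

    def test_nonpositive_inputs_propagate_as_nan(self):
        assert np.isnan(ima(0.0, 1.0))
        assert np.isnan(ima(1.0, -2.0))
        assert np.isnan(ima(float("nan"), 1.0))


class TestUcmSeries:
    def _data(self, rng, reps=20, pts=30):
        j0 = rng.standard_normal((2, 3))
        h = 1.0 + 0.1 * rng.standard_normal((reps, 3, pts))
        d = np.einsum("dk,rkp->rdp", j0, h)
        return h, d

    def test_shapes_and_finiteness(self, rng):
        h, d = self._data(rng)
        s = ucm_series(h, d, phase="lift", segment="pelvis")
        assert s.gev.shape == (30,) and s.C.shape == (30, 3, 3)
        assert np.all(np.isfinite(s.ima))

    def test_repetition_order_invariance(self, rng):
        h, d = self._data(rng)
        s1 = ucm_series(h, d)
        perm = rng.permutation(h.shape[0])
        s2 = ucm_series(h[perm], d[perm])
        assert np.allclose(s1.gev, s2.gev, atol=1e-12)
        assert np.allclose(s1.ngev, s2.ngev, atol=1e-12)

    def test_identical_repetitions_degenerate(self):
        h = np.ones((10, 3, 5))
        d = np.ones((10, 2, 5))
        with pytest.raises(ValueError, match="degenerate"):
            ucm_series(h, d)

    def test_error_reports_cycle_point(self, rng):
        h, d = self._data(rng, pts=5)
        h[:, :, 2] = 1.0  # no variability at point 3
        with pytest.raises(ValueError, match="cycle point 3"):
            ucm_series(h, d)


class TestEpochAverage:
    def _series(self, ima_vals, gev_vals=None, ngev_vals=None):
        n = len(ima_vals)
        g = np.ones(n) if gev_vals is None else np.asarray(gev_vals, float)
        ng = np.ones(n) if ngev_vals is None else np.asarray(ngev_vals, float)
        return UcmSeries(
            C=np.zeros((n, 3, 3)), gev=g, ngev=ng,
            ima=np.asarray(ima_vals, float), n_modes=3, d=2,
            phase="lift", segment="pelvis",
        )

    def test_constant_series(self):
        early, late = epoch_average(self._series(np.full(100, 0.4)))
        assert early.mean_ima == pytest.approx(0.4)
        assert late.mean_ima == pytest.approx(0.4)
        assert early.epoch == "early" and late.epoch == "late"

    def test_index_series_arithmetic(self):
        early, late = epoch_average(self._series(np.arange(1.0, 101.0)))
        assert early.mean_ima == pytest.approx(25.5)
        assert late.mean_ima == pytest.approx(75.5)

    def test_log_means(self):
        early, _ = epoch_average(
            self._series(np.zeros(100), gev_vals=np.full(100, np.e))
        )
        assert early.mean_log_gev == pytest.approx(1.0)
        assert early.mean_log_ngev == pytest.approx(0.0)

    def test_undefined_points_excluded_and_flagged(self):
        vals = np.full(100, 0.5)
        vals[:20] = np.nan  # 40% of the early epoch undefined
        early, late = epoch_average(self._series(vals))
        assert early.n_excluded == 20 and early.exclusion_warning
        assert early.mean_ima == pytest.approx(0.5)
        assert late.n_excluded == 0 and not late.exclusion_warning
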