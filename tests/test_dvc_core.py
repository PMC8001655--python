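import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from dvctomo import dvc_core, phantom
from dvctomo.dvc_core import CorrelationConfig, DisplacementField, NodeStatus
from dvctomo.register_blend import AffineTransform
from dvctomo.volio import Volume

TIGHT = CorrelationConfig(
    prefilter_kernel=1, window_size=12, search_radius=5, node_offset=1, tolerance=1e-9, max_iterations=100
)


def integer_shifted(v, d):
    return v.with_data(ndimage.shift(v.data, d, order=0, mode="constant", cval=float(v.data.min())))


class TestPrefilter:
    def test_kernel_one_is_identity(self, textured_volume):
        out = dvc_core.prefilter(textured_volume, 1)
        np.testing.assert_array_equal(out.data, textured_volume.data)

    def test_constant_unchanged(self):
        v = Volume(np.full((8, 8, 8), 3.0), voxel_size=1.0)
        out = dvc_core.prefilter(v, 3)
        np.testing.assert_allclose(out.data, 3.0)

    def test_impulse_removed(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        out = dvc_core.prefilter(Volume(data, voxel_size=1.0), 3)
        np.testing.assert_allclose(out.data, 0.0)

    def test_even_kernel_rejected(self, textured_volume):
        with pytest.raises(ValueError):
            dvc_core.prefilter(textured_volume, 4)


class TestIntegerSearch:
    def test_identity(self, textured_volume):
        d, cc = dvc_core.integer_search(textured_volume, textured_volume, (32, 32, 32), TIGHT)
        np.testing.assert_array_equal(d, [0, 0, 0])
        assert cc == pytest.approx(1.0)

    def test_integer_shift_recovered(self, textured_volume):
        shifted = integer_shifted(textured_volume, (3, -2, 1))
        d, cc = dvc_core.integer_search(textured_volume, shifted, (32, 32, 32), TIGHT)
        np.testing.assert_array_equal(d, [3, -2, 1])
        assert cc == pytest.approx(1.0)

    def test_zero_variance_window_errors(self):
        v = Volume(np.zeros((32, 32, 32)), voxel_size=1.0)
        with pytest.raises(ValueError, match="variance"):
            dvc_core.integer_search(v, v, (16, 16, 16), TIGHT)

    def test_out_of_bounds_window_errors(self, textured_volume):
        with pytest.raises(ValueError):
            dvc_core.integer_search(textured_volume, textured_volume, (2, 2, 2), TIGHT)

    def test_matches_exhaustive_oracle(self, textured_volume, rng):
        """Hill climbing agrees with brute force on a 20-node instance."""
        cfg = CorrelationConfig(
            prefilter_kernel=1, window_size=8, search_radius=4, node_offset=1
        )
        shifted = integer_shifted(textured_volume, (2, -1, 1))
        nodes = rng.integers(18, 46, size=(20, 3))
        for node in nodes:
            d_hc, cc_hc = dvc_core.integer_search(textured_volume, shifted, node, cfg)
            d_ex, cc_ex = dvc_core.exhaustive_search(textured_volume, shifted, node, cfg)
            np.testing.assert_array_equal(d_hc, d_ex)
            assert cc_hc == pytest.approx(cc_ex)


class TestSubvoxelRefine:
    def test_identity_converges_immediately(self, textured_volume):
        u, lin, status, n_iter = dvc_core.subvoxel_refine(
            textured_volume, textured_volume, (32, 32, 32), (0, 0, 0), TIGHT
        )
        assert status == NodeStatus.CONVERGED
        assert n_iter <= 1
        np.testing.assert_allclose(u, 0.0, atol=1e-12)
        np.testing.assert_allclose(lin, np.eye(3), atol=1e-12)

    def test_half_voxel_shift_within_tolerance(self, textured_volume):
        t = AffineTransform.from_translation([0.5, 0.0, 0.0])
        deformed = phantom.apply_deformation(textured_volume, t)
        d, _ = dvc_core.integer_search(textured_volume, deformed, (32, 32, 32), TIGHT)
        u, _, status, _ = dvc_core.subvoxel_refine(textured_volume, deformed, (32, 32, 32), d, TIGHT)
        assert status == NodeStatus.CONVERGED
        assert np.abs(u - [0.5, 0.0, 0.0]).max() < 0.05

    def test_exact_for_model_consistent_shift(self, textured_volume):
        """Trilinear-synthesized shifts are recovered to 1e-6."""
        truth = np.array([0.3, -0.45, 0.2])
        deformed = phantom.apply_deformation(textured_volume, AffineTransform.from_translation(truth))
        d, _ = dvc_core.integer_search(textured_volume, deformed, (32, 32, 32), TIGHT)
        u, _, status, _ = dvc_core.subvoxel_refine(textured_volume, deformed, (32, 32, 32), d, TIGHT)
        assert status == NodeStatus.CONVERGED
        assert np.abs(u - truth).max() < 1e-6

    def test_exact_for_integer_shift(self, textured_volume):
        shifted = integer_shifted(textured_volume, (2, 1, -1))
        u, _, status, _ = dvc_core.subvoxel_refine(
            textured_volume, shifted, (32, 32, 32), (2, 1, -1), TIGHT
        )
        assert status == NodeStatus.CONVERGED
        assert np.abs(u - [2, 1, -1]).max() < 1e-6

    def test_small_shear_recovered(self, textured_volume):
        L = np.eye(3)
        L[0, 1] = 0.02
        t = AffineTransform(linear=L, translation=[0.2, 0.0, 0.0])
        deformed = phantom.apply_deformation(textured_volume, t)
        node = np.array([32, 32, 32])
        d, _ = dvc_core.integer_search(textured_volume, deformed, node, TIGHT)
        u, lin, status, _ = dvc_core.subvoxel_refine(textured_volume, deformed, node, d, TIGHT)
        assert status == NodeStatus.CONVERGED
        assert abs(lin[0, 1] - 0.02) < 0.002  # within 10% of prescribed
        truth_u = t.apply(node.astype(float)) - node
        assert np.abs(u - truth_u).max() < 0.01


class TestCorrelatePlane:
    def test_identical_volumes_all_zero(self, full_texture_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, window_size=8, search_radius=3, node_offset=8)
        field = dvc_core.correlate_plane(full_texture_volume, full_texture_volume, axis=0, index=32, cfg=cfg, thickness=20)
        assert (field.status == NodeStatus.CONVERGED).all()
        np.testing.assert_allclose(field.u, 0.0, atol=1e-9)

    def test_rigid_shift_recovered(self, full_texture_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, window_size=10, search_radius=6, node_offset=8)
        shifted = integer_shifted(full_texture_volume, (0, 4, 4))
        field = dvc_core.correlate_plane(full_texture_volume, shifted, axis=0, index=32, cfg=cfg, thickness=20)
        conv = field.status == NodeStatus.CONVERGED
        assert conv.any()
        err = np.abs(field.u[conv] - [0, 4, 4]).max()
        assert err < 0.05

    def test_node_count_contract(self, textured_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, window_size=8, search_radius=3, node_offset=6)
        field = dvc_core.correlate_plane(textured_volume, textured_volume, axis=0, index=32, cfg=cfg, thickness=20)
        margin = cfg.window_size // 2 + cfg.search_radius + 1
        expected = len(np.arange(margin, 64 - margin, cfg.node_offset)) ** 2
        assert field.n_nodes == expected
        assert field.grid_shape[0] * field.grid_shape[1] == expected

    def test_slab_out_of_bounds(self, textured_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, window_size=8, search_radius=3, node_offset=8)
        with pytest.raises(ValueError, match="slab"):
            dvc_core.correlate_plane(textured_volume, textured_volume, axis=0, index=2, cfg=cfg, thickness=20)


def make_grid_field(u_grid, status=None):
    gy, gx, _ = u_grid.shape
    yy, xx = np.mgrid[0:gy, 0:gx]
    coords = np.stack([np.zeros_like(yy), yy, xx], axis=-1).reshape(-1, 3) * 8
    u = u_grid.reshape(-1, 3).astype(float)
    if status is None:
        status = np.full(gy * gx, int(NodeStatus.CONVERGED))
    return DisplacementField(
        node_coords=coords, u=u, ncc=np.ones(gy * gx), status=status, grid_shape=(gy, gx)
    )


class TestFilterField:
    def test_clean_field_unchanged(self):
        u = np.tile([1.0, 2.0, 3.0], (5, 5, 1))
        f = dvc_core.filter_field(make_grid_field(u))
        np.testing.assert_allclose(f.u, np.tile([1.0, 2.0, 3.0], (25, 1)))
        assert (f.status == NodeStatus.CONVERGED).all()

    def test_unconverged_replaced_by_neighbors(self):
        u = np.tile([1.0, 1.0, 1.0], (5, 5, 1))
        status = np.full(25, int(NodeStatus.CONVERGED))
        status[12] = NodeStatus.UNCONVERGED
        u.reshape(-1, 3)[12] = np.nan
        f = dvc_core.filter_field(make_grid_field(u, status))
        np.testing.assert_allclose(f.u[12], [1.0, 1.0, 1.0])
        assert f.status[12] == NodeStatus.REPLACED

    def test_spike_replaced(self):
        u = np.tile([1.0, 1.0, 1.0], (5, 5, 1))
        u[2, 2] = [11.0, 1.0, 1.0]
        f = dvc_core.filter_field(make_grid_field(u), outlier_k=3.0)
        np.testing.assert_allclose(f.u.reshape(5, 5, 3)[2, 2], [1.0, 1.0, 1.0])
        assert f.status.reshape(5, 5)[2, 2] == NodeStatus.REPLACED

    def test_idempotent(self, rng):
        u = rng.normal(0, 0.01, (6, 6, 3)) + [1.0, 2.0, 0.0]
        u[3, 3] = [9.0, 2.0, 0.0]
        f1 = dvc_core.filter_field(make_grid_field(u))
        f2 = dvc_core.filter_field(f1)
        np.testing.assert_allclose(f2.u, f1.u, atol=1e-12)

    def test_all_unconverged_errors(self):
        u = np.full((3, 3, 3), np.nan)
        status = np.full(9, int(NodeStatus.UNCONVERGED))
        with pytest.raises(ValueError, match="unconverged"):
            dvc_core.filter_field(make_grid_field(u, status))


class TestErrorMetrics:
    def test_mbe_zero_for_equal(self):
        assert dvc_core.mbe([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_mbe_balanced(self):
        assert dvc_core.mbe([2.0, 2.0], [1.0, 3.0]) == 0.0

    def test_mbe_matches_reported_row(self):
        # window-6 row of the calibration table: 28.2842 vs 24.38 -> 3.9
        assert dvc_core.mbe([28.2842], [24.38]) == pytest.approx(3.9042)
        assert round(dvc_core.mbe([28.2842], [24.38]), 1) == 3.9

    def test_rmse_examples(self):
        assert dvc_core.rmse([2.0, 2.0], [1.0, 3.0]) == pytest.approx(1.0)
        assert dvc_core.rmse([1.0], [1.0]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dvc_core.mbe([], [])
        with pytest.raises(ValueError):
            dvc_core.rmse([], [])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False), st.floats(-100, 100, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_rmse_dominates_mbe(self, pairs):
        p, o = zip(*pairs)
        assert dvc_core.rmse(p, o) >= abs(dvc_core.mbe(p, o)) - 1e-12


@pytest.fixture(scope="module")
def calibration_volume():
    spec = phantom.PhantomSpec(shape=(96, 96, 96), seed=7, texture_amplitude=0.2)
    return phantom.make_bone_phantom(spec)


def region_nodes(center, half, plane_axis=2):
    axes = [a for a in range(3) if a != plane_axis]
    g0, g1 = np.meshgrid(
        np.arange(center - half, center + half), np.arange(center - half, center + half), indexing="ij"
    )
    nodes = np.zeros((g0.size, 3), dtype=int)
    nodes[:, axes[0]] = g0.ravel()
    nodes[:, axes[1]] = g1.ravel()
    nodes[:, plane_axis] = center
    return nodes


class TestCalibrateWindow:
    def test_ideal_magnitude(self):
        assert dvc_core.ideal_in_plane_magnitude([20, 20]) == pytest.approx(28.2842, abs=1e-4)

    def test_zero_motion_all_zero(self, calibration_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, search_radius=2)
        rows = dvc_core.calibrate_window(
            calibration_volume, [[0, 0, 0]], region_nodes(48, 3), [8], cfg=cfg
        )
        r = rows[0]
        assert r.unconverged == 0
        assert r.mean_uYZ == pytest.approx(0.0, abs=1e-9)
        assert r.sigma_YZ == pytest.approx(0.0, abs=1e-9)
        assert r.mbe == pytest.approx(0.0, abs=1e-9)
        assert r.rmse == pytest.approx(0.0, abs=1e-9)

    def test_staircase_recovery_and_monotonicity(self, calibration_volume):
        """Noise-free 5 x (4,4) staircase: window sweep errors never grow."""
        cfg = CorrelationConfig(prefilter_kernel=1, search_radius=5)
        steps = np.tile([4, 4, 0], (3, 1))
        rows = dvc_core.calibrate_window(
            calibration_volume, steps, region_nodes(48, 3), [6, 10, 14, 18], cfg=cfg
        )
        rmses = [r.rmse for r in rows]
        for a, b in zip(rmses, rmses[1:]):
            assert b <= a + 1e-6
        final = rows[-1]
        assert final.unconverged == 0
        assert final.mean_uYZ == pytest.approx(
            dvc_core.ideal_in_plane_magnitude([12, 12]), abs=0.01
        )
        for r in rows:
            if np.isfinite(r.rmse):
                assert r.rmse >= abs(r.mbe) - 1e-12
                assert r.sigma_YZ >= 0

    def test_motion_out_of_bounds(self, calibration_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, search_radius=3)
        with pytest.raises(ValueError, match="out of bounds"):
            dvc_core.calibrate_window(
                calibration_volume, np.tile([20, 20, 0], (5, 1)), region_nodes(48, 3), [8], cfg=cfg
            )

    def test_dataframe_schema(self, calibration_volume):
        cfg = CorrelationConfig(prefilter_kernel=1, search_radius=2)
        rows = dvc_core.calibrate_window(
            calibration_volume, [[0, 0, 0]], region_nodes(48, 2), [8], cfg=cfg
        )
        df = dvc_core.calibration_to_dataframe(rows)
        assert list(df.columns) == ["window_size", "NaN", "mean_uYZ", "sigma_YZ", "MBE", "RMSE", "elapsed_s"]


class TestConfig:
    def test_window_voxel_count(self):
        assert CorrelationConfig(window_size=18).window_voxels == 5832

    def test_invalid_windows(self):
        with pytest.raises(ValueError):
            CorrelationConfig(window_size=7)
        with pytest.raises(ValueError):
            CorrelationConfig(window_size=4)
        with pytest.raises(ValueError):
            CorrelationConfig(prefilter_kernel=2)
        with pytest.raises(ValueError):
            CorrelationConfig(tolerance=0.0)
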