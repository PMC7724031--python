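"""Field sampling and pathline integration: interpolation identities,
closed-form and cross-scheme oracles, convergence, conservation,
determinism, and persistence."""

import numpy as np
import pytest

from lvflow import (
    AcquisitionMeta,
    MaskVolume,
    PhantomSpec,
    TraceConfig,
    VelocityField4D,
    generate_affine_field,
    load_pathlines,
    sample_velocity,
    save_pathlines,
    trace_all,
    trace_pathline,
)
from lvflow.exceptions import EmptyMaskError, OutOfFieldError, ShapeMismatchError
from lvflow.io import default_affine
from lvflow.tracer import _integrate


def _tiny_field(values_per_frame, n=8, h=2.0, dt=50.0):
    """A (T, n, n, n, 3) field with a uniform value per frame."""
    t = len(values_per_frame)
    data = np.zeros((t, n, n, n, 3))
    for k, v in enumerate(values_per_frame):
        data[k] = np.asarray(v)
    meta = AcquisitionMeta(venc_cm_s=140.0, dt_ms=dt, voxel_size_mm=(h, h, h),
                           cycle_length_ms=t * dt, ed_frame=0, es_frame=t // 2)
    return VelocityField4D(data=data, affine=default_affine((h, h, h)), meta=meta)


class TestSampleVelocity:
    def test_node_values_reproduced(self, small_phantom):
        f = small_phantom.field
        p = f.origin_mm + np.array([10, 12, 14]) * f.voxel_size_mm
        for k in (0, 3, f.n_frames - 1):
            v = sample_velocity(f, p, f.frame_time_ms(k))
            np.testing.assert_array_almost_equal(v, f.data[k, 10, 12, 14], decimal=12)

    def test_temporal_midpoint_is_average(self):
        f = _tiny_field([(0, 0, 0.2), (0, 0, 0.4)] + [(0, 0, 0)] * 2)
        v = sample_velocity(f, np.array([6.0, 6.0, 6.0]), 25.0)
        np.testing.assert_allclose(v, [0, 0, 0.3])

    def test_periodic_in_time(self):
        f = _tiny_field([(0.1, 0, 0), (0, 0.2, 0), (0, 0, 0.3), (0, 0, 0)])
        p = np.array([7.0, 7.0, 7.0])
        t = 37.0
        np.testing.assert_allclose(sample_velocity(f, p, t),
                                   sample_velocity(f, p, t + f.cycle_length_ms))

    def test_out_of_extent_raises(self):
        f = _tiny_field([(0, 0, 0)] * 2)
        with pytest.raises(OutOfFieldError):
            sample_velocity(f, np.array([-1.0, 5.0, 5.0]), 0.0)


class TestTracePathline:
    def test_uniform_translation_endpoint(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), cycle_length_ms=1000.0)
        bm = generate_affine_field("translation", {"velocity_m_s": (0.1, 0, 0)}, spec)
        leg = trace_pathline(bm.field, [10.0, 60.0, 60.0], 0.0, 1000.0)
        np.testing.assert_allclose(leg.positions_mm[0, -1], [110.0, 60.0, 60.0])
        assert not leg.exited[0]

    def test_rotation_closes_within_tenth_voxel(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), cycle_length_ms=1000.0)
        bm = generate_affine_field("rotation", {"omega_rad_per_s": 2 * np.pi}, spec)
        seed = np.array([90.0, 65.8, 65.8])
        leg = trace_pathline(bm.field, seed, 0.0, 1000.0)
        assert np.abs(leg.positions_mm[0, -1] - seed).max() / 2.8 < 0.1

    def test_forward_then_backward_returns_to_seed(self, small_phantom):
        """Self-inverse property on a smooth field: tracing a leg and then
        integrating back over the same interval recovers the seed."""
        f = small_phantom.field
        seeds = small_phantom.edv_mask.affine[:3, 3] + \
            np.argwhere(small_phantom.edv_mask.data)[::50] * f.voxel_size_mm
        fwd = _integrate(f, seeds, 0.0, 300.0, TraceConfig())
        back = _integrate(f, fwd.endpoints_mm, 300.0, 0.0, TraceConfig())
        err_vox = np.abs(back.endpoints_mm - seeds).max() / f.voxel_size_mm.max()
        assert err_vox < 0.25

    def test_seed_outside_raises(self, small_phantom):
        with pytest.raises(OutOfFieldError):
            trace_pathline(small_phantom.field, [-5.0, 0.0, 0.0], 0.0, 100.0)

    def test_out_of_field_freeze_flags_exit(self):
        spec = PhantomSpec(grid_shape=(16, 16, 16), cycle_length_ms=1000.0,
                           n_frames=10, es_frame=5)
        bm = generate_affine_field("translation", {"velocity_m_s": (0.1, 0, 0)}, spec)
        leg = trace_pathline(bm.field, [20.0, 20.0, 20.0], 0.0, 1000.0)
        assert leg.exited[0]
        # frozen at the last in-field position, inside the extent
        assert leg.positions_mm[0, -1, 0] <= 15 * 2.8


class TestIntegratorOracles:
    def test_euler_refined_matches_rk4(self):
        """Cross-scheme oracle: Euler at 64x substeps agrees with RK4 at the
        default substeps within 0.25 voxel."""
        spec = PhantomSpec(grid_shape=(48, 48, 48), cycle_length_ms=1000.0)
        bm = generate_affine_field("rotation", {"omega_rad_per_s": 2 * np.pi}, spec)
        seeds = np.array([[90.0, 65.8, 65.8], [70.0, 50.0, 60.0]])
        rk4 = _integrate(bm.field, seeds, 0.0, 1000.0,
                         TraceConfig(substeps_per_frame=8, store_stride=8))
        euler = _integrate(bm.field, seeds, 0.0, 1000.0,
                           TraceConfig(substeps_per_frame=512, integrator="euler",
                                       store_stride=512))
        err = np.abs(rk4.endpoints_mm - euler.endpoints_mm).max() / 2.8
        assert err < 0.25

    def test_rk4_convergence_order_above_one(self):
        """Halving the substep shrinks the endpoint error by more than the
        previous halving (empirical order > 1 on a smooth field)."""
        spec = PhantomSpec(grid_shape=(48, 48, 48), cycle_length_ms=1000.0)
        bm = generate_affine_field("rotation", {"omega_rad_per_s": 4 * np.pi}, spec)
        seeds = np.array([[100.0, 65.8, 65.8]])
        exact = bm.solution(seeds, 0.0, 1000.0)
        errs = []
        for sub in (1, 2, 4):
            leg = _integrate(bm.field, seeds, 0.0, 1000.0,
                             TraceConfig(substeps_per_frame=sub, store_stride=sub))
            errs.append(np.abs(leg.endpoints_mm - exact).max())
        assert errs[1] < errs[0] and errs[2] < errs[1]
        # error ratio improves (order > 1): successive reductions grow
        assert errs[0] / errs[1] > 2.0 and errs[1] / errs[2] > 2.0


class TestTraceAll:
    def test_one_pathline_per_edv_voxel(self, small_phantom, small_pathlines):
        assert len(small_pathlines) == int(small_phantom.edv_mask.data.sum())

    def test_parcel_volumes_partition_edv(self, small_phantom, small_pathlines):
        voxel_ml = small_phantom.edv_mask.voxel_volume_ml
        assert small_pathlines.parcel_volume_ml == voxel_ml
        assert small_pathlines.edv_volume_ml == pytest.approx(
            small_phantom.edv_mask.volume_ml(), abs=0)

    def test_zero_field_keeps_seeds(self, small_phantom):
        f = small_phantom.field
        zero = VelocityField4D(data=np.zeros_like(f.data), affine=f.affine, meta=f.meta)
        ps = trace_all(zero, small_phantom.edv_mask, TraceConfig(store_stride=8))
        np.testing.assert_array_equal(ps.forward.endpoints_mm, ps.seed_positions_mm)
        np.testing.assert_array_equal(ps.backward.endpoints_mm, ps.seed_positions_mm)

    def test_leg_time_ordering_and_seed_start(self, small_pathlines):
        ps = small_pathlines
        assert np.all(np.diff(ps.forward.times_ms) > 0)
        assert np.all(np.diff(ps.backward.times_ms) < 0)
        np.testing.assert_array_equal(ps.forward.positions_mm[:, 0], ps.seed_positions_mm)
        np.testing.assert_array_equal(ps.backward.positions_mm[:, 0], ps.seed_positions_mm)

    def test_determinism(self, small_phantom):
        a = trace_all(small_phantom.field, small_phantom.edv_mask)
        b = trace_all(small_phantom.field, small_phantom.edv_mask)
        assert np.array_equal(a.forward.positions_mm, b.forward.positions_mm)
        assert np.array_equal(a.backward.velocities_m_s, b.backward.velocities_m_s)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            MaskVolume(np.zeros((4, 4, 4)), default_affine((1, 1, 1)))

    def test_grid_mismatch_rejected(self, small_phantom):
        wrong = MaskVolume(np.ones((8, 8, 8)), default_affine((2.8,) * 3))
        with pytest.raises(ShapeMismatchError):
            trace_all(small_phantom.field, wrong)


def test_pathline_view_and_hdf5_roundtrip(tmp_path, small_pathlines):
    ps = small_pathlines
    pl = ps[5]
    assert pl.parcel_volume_ml == ps.parcel_volume_ml
    traj = pl.full_trajectory_mm()
    assert traj.shape[0] == len(ps.backward.times_ms) + len(ps.forward.times_ms) - 1
    np.testing.assert_array_equal(traj[len(ps.backward.times_ms) - 1], pl.seed_position_mm)

    p = tmp_path / "pl.h5"
    save_pathlines(ps, p)
    ps2 = load_pathlines(p)
    assert len(ps2) == len(ps)
    assert ps2.meta == ps.meta
    np.testing.assert_array_equal(ps2.forward.positions_mm, ps.forward.positions_mm)
    np.testing.assert_array_equal(ps2.backward.times_ms, ps.backward.times_ms)
    assert ps2.parcel_volume_ml == ps.parcel_volume_ml
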