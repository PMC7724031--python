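"""Phantom generator: analytic benchmark fields, waveform exactness,
ground-truth bookkeeping, determinism, and the noise model."""

import numpy as np
import pytest

from lvflow import (
    PhantomSpec,
    TraceConfig,
    add_velocity_noise,
    generate_affine_field,
    generate_lv_phantom,
    trace_all,
)
from lvflow.exceptions import PhantomSpecError, UnknownFieldKindError
from lvflow.phantom import COMPONENT_CODES, cardiac_waveform
from lvflow.tracer import _integrate

BENCH_SPEC = PhantomSpec(grid_shape=(48, 48, 48), cycle_length_ms=1000.0)
SEEDS = np.array([[70.0, 60.0, 65.8], [40.0, 45.0, 52.0], [66.0, 66.0, 66.0]])


TRANSLATION_SEEDS = np.array([[10.0, 60.0, 65.8], [20.0, 45.0, 52.0]])


@pytest.mark.parametrize(
    "kind,params",
    [
        ("zero", {}),
        ("translation", {"velocity_m_s": (0.1, 0.0, 0.0)}),
        ("rotation", {"omega_rad_per_s": 2 * np.pi}),
        ("expansion", {"rate_per_s": 0.3}),
    ],
)
def test_affine_benchmarks_match_closed_form(kind, params):
    """RK4 endpoints agree with the closed-form flow map within 0.1 voxel
    over one full cycle on every analytic benchmark field."""
    seeds = TRANSLATION_SEEDS if kind == "translation" else SEEDS
    bm = generate_affine_field(kind, params, BENCH_SPEC)
    leg = _integrate(bm.field, seeds, 0.0, 1000.0, TraceConfig())
    exact = bm.solution(seeds, 0.0, 1000.0)
    err_vox = np.abs(leg.positions_mm[:, -1] - exact).max() / BENCH_SPEC.voxel_size_mm
    assert err_vox < 0.1
    assert not leg.exited.any()
    if kind == "zero":
        assert np.allclose(leg.positions_mm, seeds[:, None, :])
    if kind == "translation":
        # 0.1 m/s for 1 s displaces exactly 100 mm in x
        np.testing.assert_allclose(exact[:, 0] - seeds[:, 0], 100.0)
    if kind == "rotation":
        # one full period returns to the seed
        np.testing.assert_allclose(exact, seeds, atol=1e-9)


def test_affine_field_rejects_bad_input():
    with pytest.raises(UnknownFieldKindError):
        generate_affine_field("vortex", {}, BENCH_SPEC)
    with pytest.raises(ValueError):
        generate_affine_field("translation", {"velocity_m_s": (np.nan, 0, 0)}, BENCH_SPEC)


def test_waveform_integrates_to_whole_voxels(small_spec):
    """The trapezoid integral of the frame-sampled waveform (what linear
    time interpolation transports) is an exact whole number of voxels over
    each cardiac phase, with zero speed at ES and nonzero speed at ED."""
    for spec in (small_spec, PhantomSpec(), PhantomSpec(cycle_length_ms=556.0, es_frame=9)):
        g, d_sys, d_dia = cardiac_waveform(spec)
        n, dt, h = spec.n_frames, spec.dt_ms, spec.voxel_size_mm
        sys_frames = [(spec.ed_frame + i) % n for i in range(spec.n_systolic_frames + 1)]
        dia_frames = [(spec.es_frame + j) % n for j in range(spec.n_diastolic_frames + 1)]
        int_sys = dt * (g[sys_frames[0]] / 2 + g[sys_frames[1:-1]].sum() + g[sys_frames[-1]] / 2)
        int_dia = dt * (g[dia_frames[0]] / 2 + g[dia_frames[1:-1]].sum() + g[dia_frames[-1]] / 2)
        assert int_sys == pytest.approx(d_sys * h, rel=1e-12)
        assert int_dia == pytest.approx(d_dia * h, rel=1e-12)
        assert g[spec.es_frame] == 0.0
        assert g[spec.ed_frame] > 0.0
        assert d_sys >= 1 and d_dia >= 1


class TestLVPhantomTruth:
    def test_fraction_bookkeeping(self, small_phantom):
        ds = small_phantom
        n = ds.truth_counts.sum()
        assert n == int(ds.edv_mask.data.sum())
        np.testing.assert_array_equal(ds.truth_fractions, ds.truth_counts / n)
        assert abs(ds.truth_fractions.sum() - 1.0) < 1e-12
        # within one voxel-count quantum of the targets
        target = np.asarray(ds.spec.target_fractions)
        assert np.all(np.abs(ds.truth_counts - target * n) <= 1.0)

    def test_every_edv_voxel_labelled_once(self, small_phantom):
        ds = small_phantom
        inside = ds.truth_labels[ds.edv_mask.data]
        assert np.all((inside >= 0) & (inside <= 3))
        assert np.all(ds.truth_labels[~ds.edv_mask.data] == -1)

    def test_degenerate_all_direct_flow(self):
        spec = PhantomSpec(target_fractions=(1.0, 0.0, 0.0, 0.0),
                           grid_shape=(32, 32, 32), peak_speed_m_s=0.05)
        ds = generate_lv_phantom(spec)
        assert np.all(ds.truth_labels[ds.edv_mask.data] == COMPONENT_CODES["DF"])
        np.testing.assert_array_equal(ds.truth_fractions, [1.0, 0.0, 0.0, 0.0])

    def test_unrealizable_quota_rejected(self):
        eps = 1e-6
        with pytest.raises(PhantomSpecError, match="quota"):
            generate_lv_phantom(PhantomSpec(
                grid_shape=(32, 32, 32), peak_speed_m_s=0.05,
                target_fractions=(1.0 - 3 * eps, eps, eps, eps)))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(target_fractions=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(PhantomSpecError):
            PhantomSpec(target_fractions=(-0.1, 0.5, 0.3, 0.3))
        with pytest.raises(PhantomSpecError):
            PhantomSpec(ed_frame=5, es_frame=5)

    def test_esv_masks_are_consistent_with_truth(self, small_phantom):
        """The forward ESV volume equals EDV minus the ejected truth volume."""
        ds = small_phantom
        n = ds.truth_counts.sum()
        ejected = ds.truth_counts[0] + ds.truth_counts[2]  # DF + DEF
        entered = ds.truth_counts[0] + ds.truth_counts[1]  # DF + RI
        assert int(ds.esv_mask_forward.data.sum()) == n - ejected
        assert int(ds.esv_mask_backward.data.sum()) == n - entered


def test_flow_map_consistency(small_phantom):
    """A fine-step reference trace reproduces the prescribed flow map's
    endpoint for every seed within 0.25 voxel."""
    ds = small_phantom
    ps = trace_all(ds.field, ds.edv_mask,
                   TraceConfig(substeps_per_frame=32, store_stride=32))
    h = ds.spec.voxel_size_mm
    fwd = np.abs(ps.forward.endpoints_mm
                 - ds.true_forward_endpoint_mm(ps.seed_positions_mm)).max() / h
    bwd = np.abs(ps.backward.endpoints_mm
                 - ds.true_backward_endpoint_mm(ps.seed_positions_mm)).max() / h
    assert fwd < 0.25 and bwd < 0.25


def test_seeded_determinism(small_spec):
    a = generate_lv_phantom(small_spec)
    b = generate_lv_phantom(small_spec)
    assert np.array_equal(a.field.data, b.field.data)
    assert np.array_equal(a.truth_labels, b.truth_labels)
    assert np.array_equal(a.edv_mask.data, b.edv_mask.data)

    noisy_spec = PhantomSpec(noise_sigma=0.02, seed=11,
                             grid_shape=(32, 32, 32), peak_speed_m_s=0.05)
    c = generate_lv_phantom(noisy_spec)
    d = generate_lv_phantom(noisy_spec)
    assert np.array_equal(c.field.data, d.field.data)
    assert not np.array_equal(c.field.data, c.clean_field.data)


class TestVelocityNoise:
    def test_zero_sigma_is_identity(self, small_phantom):
        out = add_velocity_noise(small_phantom.field, 0.0, 1)
        assert np.array_equal(out.data, small_phantom.field.data)
        assert out.data is not small_phantom.field.data

    def test_sigma_scales_with_venc(self, small_phantom):
        # 0.05 x VENC 140 cm/s = 7 cm/s; sample SD within 2 %
        out = add_velocity_noise(small_phantom.field, 0.05, 2)
        sd_cm_s = float((out.data - small_phantom.field.data).std()) * 100.0
        assert sd_cm_s == pytest.approx(7.0, rel=0.02)
        # original untouched
        assert small_phantom.field.data[..., 2].std() >= 0

    def test_same_seed_reproduces(self, small_phantom):
        a = add_velocity_noise(small_phantom.field, 0.05, 3)
        b = add_velocity_noise(small_phantom.field, 0.05, 3)
        assert np.array_equal(a.data, b.data)

    def test_negative_sigma_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            add_velocity_noise(small_phantom.field, -0.1, 0)


def test_field_is_periodic_over_the_cycle(small_phantom):
    """Sampling at t = cycle_length wraps exactly to frame 0."""
    from lvflow import sample_velocity

    f = small_phantom.field
    p = small_phantom.edv_mask.affine[:3, 3] + np.array([16, 16, 16]) * f.voxel_size_mm
    v0 = sample_velocity(f, p, 0.0)
    v1 = sample_velocity(f, p, f.cycle_length_ms)
    np.testing.assert_array_equal(v0, v1)
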