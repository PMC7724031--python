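"""Synthetic left-ventricular velocity phantom with exact ground truth.

The phantom emulates one cardiac cycle of a 4D-flow acquisition over a
deforming LV blood pool: a prolate-ellipsoidal end-diastolic pool on a
~2.8 mm isotropic grid, ~20 timeframes per cycle, diastolic inflow through a
basal orifice and systolic outflow through a second (distinct) basal orifice,
optional VENC-scaled Gaussian velocity noise, and per-voxel ground-truth
component labels (Direct flow, Retained inflow, Delayed ejection flow,
Residual volume).

Construction is flow-map-first.  The velocity waveform is spatially uniform
and purely axial, with one systolic ejection bump and one diastolic filling
bump (an E-wave-like bump of fixed absolute width plus a diastasis plateau so
blood is still moving at end-diastole).  The waveform's samples are rescaled
so that the *piecewise-linear-in-time* field — i.e. exactly what the tracer
interpolates — transports every parcel by a whole number of voxels over
systole and over diastole.  For such a field, trilinear interpolation is
exact and classical Runge–Kutta integration reduces to Simpson quadrature of
a piecewise-linear function, which is exact when substeps align with frames.
The prescribed flow map is therefore realized to machine precision, and every
EDV voxel's component label follows exactly from set arithmetic on
integer-voxel shifts.

Ground-truth labels are assigned by sorting the EDV voxels from base to apex
and apportioning them to the four components by largest-remainder quotas, so
realized fractions match the targets to within one voxel-count quantum.  The
end-systolic reference masks are then *constructed* as the shifted images of
the non-ejected (forward) and non-entered (backward) voxel sets, which makes
the endpoint-membership classification recover the prescribed labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import PhantomSpecError, UnknownFieldKindError
from .io import AcquisitionMeta, MaskVolume, VelocityField4D, default_affine

#: component order used throughout the package
COMPONENTS = ("DF", "RI", "DEF", "RV")
COMPONENT_CODES = {name: i for i, name in enumerate(COMPONENTS)}

#: rest-like and stress-like target fractions (DF, RI, DEF, RV).  The
#: published stress means (52, 20, 13, 16 %) sum to 101 % because of
#: rounding; the Residual-volume share absorbs the excess here so the
#: fractions form an exact partition.
REST_FRACTIONS = (0.36, 0.20, 0.17, 0.27)
STRESS_FRACTIONS = (0.52, 0.20, 0.13, 0.15)

#: width of the E-wave-like filling bump, ms (fixed in absolute time so that
#: the early-filling peak falls relatively later in a shortened diastole)
E_WAVE_WIDTH_MS = 300.0
#: late-diastolic plateau as a fraction of peak inflow speed (keeps blood
#: moving at ED, emulating preserved late-diastolic momentum)
DIASTASIS_FLOOR = 0.2
#: blood-pool semi-axes as fractions of the grid half-extent per axis
POOL_SEMI_AXIS_FRACTIONS = (0.30, 0.30, 0.56)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic LV acquisition.

    Defaults mirror the emulated protocol: 2.8 mm isotropic voxels, 20
    timeframes over a 909 ms cycle (66 bpm), VENC 140 cm/s, rest-like
    component fractions.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.8
    n_frames: int = 20
    cycle_length_ms: float = 909.0
    ed_frame: int = 0
    es_frame: int = 7
    target_fractions: tuple[float, float, float, float] = REST_FRACTIONS
    peak_speed_m_s: float = 0.10
    pool_scale: float = 1.0
    noise_sigma: float = 0.0
    venc_cm_s: float = 140.0
    seed: int = 0
    subject_id: str = "phantom"
    condition: str = "rest"

    def __post_init__(self):
        if abs(sum(self.target_fractions) - 1.0) > 1e-9:
            raise PhantomSpecError(
                f"target_fractions must sum to 1, got {sum(self.target_fractions)}"
            )
        if any(f < 0 for f in self.target_fractions):
            raise PhantomSpecError("target_fractions must be non-negative")
        n = self.n_frames
        if not (0 <= self.ed_frame < n and 0 <= self.es_frame < n):
            raise PhantomSpecError("ed_frame and es_frame must lie in [0, n_frames)")
        if self.ed_frame == self.es_frame:
            raise PhantomSpecError("ed_frame and es_frame must differ")
        if self.peak_speed_m_s > self.venc_cm_s / 100.0:
            raise PhantomSpecError("peak_speed exceeds VENC; wrap is not simulated")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be non-negative")
        if self.pool_scale <= 0:
            raise PhantomSpecError("pool_scale must be positive")
        if self.n_systolic_frames < 2 or self.n_diastolic_frames < 2:
            raise PhantomSpecError("each cardiac phase needs at least 2 frames")

    @property
    def dt_ms(self) -> float:
        return self.cycle_length_ms / self.n_frames

    @property
    def n_systolic_frames(self) -> int:
        return (self.es_frame - self.ed_frame) % self.n_frames

    @property
    def n_diastolic_frames(self) -> int:
        return (self.ed_frame - self.es_frame) % self.n_frames

    @property
    def heart_rate_bpm(self) -> float:
        return 60000.0 / self.cycle_length_ms

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            venc_cm_s=self.venc_cm_s,
            dt_ms=self.dt_ms,
            voxel_size_mm=(self.voxel_size_mm,) * 3,
            cycle_length_ms=self.cycle_length_ms,
            ed_frame=self.ed_frame,
            es_frame=self.es_frame,
            heart_rate_bpm=self.heart_rate_bpm,
            subject_id=self.subject_id,
            condition=self.condition,
        )


@dataclass
class PhantomDataset:
    """A generated acquisition plus its validation surface (exact truth)."""

    field: VelocityField4D
    edv_mask: MaskVolume
    esv_mask_forward: MaskVolume
    esv_mask_backward: MaskVolume
    truth_labels: np.ndarray  # int16 volume, -1 outside EDV, else component code
    truth_fractions: np.ndarray  # (4,) = counts / N
    truth_counts: np.ndarray  # (4,) int
    spec: PhantomSpec
    systolic_shift_vox: int
    diastolic_shift_vox: int
    clean_field: VelocityField4D = None

    def true_forward_endpoint_mm(self, seeds_mm: np.ndarray) -> np.ndarray:
        """Exact forward flow-map image (ED -> following ES) of seed positions."""
        out = np.array(seeds_mm, dtype=float, copy=True)
        out[..., 2] += self.systolic_shift_vox * self.spec.voxel_size_mm
        return out

    def true_backward_endpoint_mm(self, seeds_mm: np.ndarray) -> np.ndarray:
        """Exact backward flow-map image (ED -> preceding ES) of seed positions."""
        out = np.array(seeds_mm, dtype=float, copy=True)
        out[..., 2] -= self.diastolic_shift_vox * self.spec.voxel_size_mm
        return out


# ---------------------------------------------------------------------------
# waveform


def cardiac_waveform(spec: PhantomSpec) -> tuple[np.ndarray, int, int]:
    """Per-frame axial speed samples (m/s) and exact voxel displacements.

    Returns ``(g, d_sys, d_dia)`` where ``g[k]`` is the spatially uniform
    z-velocity at frame ``k`` and the trapezoid integral of the
    linearly-interpolated samples equals exactly ``d_sys`` voxels over systole
    (ED to ES) and ``d_dia`` voxels over diastole (ES to next ED).  Speed is
    zero at ES (flow reversal) and positive at ED (late-diastolic motion).

    Note: 1 m/s integrated over ms gives mm numerically, so no unit factors
    appear in the quadrature.
    """
    n, dt, h = spec.n_frames, spec.dt_ms, spec.voxel_size_mm
    n_sys, n_dia = spec.n_systolic_frames, spec.n_diastolic_frames
    g = np.zeros(n)

    # diastolic samples at frames es+1 .. es+n_dia (the last one is ED)
    t_dia = np.arange(1, n_dia + 1) * dt
    bump = np.where(
        t_dia <= E_WAVE_WIDTH_MS, np.sin(np.pi * t_dia / E_WAVE_WIDTH_MS) ** 2, 0.0
    )
    dia_raw = spec.peak_speed_m_s * np.maximum(bump, DIASTASIS_FLOOR)
    # trapezoid with g(ES) = 0; ED sample weighted 1/2 at the interval end
    integral_dia = dt * (np.sum(dia_raw[:-1]) + dia_raw[-1] / 2.0)
    d_dia = max(1, round(integral_dia / h))
    lam_dia = d_dia * h / integral_dia
    dia = dia_raw * lam_dia
    for j in range(1, n_dia + 1):
        g[(spec.es_frame + j) % n] = dia[j - 1]
    g_ed = dia[-1]

    # systolic interior samples at frames ed+1 .. ed+n_sys-1
    tau = np.arange(1, n_sys) / n_sys
    sys_raw = spec.peak_speed_m_s * np.sin(np.pi * tau) ** 2
    integral_sys = dt * (g_ed / 2.0 + np.sum(sys_raw))
    d_sys = max(1, round(integral_sys / h))
    lam_sys = (d_sys * h - dt * g_ed / 2.0) / (dt * np.sum(sys_raw))
    if lam_sys <= 0:
        raise PhantomSpecError("systolic waveform not realizable (displacement < ED speed tail)")
    for i in range(1, n_sys):
        g[(spec.ed_frame + i) % n] = sys_raw[i - 1] * lam_sys
    g[spec.es_frame] = 0.0
    g[spec.ed_frame] = g_ed
    return g, int(d_sys), int(d_dia)


# ---------------------------------------------------------------------------
# LV phantom


def _pool_geometry(spec: PhantomSpec):
    """Ellipsoid centre (voxel units) and semi-axes (mm) of the blood pool."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    h = spec.voxel_size_mm
    centre_vox = (shape - 1) / 2.0
    half_extent_mm = (shape - 1) / 2.0 * h
    semi_axes_mm = spec.pool_scale * np.asarray(POOL_SEMI_AXIS_FRACTIONS) * half_extent_mm
    # prolate along z, capped below the half extent
    semi_axes_mm = np.minimum(semi_axes_mm, 0.95 * half_extent_mm)
    return centre_vox, semi_axes_mm


def _largest_remainder_quotas(n: int, fractions) -> np.ndarray:
    """Integer quotas summing to n, each within one unit of n * fraction."""
    ideal = np.asarray(fractions, dtype=float) * n
    counts = np.floor(ideal).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_lv_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate a synthetic LV acquisition with exact per-voxel truth labels.

    Raises :class:`PhantomSpecError` if the fractions are invalid or the grid
    cannot realize every requested component with at least one voxel.
    """
    h = spec.voxel_size_mm
    shape = spec.grid_shape
    centre_vox, semi_mm = _pool_geometry(spec)

    idx = np.indices(shape).reshape(3, -1).T  # (nvox, 3) voxel indices
    rel = (idx - centre_vox) * h / semi_mm
    inside = (rel**2).sum(axis=1) <= 1.0
    pool = idx[inside]
    n_pool = pool.shape[0]
    if n_pool == 0:
        raise PhantomSpecError("grid too small: empty blood pool")

    g, d_sys, d_dia = cardiac_waveform(spec)

    # travel bound: pool plus displacements must stay on the grid
    z_top = pool[:, 2].max() + d_sys
    z_bot = pool[:, 2].min() - d_dia
    if z_top > shape[2] - 1 or z_bot < 0:
        raise PhantomSpecError(
            "blood pool leaves the grid under the requested waveform; "
            "enlarge the grid or reduce peak_speed"
        )

    quotas = _largest_remainder_quotas(n_pool, spec.target_fractions)
    for name, q, f in zip(COMPONENTS, quotas, spec.target_fractions):
        if f > 0 and q < 1:
            raise PhantomSpecError(
                f"grid too small to realize component {name}: quota < 1 voxel"
            )

    # base-to-apex ordering (descending z, then y, x for determinism); the
    # ejected blood (DF then DEF) occupies the basal end near the outflow
    order = np.lexsort((pool[:, 0], pool[:, 1], -pool[:, 2]))
    sorted_pool = pool[order]
    labels_flat = np.empty(n_pool, dtype=np.int16)
    block_order = ("DF", "DEF", "RI", "RV")
    start = 0
    for name in block_order:
        q = quotas[COMPONENT_CODES[name]]
        labels_flat[start:start + q] = COMPONENT_CODES[name]
        start += q

    labels = np.full(shape, -1, dtype=np.int16)
    labels[tuple(sorted_pool.T)] = labels_flat

    ejected = np.isin(labels_flat, (COMPONENT_CODES["DF"], COMPONENT_CODES["DEF"]))
    entered = np.isin(labels_flat, (COMPONENT_CODES["DF"], COMPONENT_CODES["RI"]))

    affine = default_affine((h, h, h))
    edv = np.zeros(shape, dtype=bool)
    edv[tuple(pool.T)] = True

    esv_fwd = np.zeros(shape, dtype=bool)
    kept_fwd = sorted_pool[~ejected] + np.array([0, 0, d_sys])
    esv_fwd[tuple(kept_fwd.T)] = True

    esv_bwd = np.zeros(shape, dtype=bool)
    kept_bwd = sorted_pool[~entered] + np.array([0, 0, -d_dia])
    esv_bwd[tuple(kept_bwd.T)] = True

    data = np.zeros((spec.n_frames, *shape, 3), dtype=np.float32)
    data[..., 2] = g.astype(np.float32)[:, None, None, None]
    clean = VelocityField4D(data=data, affine=affine, meta=spec.meta())

    field = clean
    if spec.noise_sigma > 0:
        field = add_velocity_noise(clean, spec.noise_sigma, spec.seed)

    counts = np.bincount(labels_flat, minlength=4)
    return PhantomDataset(
        field=field,
        edv_mask=MaskVolume(data=edv, affine=affine, label="EDV"),
        esv_mask_forward=MaskVolume(data=esv_fwd, affine=affine, label="ESV",
                                    allow_empty=True),
        esv_mask_backward=MaskVolume(data=esv_bwd, affine=affine, label="ESV",
                                     allow_empty=True),
        truth_labels=labels,
        truth_fractions=counts / n_pool,
        truth_counts=counts,
        spec=spec,
        systolic_shift_vox=d_sys,
        diastolic_shift_vox=d_dia,
        clean_field=clean,
    )


# ---------------------------------------------------------------------------
# analytic benchmark fields


@dataclass
class AffineBenchmark:
    """A benchmark field whose pathlines have a closed form.

    ``solution(seeds_mm, t0_ms, t1_ms)`` returns the exact positions at
    ``t1`` of parcels located at ``seeds_mm`` at ``t0``.
    """

    field: VelocityField4D
    kind: str
    solution: callable


def generate_affine_field(kind: str, params: dict, spec: PhantomSpec) -> AffineBenchmark:
    """Build a steady benchmark field (zero / translation / rotation / expansion).

    These fields are linear in space, so trilinear interpolation reproduces
    them exactly and integrator error is attributable to the time stepper
    alone.  Units: positions mm, time ms, velocities m/s (1 m/s = 1 mm/ms).
    """
    params = dict(params or {})
    for v in params.values():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite benchmark parameter: {params}")
    h = spec.voxel_size_mm
    shape = spec.grid_shape
    centre_mm = (np.asarray(shape) - 1) / 2.0 * h
    pos = np.stack(np.indices(shape), axis=-1) * h  # (X,Y,Z,3) world mm

    if kind == "zero":
        vel = np.zeros((*shape, 3))

        def solution(seeds_mm, t0_ms, t1_ms):
            return np.array(seeds_mm, dtype=float, copy=True)

    elif kind == "translation":
        c = np.asarray(params["velocity_m_s"], dtype=float)
        vel = np.broadcast_to(c, (*shape, 3)).copy()

        def solution(seeds_mm, t0_ms, t1_ms):
            return np.asarray(seeds_mm, dtype=float) + c * (t1_ms - t0_ms)

    elif kind == "rotation":
        omega = float(params["omega_rad_per_s"])
        centre = np.asarray(params.get("center_mm", centre_mm), dtype=float)
        rel = pos - centre
        # rigid rotation about the z axis: v = omega x r, in mm/ms (== m/s)
        vel = np.zeros((*shape, 3))
        vel[..., 0] = -omega / 1000.0 * rel[..., 1]
        vel[..., 1] = omega / 1000.0 * rel[..., 0]

        def solution(seeds_mm, t0_ms, t1_ms):
            seeds = np.asarray(seeds_mm, dtype=float)
            ang = omega * (t1_ms - t0_ms) / 1000.0
            rel = seeds - centre
            out = np.array(seeds, dtype=float, copy=True)
            out[..., 0] = centre[0] + np.cos(ang) * rel[..., 0] - np.sin(ang) * rel[..., 1]
            out[..., 1] = centre[1] + np.sin(ang) * rel[..., 0] + np.cos(ang) * rel[..., 1]
            return out

    elif kind == "expansion":
        rate = float(params["rate_per_s"])
        centre = np.asarray(params.get("center_mm", centre_mm), dtype=float)
        vel = rate / 1000.0 * (pos - centre)

        def solution(seeds_mm, t0_ms, t1_ms):
            seeds = np.asarray(seeds_mm, dtype=float)
            return centre + (seeds - centre) * math.exp(rate * (t1_ms - t0_ms) / 1000.0)

    else:
        raise UnknownFieldKindError(f"unknown benchmark field kind: {kind!r}")

    data = np.broadcast_to(vel, (spec.n_frames, *shape, 3)).astype(np.float64).copy()
    field = VelocityField4D(
        data=data, affine=default_affine((h, h, h)), meta=spec.meta()
    )
    return AffineBenchmark(field=field, kind=kind, solution=solution)


# ---------------------------------------------------------------------------
# noise


def add_velocity_noise(field: VelocityField4D, noise_sigma: float, seed: int) -> VelocityField4D:
    """Add i.i.d. zero-mean Gaussian noise of SD ``noise_sigma * VENC``.

    Emulates phase-contrast velocity noise, whose standard deviation scales
    with the velocity-encoding limit.  The input field is left unmodified;
    the same seed always yields the same output.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_sigma == 0:
        return replace(field, data=field.data.copy())
    rng = np.random.default_rng(seed)
    sigma_m_s = noise_sigma * field.meta.venc_cm_s / 100.0
    noisy = field.data + rng.normal(0.0, sigma_m_s, size=field.data.shape).astype(
        field.data.dtype
    )
    return replace(field, data=noisy)
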