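"""Lagrangian pathline tracing through a time-resolved velocity field.

Pathlines are emitted from every foreground voxel of the end-diastolic mask
and integrated forward to the following end-systole and backward to the
preceding end-systole, so that both legs together cover the entire cardiac
cycle.  Integration is fixed-step classical Runge–Kutta (RK4 default; Euler
available for cross-scheme checks) over a field interpolated trilinearly in
space and linearly in time, periodic over the cycle.

Units are chosen so no conversion factors appear inside the integrator:
positions in mm, time in ms, velocities in m/s (1 m/s == 1 mm/ms).

All seeds are advanced together as ``(N, 3)`` arrays; per-pathline access is
provided by lightweight views.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .exceptions import EmptyMaskError, LVFlowError, OutOfFieldError, ShapeMismatchError
from .io import AcquisitionMeta, MaskVolume, VelocityField4D


@dataclass(frozen=True)
class TraceConfig:
    """Integration settings.

    substeps_per_frame: integration steps per timeframe interval (so the step
        size is dt / substeps_per_frame and steps align with frame boundaries).
    integrator: "rk4" (classical 4-stage) or "euler".
    out_of_field_policy: "freeze" holds a parcel at its last in-field position
        and flags the exit (volume-conserving); "drop" flags it and blanks the
        remainder of its trajectory with NaN.
    store_stride: keep every k-th substep position (the endpoint is always
        kept).
    """

    substeps_per_frame: int = 8
    integrator: str = "rk4"
    out_of_field_policy: str = "freeze"
    store_stride: int = 1

    def __post_init__(self):
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")
        if self.store_stride < 1:
            raise ValueError("store_stride must be >= 1")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.out_of_field_policy not in ("freeze", "drop"):
            raise ValueError(f"unknown out_of_field_policy {self.out_of_field_policy!r}")


# ---------------------------------------------------------------------------
# field sampling


def _time_weights(field: VelocityField4D, t_ms: float):
    tau = (t_ms % field.cycle_length_ms) / field.dt_ms
    k0 = int(np.floor(tau))
    w = tau - k0
    k0 %= field.n_frames
    k1 = (k0 + 1) % field.n_frames
    return k0, k1, w


def _gather_trilinear(vol: np.ndarray, i0: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Trilinear gather from ``vol`` (X, Y, Z, 3) at base corners + fractions."""
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    x1, y1, z1 = x0 + 1, y0 + 1, z0 + 1
    fx, fy, fz = (frac[:, i][:, None] for i in range(3))
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    return (
        vol[x0, y0, z0] * gx * gy * gz
        + vol[x1, y0, z0] * fx * gy * gz
        + vol[x0, y1, z0] * gx * fy * gz
        + vol[x0, y0, z1] * gx * gy * fz
        + vol[x1, y1, z0] * fx * fy * gz
        + vol[x1, y0, z1] * fx * gy * fz
        + vol[x0, y1, z1] * gx * fy * fz
        + vol[x1, y1, z1] * fx * fy * fz
    )


def _sample_batch(field: VelocityField4D, pos_mm: np.ndarray, t_ms: float):
    """Velocities (N, 3) at positions/time plus an in-field boolean mask.

    Out-of-field positions are sampled at the clamped boundary location and
    reported via the mask; the caller applies the out-of-field policy.
    """
    shape = np.asarray(field.grid_shape)
    u = (pos_mm - field.origin_mm) / field.voxel_size_mm
    inside = np.all((u >= 0.0) & (u <= shape - 1), axis=-1)
    u = np.clip(u, 0.0, shape - 1)
    i0 = np.minimum(u.astype(np.intp), shape - 2)
    frac = u - i0
    k0, k1, w = _time_weights(field, t_ms)
    v = _gather_trilinear(field.data[k0], i0, frac)
    if w != 0.0:
        v = (1.0 - w) * v + w * _gather_trilinear(field.data[k1], i0, frac)
    return v, inside


def sample_velocity(field: VelocityField4D, position_mm, t_ms: float) -> np.ndarray:
    """Interpolated velocity (m/s) at one world position and time.

    Trilinear in space, linear in time, periodic over the cycle.  Raises
    :class:`OutOfFieldError` outside the grid's world extent.
    """
    pos = np.atleast_2d(np.asarray(position_mm, dtype=float))
    v, inside = _sample_batch(field, pos, float(t_ms))
    if not inside.all():
        raise OutOfFieldError(f"position {position_mm} outside field extent at t={t_ms} ms")
    return v[0]


# ---------------------------------------------------------------------------
# integration


@dataclass
class PathlineLeg:
    """One integration leg for all seeds (times shared, positions per seed)."""

    times_ms: np.ndarray  # (S,)
    positions_mm: np.ndarray  # (N, S, 3)
    velocities_m_s: np.ndarray  # (N, S, 3)
    exited: np.ndarray  # (N,) bool

    @property
    def endpoints_mm(self) -> np.ndarray:
        return self.positions_mm[:, -1, :]


def _integrate(field, seeds_mm, t0_ms, t1_ms, config: TraceConfig) -> PathlineLeg:
    seeds = np.atleast_2d(np.asarray(seeds_mm, dtype=float))
    n = seeds.shape[0]
    span = t1_ms - t0_ms
    h_step = np.sign(span) * field.dt_ms / config.substeps_per_frame if span else 0.0
    n_steps = int(round(abs(span) / (field.dt_ms / config.substeps_per_frame)))
    if n_steps == 0:
        v, inside = _sample_batch(field, seeds, t0_ms)
        if not inside.all():
            raise OutOfFieldError("seed outside field extent")
        return PathlineLeg(
            times_ms=np.array([t0_ms]),
            positions_mm=seeds[:, None, :].copy(),
            velocities_m_s=v[:, None, :],
            exited=np.zeros(n, dtype=bool),
        )
    h_step = span / n_steps  # exact span division; equals dt/substeps up to fp

    _, inside = _sample_batch(field, seeds, t0_ms)
    if not inside.all():
        bad = np.flatnonzero(~inside)
        raise OutOfFieldError(f"{bad.size} seed(s) outside field extent, first: {seeds[bad[0]]}")

    stored = sorted(set(range(0, n_steps + 1, config.store_stride)) | {n_steps})
    s_total = len(stored)
    positions = np.empty((n, s_total, 3))
    velocities = np.empty((n, s_total, 3))
    times = np.empty(s_total)
    store_map = {step: j for j, step in enumerate(stored)}

    x = seeds.copy()
    active = np.ones(n, dtype=bool)
    exited = np.zeros(n, dtype=bool)

    def record(step, t, vel):
        j = store_map[step]
        times[j] = t
        positions[:, j, :] = x
        velocities[:, j, :] = vel

    v0, _ = _sample_batch(field, x, t0_ms)
    if 0 in store_map:
        record(0, t0_ms, v0)

    for step in range(1, n_steps + 1):
        t = t0_ms + (step - 1) * h_step
        if config.integrator == "rk4":
            k1, in1 = _sample_batch(field, x, t)
            k2, in2 = _sample_batch(field, x + 0.5 * h_step * k1, t + 0.5 * h_step)
            k3, in3 = _sample_batch(field, x + 0.5 * h_step * k2, t + 0.5 * h_step)
            k4, in4 = _sample_batch(field, x + h_step * k3, t + h_step)
            dx = (h_step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            ok = in1 & in2 & in3 & in4
        else:  # euler
            k1, in1 = _sample_batch(field, x, t)
            dx = h_step * k1
            ok = in1
        x_new = x + dx
        _, in_end = _sample_batch(field, x_new, t + h_step)
        ok &= in_end
        if not np.all(np.isfinite(dx[active])):
            bad = np.flatnonzero(active & ~np.all(np.isfinite(dx), axis=-1))
            raise LVFlowError(
                f"non-finite velocity during integration at t={t + h_step:.3f} ms "
                f"(pathline index {bad[0]})"
            )
        newly_out = active & ~ok
        exited |= newly_out
        active &= ok
        x = np.where(active[:, None], x_new, x)  # freeze policy: hold position
        if step in store_map:
            vel, _ = _sample_batch(field, x, t + h_step)
            record(step, t + h_step, vel)

    if config.out_of_field_policy == "drop":
        positions[exited] = np.nan
        velocities[exited] = np.nan
    return PathlineLeg(times_ms=times, positions_mm=positions,
                       velocities_m_s=velocities, exited=exited)


def trace_pathline(field, seed_mm, t_start_ms, t_end_ms,
                   config: TraceConfig = TraceConfig()) -> PathlineLeg:
    """Trace a single seed from ``t_start`` to ``t_end`` (backward if earlier).

    Returns a single-seed :class:`PathlineLeg` (positions shaped ``(1, S, 3)``).
    """
    return _integrate(field, np.atleast_2d(seed_mm), t_start_ms, t_end_ms, config)


# ---------------------------------------------------------------------------
# pathline containers


class Pathline:
    """Read-only view of one trajectory in a :class:`PathlineSet`."""

    def __init__(self, parent: "PathlineSet", i: int):
        self._p = parent
        self._i = i

    @property
    def seed_voxel(self):
        return tuple(self._p.seeds_vox[self._i])

    @property
    def seed_position_mm(self):
        return self._p.seed_positions_mm[self._i]

    @property
    def forward_positions_mm(self):
        return self._p.forward.positions_mm[self._i]

    @property
    def backward_positions_mm(self):
        return self._p.backward.positions_mm[self._i]

    @property
    def forward_velocities_m_s(self):
        return self._p.forward.velocities_m_s[self._i]

    @property
    def backward_velocities_m_s(self):
        return self._p.backward.velocities_m_s[self._i]

    @property
    def forward_exit(self) -> bool:
        return bool(self._p.forward.exited[self._i])

    @property
    def backward_exit(self) -> bool:
        return bool(self._p.backward.exited[self._i])

    @property
    def parcel_volume_ml(self) -> float:
        return self._p.parcel_volume_ml

    def full_trajectory_mm(self) -> np.ndarray:
        """Positions from the preceding ES through ED to the following ES."""
        back = self.backward_positions_mm[::-1]  # ES_prev ... ED
        return np.concatenate([back, self.forward_positions_mm[1:]], axis=0)


@dataclass
class PathlineSet:
    """All pathlines of one dataset (one per EDV foreground voxel)."""

    seeds_vox: np.ndarray  # (N, 3) int
    seed_positions_mm: np.ndarray  # (N, 3)
    forward: PathlineLeg  # times increase from ED to following ES
    backward: PathlineLeg  # times decrease from ED to preceding ES
    parcel_volume_ml: float
    meta: AcquisitionMeta

    def __len__(self) -> int:
        return self.seeds_vox.shape[0]

    def __getitem__(self, i: int) -> Pathline:
        return Pathline(self, i)

    @property
    def edv_volume_ml(self) -> float:
        return len(self) * self.parcel_volume_ml

    @property
    def ed_velocities_m_s(self) -> np.ndarray:
        """Velocity of every parcel at exactly the ED time (seed instant)."""
        return self.forward.velocities_m_s[:, 0, :]


def trace_all(field: VelocityField4D, edv_mask: MaskVolume,
              config: TraceConfig = TraceConfig()) -> PathlineSet:
    """Trace one pathline per EDV voxel over the entire cardiac cycle.

    Seeds at voxel centres at the ED frame time; the forward leg runs to the
    following ES frame time and the backward leg to the preceding ES frame
    time (periodic wrap across the cycle boundary).  Each pathline represents
    one flow-grid voxel volume of blood, so total traced volume equals the
    EDV exactly.
    """
    if edv_mask.grid_shape != field.grid_shape:
        raise ShapeMismatchError(
            f"EDV mask grid {edv_mask.grid_shape} != flow grid {field.grid_shape}"
        )
    if not np.allclose(edv_mask.affine, field.affine):
        raise ShapeMismatchError("EDV mask and flow field affines disagree")
    seeds_vox = np.argwhere(edv_mask.data)
    if seeds_vox.size == 0:
        raise EmptyMaskError("EDV mask has no foreground voxels")
    seeds_mm = field.origin_mm + seeds_vox * field.voxel_size_mm

    meta = field.meta
    n, dt = field.n_frames, field.dt_ms
    t_ed = meta.ed_frame * dt
    t_es_fwd = t_ed + ((meta.es_frame - meta.ed_frame) % n) * dt
    t_es_bwd = t_ed - ((meta.ed_frame - meta.es_frame) % n) * dt

    forward = _integrate(field, seeds_mm, t_ed, t_es_fwd, config)
    backward = _integrate(field, seeds_mm, t_ed, t_es_bwd, config)
    from .io import voxel_volume_ml as _vox_ml

    return PathlineSet(
        seeds_vox=seeds_vox,
        seed_positions_mm=seeds_mm,
        forward=forward,
        backward=backward,
        parcel_volume_ml=_vox_ml(field.affine),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# persistence (HDF5 archive reused between pipeline stages)


def save_pathlines(pathlines: PathlineSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["meta_json"] = json.dumps(pathlines.meta.to_dict(), sort_keys=True)
        f.attrs["parcel_volume_ml"] = pathlines.parcel_volume_ml
        f.create_dataset("seeds_vox", data=pathlines.seeds_vox)
        f.create_dataset("seed_positions_mm", data=pathlines.seed_positions_mm)
        for name, leg in (("forward", pathlines.forward), ("backward", pathlines.backward)):
            g = f.create_group(name)
            g.create_dataset("times_ms", data=leg.times_ms)
            g.create_dataset("positions_mm", data=leg.positions_mm)
            g.create_dataset("velocities_m_s", data=leg.velocities_m_s)
            g.create_dataset("exited", data=leg.exited)
    return path


def load_pathlines(path) -> PathlineSet:
    with h5py.File(path, "r") as f:
        legs = {}
        for name in ("forward", "backward"):
            g = f[name]
            legs[name] = PathlineLeg(
                times_ms=g["times_ms"][()],
                positions_mm=g["positions_mm"][()],
                velocities_m_s=g["velocities_m_s"][()],
                exited=g["exited"][()].astype(bool),
            )
        return PathlineSet(
            seeds_vox=f["seeds_vox"][()],
            seed_positions_mm=f["seed_positions_mm"][()],
            forward=legs["forward"],
            backward=legs["backward"],
            parcel_volume_ml=float(f.attrs["parcel_volume_ml"]),
            meta=AcquisitionMeta.from_dict(json.loads(f.attrs["meta_json"])),
        )
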