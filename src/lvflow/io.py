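"""Readers and writers for the on-disk artifacts of the flow pipeline.

Velocity data travel as three per-direction 4D NIfTI volumes (one per velocity
component, stored in cm/s — the native scale of a phase-contrast acquisition
with a stated VENC) plus a JSON metadata sidecar.  Masks and ground-truth label
volumes are 3D NIfTI.  Pathlines are exported as VTK XML PolyData (``.vtp``)
polylines for inspection in ParaView or similar.  Result tables are plain CSV.

All in-memory computation is SI (mm for world positions, m/s for velocities,
ms for time); unit conversions happen only here, at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import nibabel as nib
import numpy as np

from .exceptions import (
    EmptyMaskError,
    LVFlowError,
    MissingSidecarKeyError,
    ShapeMismatchError,
)

log = logging.getLogger(__name__)

#: axis order of velocity components everywhere in the package
AXES = ("x", "y", "z")

#: required sidecar keys (values the pipeline cannot run without)
REQUIRED_SIDECAR_KEYS = ("venc_cm_s", "dt_ms", "ed_frame", "es_frame")

CM_PER_M = 100.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one 4D-flow dataset.

    Parameters mirror the JSON sidecar: VENC and timing of the phase-contrast
    acquisition, cardiac phase indices, and subject bookkeeping.
    """

    venc_cm_s: float
    dt_ms: float
    voxel_size_mm: tuple[float, float, float]
    cycle_length_ms: float
    ed_frame: int
    es_frame: int
    heart_rate_bpm: float | None = None
    subject_id: str = ""
    condition: str = "rest"

    def __post_init__(self):
        if self.venc_cm_s <= 0:
            raise ValueError("venc_cm_s must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm components must be positive")
        if self.dt_ms <= 0 or self.cycle_length_ms <= 0:
            raise ValueError("dt_ms and cycle_length_ms must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.cycle_length_ms / self.dt_ms))

    def validate_timing(self, n_frames: int) -> None:
        """dt x (actual frame count) must equal the cycle length within one dt."""
        if abs(self.dt_ms * n_frames - self.cycle_length_ms) > self.dt_ms:
            raise ValueError(
                f"dt_ms * n_frames = {self.dt_ms * n_frames} disagrees with "
                f"cycle_length_ms = {self.cycle_length_ms} by more than one dt"
            )

    def to_dict(self) -> dict:
        return {
            "venc_cm_s": self.venc_cm_s,
            "dt_ms": self.dt_ms,
            "voxel_size_mm": list(self.voxel_size_mm),
            "cycle_length_ms": self.cycle_length_ms,
            "ed_frame": self.ed_frame,
            "es_frame": self.es_frame,
            "heart_rate_bpm": self.heart_rate_bpm,
            "subject_id": self.subject_id,
            "condition": self.condition,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in d]
        if missing:
            raise MissingSidecarKeyError(missing)
        voxel = tuple(float(v) for v in d.get("voxel_size_mm", (1.0, 1.0, 1.0)))
        return cls(
            venc_cm_s=float(d["venc_cm_s"]),
            dt_ms=float(d["dt_ms"]),
            voxel_size_mm=voxel,
            cycle_length_ms=float(d.get("cycle_length_ms", 0.0) or 0.0)
            or float(d["dt_ms"]) * int(d.get("n_frames", 0)),
            ed_frame=int(d["ed_frame"]),
            es_frame=int(d["es_frame"]),
            heart_rate_bpm=(
                float(d["heart_rate_bpm"]) if d.get("heart_rate_bpm") is not None else None
            ),
            subject_id=str(d.get("subject_id", "")),
            condition=str(d.get("condition", "rest")),
        )


@dataclass
class VelocityField4D:
    """A time-resolved 3D velocity vector field on a regular grid.

    ``data`` has shape ``(T, X, Y, Z, 3)`` in m/s; the last axis orders the
    x, y, z velocity components.  ``affine`` maps 0-based voxel indices to
    world millimetres; a voxel's world position is its centre.  The field is
    periodic in time: frame ``T`` is frame ``0``.
    """

    data: np.ndarray
    affine: np.ndarray
    meta: AcquisitionMeta
    wrap_flag_count: int = 0

    def __post_init__(self):
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise ShapeMismatchError(
                f"velocity data must have shape (T, X, Y, Z, 3), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("velocity field contains non-finite values")
        self.meta.validate_timing(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.asarray(self.meta.voxel_size_mm, dtype=float)

    @property
    def dt_ms(self) -> float:
        return self.meta.dt_ms

    @property
    def cycle_length_ms(self) -> float:
        return self.n_frames * self.meta.dt_ms

    @property
    def origin_mm(self) -> np.ndarray:
        return np.asarray(self.affine[:3, 3], dtype=float)

    def frame_time_ms(self, k: int) -> float:
        return k * self.meta.dt_ms

    def world_extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corners of the interpolable world region (voxel centres)."""
        lo = self.origin_mm
        hi = lo + (np.array(self.grid_shape) - 1) * self.voxel_size_mm
        return lo, hi

    def count_wrap_flags(self) -> int:
        """Number of samples whose speed on any axis exceeds VENC."""
        venc_m_s = self.meta.venc_cm_s / CM_PER_M
        return int(np.count_nonzero(np.abs(self.data) > venc_m_s + 1e-12))


@dataclass
class MaskVolume:
    """A binary segmentation (LV blood pool at ED or ES) on its own grid.

    A segmented mask must have at least one foreground voxel;
    ``allow_empty`` admits the degenerate constructed reference masks of
    fully-ejected phantoms (e.g. a target decomposition that is 100 %
    Direct flow leaves an empty end-systolic reference set).
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "EDV"
    allow_empty: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask data must be strictly binary")
        self.data = self.data.astype(bool)
        if not self.data.any() and not self.allow_empty:
            raise EmptyMaskError(f"{self.label} mask has no foreground voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3]).astype(float)

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.affine)

    def volume_ml(self) -> float:
        return int(self.data.sum()) * self.voxel_volume_ml


def voxel_volume_ml(affine: np.ndarray) -> float:
    """Voxel volume from an index-to-mm affine, in mL.

    For orthogonal affines (the usual case) this is the exact product of the
    per-axis scales, avoiding the tiny float drift of a determinant.
    """
    lin = np.asarray(affine)[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if not off_diag.any():
        vol_mm3 = float(np.prod(np.abs(np.diag(lin))))
    else:
        vol_mm3 = float(abs(np.linalg.det(lin)))
    return vol_mm3 / 1000.0


def default_affine(voxel_size_mm) -> np.ndarray:
    """Axis-aligned affine: voxel index i -> i * voxel_size mm, origin 0."""
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_size_mm
    return a


# ---------------------------------------------------------------------------
# velocity volumes


def write_velocity(field: VelocityField4D, out_dir) -> dict[str, Path]:
    """Write a field as three per-direction 4D NIfTI volumes plus JSON sidecar.

    Velocities are stored in cm/s.  Returns the mapping of artifact name to
    path (keys ``vel_x``, ``vel_y``, ``vel_z``, ``sidecar``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, ax in enumerate(AXES):
        # (T, X, Y, Z) -> (X, Y, Z, T) as NIfTI expects; convert in float64
        vol = np.moveaxis(field.data[..., i], 0, -1).astype(np.float64) * CM_PER_M
        img = nib.Nifti1Image(np.ascontiguousarray(vol), field.affine)
        p = out_dir / f"vel_{ax}.nii.gz"
        nib.save(img, p)
        paths[f"vel_{ax}"] = p
    sidecar = out_dir / "flow_meta.json"
    sidecar.write_text(json.dumps(field.meta.to_dict(), indent=2, sort_keys=True))
    paths["sidecar"] = sidecar
    return paths


def read_velocity(paths, sidecar) -> VelocityField4D:
    """Read three per-direction 4D volumes + sidecar into a VelocityField4D.

    ``paths`` is an (x, y, z)-ordered sequence of file paths.  Stored values
    are cm/s and converted to internal m/s.  Velocity magnitudes exceeding the
    sidecar VENC are counted as wrap flags (logged, never silently accepted).
    """
    meta = AcquisitionMeta.from_dict(json.loads(Path(sidecar).read_text()))
    vols, affine = [], None
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim != 4:
            raise ShapeMismatchError(f"{p}: expected a 4D volume, got shape {arr.shape}")
        vols.append(arr)
        if affine is None:
            affine = img.affine
    if not (vols[0].shape == vols[1].shape == vols[2].shape):
        raise ShapeMismatchError(
            f"velocity components disagree in shape: {[v.shape for v in vols]}"
        )
    # (X, Y, Z, T) x 3 -> (T, X, Y, Z, 3), cm/s -> m/s
    data = np.stack([np.moveaxis(v, -1, 0) for v in vols], axis=-1) / CM_PER_M
    field = VelocityField4D(data=data, affine=affine, meta=meta)
    n_wrap = field.count_wrap_flags()
    if n_wrap:
        log.warning("%d velocity samples exceed VENC=%.1f cm/s (possible wrap)",
                    n_wrap, meta.venc_cm_s)
    field.wrap_flag_count = n_wrap
    return field


# ---------------------------------------------------------------------------
# masks and label volumes


def write_mask(mask: MaskVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, path)
    return path


def read_mask(path, label: str = "EDV") -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(data=np.asarray(img.dataobj) > 0, affine=img.affine, label=label)


def write_labels(labels: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write an integer-coded per-voxel component label volume (-1 = outside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), path)
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


# ---------------------------------------------------------------------------
# pathline geometry export (VTK XML PolyData)


def export_pathlines(pathlines, labels, out) -> Path:
    """Export traced pathlines as a VTK XML PolyData (.vtp) polyline file.

    One polyline per pathline (backward leg reversed, then forward leg, i.e.
    running from the preceding end-systole through ED to the following
    end-systole), positions in world mm, with an integer ``component`` cell
    attribute per polyline.  The ascii .vtp opens directly in ParaView.
    """
    labels = np.asarray(labels)
    n = len(pathlines)
    if labels.shape[0] != n:
        raise LVFlowError(
            f"label array length {labels.shape[0]} != pathline count {n}"
        )
    if n == 0:
        log.warning("exporting an empty pathline set to %s", out)

    points, connectivity, offsets = [], [], []
    offset = 0
    for i in range(n):
        pl = pathlines[i]
        traj = pl.full_trajectory_mm()
        if traj.shape[0] < 2:
            raise LVFlowError(f"pathline {i} has fewer than 2 stored positions")
        points.append(traj)
        connectivity.extend(range(offset, offset + traj.shape[0]))
        offset += traj.shape[0]
        offsets.append(offset)
    pts = np.concatenate(points, axis=0) if points else np.zeros((0, 3))

    def _ascii(a, fmt="%.6g"):
        return " ".join(fmt % v for v in np.asarray(a).ravel())

    root = ElementTree.Element(
        "VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian"
    )
    poly = ElementTree.SubElement(root, "PolyData")
    piece = ElementTree.SubElement(
        poly, "Piece",
        NumberOfPoints=str(pts.shape[0]), NumberOfVerts="0",
        NumberOfLines=str(n), NumberOfStrips="0", NumberOfPolys="0",
    )
    pts_el = ElementTree.SubElement(piece, "Points")
    da = ElementTree.SubElement(
        pts_el, "DataArray", type="Float32", NumberOfComponents="3", format="ascii"
    )
    da.text = _ascii(pts.astype(np.float32))
    lines_el = ElementTree.SubElement(piece, "Lines")
    conn = ElementTree.SubElement(
        lines_el, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = " ".join(str(c) for c in connectivity)
    offs = ElementTree.SubElement(
        lines_el, "DataArray", type="Int64", Name="offsets", format="ascii"
    )
    offs.text = " ".join(str(o) for o in offsets)
    cell = ElementTree.SubElement(piece, "CellData", Scalars="component")
    lab = ElementTree.SubElement(
        cell, "DataArray", type="Int32", Name="component", format="ascii"
    )
    lab.text = " ".join(str(int(v)) for v in labels)

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    ElementTree.ElementTree(root).write(out, xml_declaration=True, encoding="utf-8")
    return out


# ---------------------------------------------------------------------------
# result tables

VOLUMETRICS_COLUMNS = [
    "subject_id", "condition", "edv_ml", "esv_ml", "sv_ml", "ef_pct", "co_l_min",
]
COMPONENT_COLUMNS = [
    "subject_id", "condition",
    "df_pct", "ri_pct", "def_pct", "rv_pct",
    "df_ml", "ri_ml", "def_ml", "rv_ml",
    "ke_ed_df_uj_ml", "ke_ed_ri_uj_ml", "ke_ed_def_uj_ml", "ke_ed_rv_uj_ml",
    "qc_discrepancy_pct", "qc_excluded",
]


def write_results(results, out_dir) -> dict[str, Path]:
    """Write volumetrics and component-fraction/KE CSVs for a set of datasets.

    ``results`` is an iterable of :class:`~lvflow.pipeline.ComponentResult`.
    Returns paths keyed ``volumetrics`` and ``components``.
    """
    import pandas as pd

    results = list(results)
    if not results:
        raise LVFlowError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vol_rows, comp_rows = [], []
    for r in results:
        v = r.volumes
        vol_rows.append([r.subject_id, r.condition, v.edv_ml, v.esv_ml, v.sv_ml,
                         v.ef_pct, v.co_l_min])
        f = r.fractions
        ke = r.ke_ed_uj_ml
        comp_rows.append(
            [r.subject_id, r.condition]
            + list(np.round(f.fractions_pct, 10))
            + list(np.round(f.volumes_ml, 10))
            + [ke.get(c) for c in ("DF", "RI", "DEF", "RV")]
            + [r.qc.discrepancy_pct, r.qc.excluded]
        )
    paths = {}
    vol = pd.DataFrame(vol_rows, columns=VOLUMETRICS_COLUMNS)
    comp = pd.DataFrame(comp_rows, columns=COMPONENT_COLUMNS)
    paths["volumetrics"] = out_dir / "volumetrics.csv"
    paths["components"] = out_dir / "components.csv"
    vol.to_csv(paths["volumetrics"], index=False)
    comp.to_csv(paths["components"], index=False)
    return paths
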