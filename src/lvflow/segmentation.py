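"""Mask resampling, ventricular volumetrics, and data quality control.

Segmentations are drawn on the (higher-resolution) morphological images and
resampled to the flow grid by nearest-neighbour sampling at each flow-voxel
centre, which preserves binarity.  Volumes are exact integer voxel counts
times the voxel volume.  The quality-control rule mirrors the study design:
a dataset whose LV inflow and outflow volumes disagree by more than 15 % is
excluded from group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DisjointGridsError, EmptyMaskError
from .io import MaskVolume, VelocityField4D

log = logging.getLogger(__name__)

#: inflow-outflow discrepancy above which a dataset is excluded, percent
QC_DISCREPANCY_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class VentricularVolumes:
    """Global volumetrics: EDV, ESV, SV = EDV - ESV, EF, and CO if HR known."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    co_l_min: float | None = None


@dataclass(frozen=True)
class QCReport:
    """Inflow-outflow consistency check plus tracing/acquisition tallies."""

    inflow_ml: float
    outflow_ml: float
    discrepancy_pct: float
    excluded: bool
    threshold_pct: float = QC_DISCREPANCY_THRESHOLD_PCT
    wrap_flag_count: int = 0
    out_of_field_pathlines: int = 0


def resample_mask(mask: MaskVolume, target: VelocityField4D) -> MaskVolume:
    """Resample a mask onto the flow grid (nearest neighbour at voxel centres).

    Raises :class:`DisjointGridsError` when the two grids share no world
    extent at all.
    """
    tgt_shape = np.asarray(target.grid_shape)
    # world coordinates of every flow-voxel centre
    idx = np.indices(tuple(tgt_shape)).reshape(3, -1).T
    world = target.origin_mm + idx * target.voxel_size_mm

    src_affine_inv = np.linalg.inv(mask.affine)
    src = world @ src_affine_inv[:3, :3].T + src_affine_inv[:3, 3]
    nearest = np.floor(src + 0.5).astype(np.intp)
    shape = np.asarray(mask.grid_shape)
    in_src = np.all((nearest >= 0) & (nearest < shape), axis=-1)
    if not in_src.any():
        raise DisjointGridsError("mask and flow grid share no world extent")
    out = np.zeros(tgt_shape, dtype=bool)
    vals = np.zeros(idx.shape[0], dtype=bool)
    ig = nearest[in_src]
    vals[in_src] = mask.data[ig[:, 0], ig[:, 1], ig[:, 2]]
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = vals
    return MaskVolume(data=out, affine=target.affine.copy(), label=mask.label)


def ventricular_volumes(edv_mask: MaskVolume, esv_mask: MaskVolume,
                        heart_rate_bpm: float | None = None) -> VentricularVolumes:
    """EDV/ESV/SV/EF (and CO when heart rate is given) from binary masks.

    Volumes are foreground voxel counts times the voxel volume, so repeated
    runs are bit-reproducible.  An ESV >= EDV is physiologically abnormal and
    logged, but still computed.
    """
    if not edv_mask.data.any():
        raise EmptyMaskError("EDV mask is empty")
    edv = edv_mask.volume_ml()
    esv = esv_mask.volume_ml()
    if esv >= edv:
        log.warning("ESV (%.1f mL) >= EDV (%.1f mL): physiologically abnormal", esv, edv)
    return volumetrics_from_volumes(edv, esv, heart_rate_bpm)


def volumetrics_from_volumes(edv_ml: float, esv_ml: float,
                             heart_rate_bpm: float | None = None) -> VentricularVolumes:
    """The volumetric identities SV = EDV - ESV, EF = 100 SV/EDV, CO = SV HR."""
    sv = edv_ml - esv_ml
    ef = 100.0 * sv / edv_ml if edv_ml > 0 else 0.0
    co = sv * heart_rate_bpm / 1000.0 if heart_rate_bpm is not None else None
    return VentricularVolumes(edv_ml=edv_ml, esv_ml=esv_ml, sv_ml=sv, ef_pct=ef,
                              co_l_min=co)


def qc_inflow_outflow(fractions, threshold_pct: float = QC_DISCREPANCY_THRESHOLD_PCT,
                      wrap_flag_count: int = 0,
                      out_of_field_pathlines: int = 0) -> QCReport:
    """Inflow-outflow consistency from the component decomposition.

    Inflow is the blood that entered during diastole (DF + RI volumes) and
    outflow the blood ejected during systole (DF + DEF volumes); the
    discrepancy is 100 |inflow - outflow| / max(inflow, outflow).  Exceeding
    the threshold marks the dataset excluded.
    """
    from .classifier import Component

    inflow = fractions.volume_of(Component.DF) + fractions.volume_of(Component.RI)
    outflow = fractions.volume_of(Component.DF) + fractions.volume_of(Component.DEF)
    denom = max(inflow, outflow)
    if denom == 0:
        log.warning("zero inflow and outflow; discrepancy defined as 0")
        disc = 0.0
    else:
        disc = 100.0 * abs(inflow - outflow) / denom
    return QCReport(
        inflow_ml=inflow,
        outflow_ml=outflow,
        discrepancy_pct=disc,
        excluded=disc > threshold_pct,
        threshold_pct=threshold_pct,
        wrap_flag_count=wrap_flag_count,
        out_of_field_pathlines=out_of_field_pathlines,
    )
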