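"""Four-way functional decomposition of the end-diastolic blood volume.

Each pathline's route decides its component: whether its backward-leg
endpoint lies outside the preceding end-systolic blood pool (it *entered*
the LV during diastole) and whether its forward-leg endpoint lies outside
the following end-systolic blood pool (it was *ejected* during systole).
The 2x2 truth table gives the four components of the standard
intraventricular flow decomposition:

================  =================  ====================
entered diastole  ejected systole    component
================  =================  ====================
yes               yes                Direct flow (DF)
yes               no                 Retained inflow (RI)
no                yes                Delayed ejection flow (DEF)
no                no                 Residual volume (RV)
================  =================  ====================
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .exceptions import LVFlowError
from .io import MaskVolume
from .tracer import PathlineSet


class Component(IntEnum):
    DF = 0
    RI = 1
    DEF = 2
    RV = 3


def classify_pathline(entered_in_diastole: bool, ejected_in_systole: bool) -> Component:
    """Map the (entered, ejected) route booleans to a flow component.

    Total and exclusive: the four input combinations yield the four distinct
    components.
    """
    if entered_in_diastole:
        return Component.DF if ejected_in_systole else Component.RI
    return Component.DEF if ejected_in_systole else Component.RV


def _membership(mask: MaskVolume, points_mm: np.ndarray) -> np.ndarray:
    """Nearest-voxel foreground membership of world points (NaN -> outside).

    The nearest voxel is found by half-up rounding per axis of the fractional
    voxel coordinate, so points exactly on a voxel-boundary midplane resolve
    deterministically toward the higher index.
    """
    pts = np.atleast_2d(points_mm)
    origin = mask.affine[:3, 3]
    u = (pts - origin) / mask.voxel_size_mm
    with np.errstate(invalid="ignore"):
        idx = np.floor(u + 0.5).astype(np.intp)  # half-up per axis
    shape = np.asarray(mask.grid_shape)
    finite = np.all(np.isfinite(u), axis=-1)
    in_grid = finite & np.all((idx >= 0) & (idx < shape), axis=-1)
    member = np.zeros(pts.shape[0], dtype=bool)
    if in_grid.any():
        ig = idx[in_grid]
        member[in_grid] = mask.data[ig[:, 0], ig[:, 1], ig[:, 2]]
    return member


def endpoint_membership(pathline, esv_forward: MaskVolume, esv_backward: MaskVolume):
    """(entered_in_diastole, ejected_in_systole) for a single pathline.

    An endpoint that left the field of view (exit flag) counts as outside the
    end-systolic pool — the physical case of blood that exited through the
    aorta beyond the imaged volume; such pathlines are tallied in QC.
    """
    fwd_end = pathline.forward_positions_mm[-1]
    bwd_end = pathline.backward_positions_mm[-1]
    ejected = pathline.forward_exit or not _membership(esv_forward, fwd_end)[0]
    entered = pathline.backward_exit or not _membership(esv_backward, bwd_end)[0]
    return bool(entered), bool(ejected)


@dataclass
class ComponentFractions:
    """Component volumes and their shares of the end-diastolic volume."""

    counts: np.ndarray  # (4,) pathlines per component, DF/RI/DEF/RV order
    volumes_ml: np.ndarray  # (4,)
    fractions_pct: np.ndarray  # (4,) percentages of EDV
    edv_ml: float
    labels: np.ndarray  # (N,) per-pathline Component codes

    def as_dict(self) -> dict[str, float]:
        return {c.name: float(self.fractions_pct[c]) for c in Component}

    def volume_of(self, component: Component) -> float:
        return float(self.volumes_ml[int(component)])


def component_labels(pathlines: PathlineSet, esv_forward: MaskVolume,
                     esv_backward: MaskVolume) -> np.ndarray:
    """Vectorized per-pathline component codes for a whole PathlineSet."""
    fwd_end = pathlines.forward.endpoints_mm
    bwd_end = pathlines.backward.endpoints_mm
    ejected = pathlines.forward.exited | ~_membership(esv_forward, fwd_end)
    entered = pathlines.backward.exited | ~_membership(esv_backward, bwd_end)
    labels = np.where(
        entered,
        np.where(ejected, Component.DF, Component.RI),
        np.where(ejected, Component.DEF, Component.RV),
    )
    return labels.astype(np.int16)


def component_fractions(pathlines: PathlineSet, esv_forward: MaskVolume,
                        esv_backward: MaskVolume) -> ComponentFractions:
    """Classify every pathline and aggregate volumes and EDV percentages.

    Volumes are pathline counts times the parcel (voxel) volume, so the four
    components partition the EDV exactly and fractions sum to 100 %.
    """
    if len(pathlines) == 0:
        raise LVFlowError("empty PathlineSet")
    labels = component_labels(pathlines, esv_forward, esv_backward)
    counts = np.bincount(labels, minlength=4)
    volumes = counts * pathlines.parcel_volume_ml
    edv = pathlines.edv_volume_ml
    return ComponentFractions(
        counts=counts,
        volumes_ml=volumes,
        fractions_pct=100.0 * counts / len(pathlines),
        edv_ml=edv,
        labels=labels,
    )


def label_agreement(labels: np.ndarray, pathlines: PathlineSet,
                    truth_labels: np.ndarray) -> float:
    """Fraction of pathlines whose label matches the phantom ground truth.

    ``truth_labels`` is the integer-coded label volume of a PhantomDataset
    (-1 outside the EDV); pathline seed voxels index into it.
    """
    s = pathlines.seeds_vox
    truth = truth_labels[s[:, 0], s[:, 1], s[:, 2]]
    return float(np.mean(labels == truth))
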