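"""Kinetic energy of the flow components.

Each pathline represents a parcel of blood of volume V (one flow-grid voxel)
moving with the interpolated velocity v(t) along its trajectory; its kinetic
energy is

    KE(t) = 1/2 * rho * V * |v(t)|^2,      rho = 1060 kg/m^3

reported in microjoules (and per-millilitre of component volume, the
scale used for the end-diastolic summary).  Speeds are taken from the
velocities stored with the trace — the same interpolated values that moved
the parcel — not re-sampled from the raw grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import Component
from .exceptions import LVFlowError
from .tracer import PathlineSet

log = logging.getLogger(__name__)

#: density of blood, kg/m^3
RHO_BLOOD = 1060.0

ML_TO_M3 = 1e-6
J_TO_UJ = 1e6


def kinetic_energy_uj(volume_ml, speed_m_s, rho: float = RHO_BLOOD):
    """KE = 1/2 rho V |v|^2 in microjoules (V in mL, v in m/s)."""
    return 0.5 * rho * (np.asarray(volume_ml) * ML_TO_M3) * np.asarray(speed_m_s) ** 2 * J_TO_UJ


@dataclass
class KECurve:
    """Kinetic energy of one component sampled over (part of) the cycle."""

    component: Component
    times_ms: np.ndarray
    ke_total_uj: np.ndarray
    ke_per_ml_uj: np.ndarray
    volume_ml: float
    ke_per_ml_at_ed_uj: float


def _assembled_times_speeds2(pathline):
    """Times and squared speeds from the preceding ES through ED to the next ES."""
    t_back = pathline._p.backward.times_ms[::-1]
    t_fwd = pathline._p.forward.times_ms
    v_back = pathline.backward_velocities_m_s[::-1]
    v_fwd = pathline.forward_velocities_m_s
    times = np.concatenate([t_back, t_fwd[1:]])
    vel = np.concatenate([v_back, v_fwd[1:]], axis=0)
    return times, np.sum(vel**2, axis=-1)


def pathline_ke(pathline, rho: float = RHO_BLOOD):
    """KE time series (times_ms, ke_uj) of one pathline over the full cycle.

    Ordered from the preceding end-systole through ED to the following
    end-systole (the duplicated ED sample of the two legs appears once).
    """
    if pathline.forward_velocities_m_s is None:
        raise LVFlowError("pathline has no stored velocities")
    times, sp2 = _assembled_times_speeds2(pathline)
    ke = 0.5 * rho * (pathline.parcel_volume_ml * ML_TO_M3) * sp2 * J_TO_UJ
    return times, ke


def _leg_speeds2(leg) -> np.ndarray:
    return np.sum(leg.velocities_m_s**2, axis=-1)


def component_ke(pathlines: PathlineSet, labels: np.ndarray,
                 rho: float = RHO_BLOOD) -> dict[Component, KECurve]:
    """Per-component KE over the whole traced cycle plus the ED summary.

    Returns a mapping Component -> KECurve; components with no pathlines are
    absent from the mapping (with a warning), not reported as zero.
    The ED value uses the velocities at exactly the ED frame time (the shared
    first sample of both legs).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(pathlines):
        raise LVFlowError("labels do not cover all pathlines")
    v_parcel = pathlines.parcel_volume_ml
    # assembled cycle: backward leg reversed, then forward leg minus duplicate ED
    times = np.concatenate([pathlines.backward.times_ms[::-1],
                            pathlines.forward.times_ms[1:]])
    sp2 = np.concatenate(
        [_leg_speeds2(pathlines.backward)[:, ::-1], _leg_speeds2(pathlines.forward)[:, 1:]],
        axis=1,
    )  # (N, S)
    sp2_ed = np.sum(pathlines.ed_velocities_m_s**2, axis=-1)

    out: dict[Component, KECurve] = {}
    for comp in Component:
        sel = labels == int(comp)
        n = int(np.count_nonzero(sel))
        if n == 0:
            log.warning("component %s is empty; KE curve absent", comp.name)
            continue
        vol_ml = n * v_parcel
        ke_total = 0.5 * rho * (v_parcel * ML_TO_M3) * sp2[sel].sum(axis=0) * J_TO_UJ
        ke_ed_total = 0.5 * rho * (v_parcel * ML_TO_M3) * sp2_ed[sel].sum() * J_TO_UJ
        out[comp] = KECurve(
            component=comp,
            times_ms=times,
            ke_total_uj=ke_total,
            ke_per_ml_uj=ke_total / vol_ml,
            volume_ml=vol_ml,
            ke_per_ml_at_ed_uj=float(ke_ed_total / vol_ml),
        )
    return out


def ke_per_ml_at_ed(pathlines: PathlineSet, labels: np.ndarray,
                    rho: float = RHO_BLOOD) -> dict[str, float]:
    """End-diastolic KE/mL (uJ/mL) per component name, the Table-style summary."""
    return {c.name: curve.ke_per_ml_at_ed_uj
            for c, curve in component_ke(pathlines, labels, rho=rho).items()}


def diastolic_ke_curves(pathlines: PathlineSet, labels: np.ndarray,
                        rho: float = RHO_BLOOD) -> dict[Component, KECurve]:
    """Per-component KE/mL over diastole (preceding ES up to ED, time-forward).

    The final sample of each curve is that component's KE/mL at ED.
    """
    labels = np.asarray(labels)
    times = pathlines.backward.times_ms[::-1]  # ascending: ES_prev ... ED
    sp2 = _leg_speeds2(pathlines.backward)[:, ::-1]
    v_parcel = pathlines.parcel_volume_ml
    out: dict[Component, KECurve] = {}
    for comp in Component:
        sel = labels == int(comp)
        n = int(np.count_nonzero(sel))
        if n == 0:
            log.warning("component %s is empty; diastolic curve absent", comp.name)
            continue
        vol_ml = n * v_parcel
        ke_total = 0.5 * rho * (v_parcel * ML_TO_M3) * sp2[sel].sum(axis=0) * J_TO_UJ
        out[comp] = KECurve(
            component=comp,
            times_ms=times,
            ke_total_uj=ke_total,
            ke_per_ml_uj=ke_total / vol_ml,
            volume_ml=vol_ml,
            ke_per_ml_at_ed_uj=float(ke_total[-1] / vol_ml),
        )
    return out
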