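"""Isometric joint torque and summed flexor/extensor aggregates.

Torque assumes maximum isometric contraction at every pose:

    tau = PCSA * MA * FPUA

with PCSA in m^2, the moment arm MA in metres (signed, extensor positive)
and FPUA the maximum isometric muscle stress in N m^-2 (default 300 000,
the middle of the commonly reported 200 000--400 000 range).  No
length- or velocity-dependent force model is applied.

Summed group curves classify each strand *instantaneously* at every grid
angle: moment arms above +eps count as extensor, below -eps as flexor, so
a muscle whose predicted function switches mid-sweep (e.g. a two-joint
muscle at extreme flexion) changes group exactly at its zero crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .momentarm import MomentArmCurve

__all__ = [
    "DEFAULT_FPUA",
    "SIGN_EPS_M",
    "strand_torque",
    "torque_curve",
    "GroupCurves",
    "summed_group_curves",
    "find_peak",
    "find_sign_change",
]

DEFAULT_FPUA = 300_000.0  # N m^-2, maximum isometric muscle stress
SIGN_EPS_M = 1e-6         # |MA| below this joins neither group (avoids jitter)


def strand_torque(pcsa_m2, ma_m, fpua: float = DEFAULT_FPUA):
    """tau = PCSA * MA * FPUA (N m); sign carried by the moment arm."""
    pcsa = np.asarray(pcsa_m2, dtype=float)
    if np.any(pcsa < 0):
        raise ValueError("PCSA must be non-negative")
    out = pcsa * np.asarray(ma_m, dtype=float) * fpua
    return float(out) if np.isscalar(ma_m) and np.isscalar(pcsa_m2) else out


def torque_curve(curve: MomentArmCurve, fpua: float = DEFAULT_FPUA) -> MomentArmCurve:
    """Attach an isometric torque trace to a moment-arm curve."""
    if curve.pcsa_m2 is None:
        raise ValueError(f"curve {curve.entity!r} has no PCSA; cannot compute torque")
    return replace(
        curve,
        torque_nm=strand_torque(curve.pcsa_m2, curve.ma_m, fpua),
        fpua_nm2=fpua,
    )


@dataclass
class GroupCurves:
    """Summed extensor and flexor moment arm and torque over one sweep."""

    joint: str
    lock: str
    angles_deg: np.ndarray
    extensor_ma_m: np.ndarray
    flexor_ma_m: np.ndarray
    extensor_torque_nm: np.ndarray
    flexor_torque_nm: np.ndarray
    fpua_nm2: float

    def curve(self, group: str, quantity: str = "ma") -> MomentArmCurve:
        """View one summed trace as a MomentArmCurve (for CSV/summaries)."""
        values = {
            ("extensor", "ma"): self.extensor_ma_m,
            ("flexor", "ma"): self.flexor_ma_m,
        }[(group, "ma")]
        tau = {
            "extensor": self.extensor_torque_nm,
            "flexor": self.flexor_torque_nm,
        }[group]
        _ = quantity
        return MomentArmCurve(
            joint=self.joint,
            entity=f"summed_{group}",
            kind="group",
            lock=self.lock,
            angles_deg=self.angles_deg,
            ma_m=values,
            torque_nm=tau,
            fpua_nm2=self.fpua_nm2,
        )


def summed_group_curves(
    curves: list[MomentArmCurve],
    fpua: float = DEFAULT_FPUA,
    eps_m: float = SIGN_EPS_M,
    kind: str = "strand",
) -> GroupCurves:
    """Sum strand curves into extensor and flexor aggregates per angle.

    ``curves`` must share one joint, lock setting and angle grid;
    classification is per strand (per muscle if ``kind='muscle'``) and per
    angle.  Torque sums require a PCSA on every contributing curve.
    """
    parts = [c for c in curves if c.kind == kind]
    if not parts:
        raise ValueError(f"no curves of kind {kind!r} to sum")
    ref = parts[0]
    for c in parts[1:]:
        if c.joint != ref.joint or c.lock != ref.lock:
            raise ValueError("cannot sum curves from different sweeps")
        if not np.array_equal(c.angles_deg, ref.angles_deg):
            raise ValueError("cannot sum curves on mismatched angle grids")

    grid = ref.angles_deg
    ext_ma = np.zeros_like(grid)
    flx_ma = np.zeros_like(grid)
    ext_tau = np.zeros_like(grid)
    flx_tau = np.zeros_like(grid)
    for c in parts:
        is_ext = c.ma_m > eps_m
        is_flx = c.ma_m < -eps_m
        ext_ma += np.where(is_ext, c.ma_m, 0.0)
        flx_ma += np.where(is_flx, c.ma_m, 0.0)
        if c.pcsa_m2 is not None:
            tau = strand_torque(c.pcsa_m2, c.ma_m, fpua)
            ext_tau += np.where(is_ext, tau, 0.0)
            flx_tau += np.where(is_flx, tau, 0.0)
    return GroupCurves(
        joint=ref.joint,
        lock=ref.lock,
        angles_deg=grid,
        extensor_ma_m=ext_ma,
        flexor_ma_m=flx_ma,
        extensor_torque_nm=ext_tau,
        flexor_torque_nm=flx_tau,
        fpua_nm2=fpua,
    )


def find_peak(angles_deg, values) -> tuple[float, float]:
    """Grid argmax of |value|: (angle, signed value) at the peak.

    Peaks are reported at grid resolution (no interpolation), the way
    10-degree-stepped curves are read off a figure.
    """
    angles = np.asarray(angles_deg, dtype=float)
    vals = np.asarray(values, dtype=float)
    if angles.size == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(np.abs(vals)))
    return float(angles[i]), float(vals[i])


def find_sign_change(angles_deg, values, eps: float = 0.0) -> float | None:
    """Angle of the first sign change, linearly interpolated, else None."""
    angles = np.asarray(angles_deg, dtype=float)
    vals = np.asarray(values, dtype=float)
    sign = np.sign(np.where(np.abs(vals) <= eps, 0.0, vals))
    last = None  # index of the last sample with a definite sign
    for i in range(len(vals)):
        if sign[i] == 0.0:
            continue
        if last is not None and sign[i] != sign[last]:
            if i - last > 1:
                # a zero sample sits in between: that grid angle is the crossing
                return float(angles[last + 1])
            y0, y1 = vals[last], vals[i]
            t = y0 / (y0 - y1)  # linear interpolation between bracketing points
            return float(angles[last] + t * (angles[i] - angles[last]))
        last = i
    return None
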