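"""Locomotor joint-angle ranges and their overlay on moment-arm curves.

Published kinematic ranges for bipedal walking, terrestrial
quadrupedalism and vertical climbing are shipped as an editable CSV
(``data/locomotor_ranges.csv``) expressed in the model's joint-angle
convention.  The values are approximate -- several sources only publish
graphs -- and each row carries a provenance note.  A range may be
open-ended on one side (e.g. only the maximum climbing dorsiflexion is
reported); open ends clip to the curve's sweep domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .momentarm import MomentArmCurve

__all__ = [
    "LocomotorRange",
    "load_ranges",
    "range_summary",
    "compare_modes",
]


@dataclass
class LocomotorRange:
    """Joint-angle interval used by one locomotor mode (model convention)."""

    mode: str
    joint: str
    min_deg: float | None
    max_deg: float | None
    abduction_deg: float = 0.0
    source: str = ""

    def clipped(self, grid: np.ndarray) -> tuple[float, float]:
        lo = self.min_deg if self.min_deg is not None else float(grid[0])
        hi = self.max_deg if self.max_deg is not None else float(grid[-1])
        lo = max(lo, float(grid[0]))
        hi = min(hi, float(grid[-1]))
        if lo > hi:
            raise ValueError(
                f"range {self.mode}/{self.joint} [{self.min_deg}, {self.max_deg}] "
                f"does not overlap the sweep domain [{grid[0]}, {grid[-1]}]"
            )
        return lo, hi


def load_ranges(path=None) -> list[LocomotorRange]:
    """Read locomotor ranges from CSV (default: the packaged file)."""
    if path is None:
        with resources.files("limbmoment.data").joinpath(
            "locomotor_ranges.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LocomotorRange(
                mode=row.mode,
                joint=row.joint,
                min_deg=None if pd.isna(row.min_deg) else float(row.min_deg),
                max_deg=None if pd.isna(row.max_deg) else float(row.max_deg),
                abduction_deg=0.0 if pd.isna(row.abduction_deg) else float(row.abduction_deg),
                source=getattr(row, "source", ""),
            )
        )
    return out


def _samples_in_range(curve_angles, curve_values, lo, hi):
    angles = np.asarray(curve_angles, dtype=float)
    values = np.asarray(curve_values, dtype=float)
    inside = (angles >= lo) & (angles <= hi)
    samples = list(values[inside])
    for end in (lo, hi):
        if not np.any(np.isclose(angles, end)):
            samples.append(float(np.interp(end, angles, values)))
    if not samples:
        raise ValueError(f"interval [{lo}, {hi}] contains no curve samples")
    return np.asarray(samples)


def range_summary(curve: MomentArmCurve, rng: LocomotorRange) -> dict[str, float]:
    """Mean/min/max of the curve's MA (and torque) inside the interval.

    Grid points inside the closed interval are used directly; non-grid
    endpoints contribute linearly interpolated values.
    """
    lo, hi = rng.clipped(curve.angles_deg)
    ma = _samples_in_range(curve.angles_deg, curve.ma_m, lo, hi)
    out = {
        "mode": rng.mode,
        "joint": rng.joint,
        "lo_deg": lo,
        "hi_deg": hi,
        "ma_mean_m": float(np.mean(ma)),
        "ma_min_m": float(np.min(ma)),
        "ma_max_m": float(np.max(ma)),
    }
    if curve.torque_nm is not None:
        tau = _samples_in_range(curve.angles_deg, curve.torque_nm, lo, hi)
        out.update(
            torque_mean_nm=float(np.mean(tau)),
            torque_min_nm=float(np.min(tau)),
            torque_max_nm=float(np.max(tau)),
        )
    return out


def compare_modes(
    curve: MomentArmCurve, ranges: list[LocomotorRange]
) -> pd.DataFrame:
    """Ranked comparison of locomotor modes over one summed curve.

    Modes are ranked by mean |MA| within their interval (rank 1 highest);
    equal means share a rank and are flagged as ties.  ``diff_vs_best``
    gives the shortfall of each mode's mean against the best one.
    """
    if len(ranges) < 2:
        raise ValueError("need at least two ranges to compare")
    rows = [range_summary(curve, r) for r in ranges]
    df = pd.DataFrame(rows)
    df["ma_mean_abs_m"] = df["ma_mean_m"].abs()
    df = df.sort_values("ma_mean_abs_m", ascending=False).reset_index(drop=True)
    df["rank"] = df["ma_mean_abs_m"].rank(method="min", ascending=False).astype(int)
    df["tied"] = df.duplicated("ma_mean_abs_m", keep=False)
    df["diff_vs_best"] = df["ma_mean_abs_m"].iloc[0] - df["ma_mean_abs_m"]
    return df
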