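"""Attachment-point perturbation analysis.

Muscles whose origins or insertions sit close to a joint centre can be
functionally sensitive to small placement errors: a centimetre shift may
move the predicted flexor-to-extensor switch by tens of degrees.  This
module displaces selected attachment points in their segment frame
(leaving the original model untouched), re-runs the sweep, and reports
moment-arm deltas, peak shifts and sign-change shifts against baseline.

"Superior"/"inferior" offsets are mapped to the segment-frame axis most
aligned with the limb's long axis; in the default axis convention that is
+Y / -Y.  Models with a differently oriented root frame should pass
explicit offset vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LimbModel
from .momentarm import MomentArmCurve, SweepSpec, sweep_moment_arms
from .torque import find_peak, find_sign_change

__all__ = [
    "DIRECTIONS",
    "direction_vector",
    "perturb_attachment",
    "Perturbation",
    "SensitivityResult",
    "sensitivity_report",
]

DIRECTIONS = {
    "superior": np.array([0.0, 1.0, 0.0]),
    "inferior": np.array([0.0, -1.0, 0.0]),
    "anterior": np.array([1.0, 0.0, 0.0]),
    "posterior": np.array([-1.0, 0.0, 0.0]),
}


def direction_vector(name: str, magnitude_m: float) -> np.ndarray:
    """Offset vector for a named anatomical direction (default frame)."""
    try:
        return DIRECTIONS[name] * magnitude_m
    except KeyError:
        raise ValueError(
            f"unknown direction {name!r}; expected one of {sorted(DIRECTIONS)}"
        ) from None


def perturb_attachment(
    model: LimbModel,
    muscle: str,
    point_selector: str,
    offset_vector_m,
    strand: str | None = None,
) -> LimbModel:
    """Copy of ``model`` with selected attachment point(s) displaced.

    ``point_selector`` is a point role ('origin', 'insertion', 'via') or an
    explicit point label; ``strand=None`` applies to every strand of the
    muscle (e.g. both heads of a two-headed muscle at once).  The offset is
    applied in the point's segment frame; everything else is untouched.
    """
    offset = np.asarray(offset_vector_m, dtype=float).reshape(3)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")
    new = model.copy()
    hits = 0
    for path in new.paths:
        if path.muscle != muscle:
            continue
        if strand is not None and path.strand != strand:
            continue
        for pt in path.points:
            if pt.role == point_selector or pt.label == point_selector:
                pt.location = pt.location + offset
                hits += 1
    if hits == 0:
        raise KeyError(
            f"no point {point_selector!r} on muscle {muscle!r}"
            + (f" strand {strand!r}" if strand else "")
        )
    return new


@dataclass
class Perturbation:
    """One named attachment displacement to evaluate."""

    name: str
    muscle: str
    point_selector: str
    offset_vector_m: np.ndarray
    strand: str | None = None

    def __post_init__(self) -> None:
        self.offset_vector_m = np.asarray(self.offset_vector_m, dtype=float).reshape(3)


@dataclass
class SensitivityResult:
    """Baseline and perturbed moment-arm curves for one muscle and sweep."""

    muscle: str
    sweep: SweepSpec
    baseline: MomentArmCurve
    perturbed: dict[str, MomentArmCurve] = field(default_factory=dict)

    def delta(self, name: str) -> np.ndarray:
        return self.perturbed[name].ma_m - self.baseline.ma_m

    def summary(self) -> pd.DataFrame:
        """Peak and sign-change shifts per perturbation, baseline first."""
        rows = []

        def describe(tag, curve):
            peak_angle, peak_value = find_peak(curve.angles_deg, curve.ma_m)
            rows.append(
                {
                    "perturbation": tag,
                    "muscle": self.muscle,
                    "joint": self.sweep.joint,
                    "peak_angle_deg": peak_angle,
                    "peak_ma_m": peak_value,
                    "sign_change_deg": find_sign_change(curve.angles_deg, curve.ma_m),
                    "mean_delta_ma_m": (
                        float(np.mean(curve.ma_m - self.baseline.ma_m))
                    ),
                }
            )

        describe("baseline", self.baseline)
        for name, curve in self.perturbed.items():
            describe(name, curve)
        df = pd.DataFrame(rows)
        base = df.iloc[0]
        df["peak_shift_deg"] = df["peak_angle_deg"] - base["peak_angle_deg"]
        df["sign_change_shift_deg"] = df["sign_change_deg"] - base["sign_change_deg"]
        return df


def _muscle_curve(curves: list[MomentArmCurve], muscle: str) -> MomentArmCurve:
    for c in curves:
        if c.kind == "muscle" and c.entity == muscle:
            return c
    raise KeyError(f"sweep produced no muscle-level curve for {muscle!r}")


def sensitivity_report(
    model: LimbModel,
    perturbations: list[Perturbation],
    sweep: SweepSpec,
    method: str = "excursion",
) -> dict[str, SensitivityResult]:
    """Run the sweep for the baseline and every perturbation.

    Returns one :class:`SensitivityResult` per perturbed muscle; with an
    empty perturbation list the report contains baselines only.
    """
    base_curves = sweep_moment_arms(model, sweep, method=method)
    muscles = sorted({p.muscle for p in perturbations}) or sorted(
        {c.entity for c in base_curves if c.kind == "muscle"}
    )
    results = {
        m: SensitivityResult(m, sweep, _muscle_curve(base_curves, m))
        for m in muscles
    }
    for pert in perturbations:
        perturbed_model = perturb_attachment(
            model, pert.muscle, pert.point_selector, pert.offset_vector_m, pert.strand
        )
        curves = sweep_moment_arms(perturbed_model, sweep, method=method)
        results[pert.muscle].perturbed[pert.name] = _muscle_curve(curves, pert.muscle)
    return results
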