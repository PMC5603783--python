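#!/usr/bin/env python
"""Overlay locomotor joint-angle ranges on the summed curves.

For each joint, summarises the summed extensor and flexor moment arm and
torque inside the published joint-angle intervals used during bipedal
walking, terrestrial quadrupedalism and vertical climbing (packaged in
limbmoment/data/locomotor_ranges.csv, model convention), and ranks the
modes by mean leverage.

Output: results/locomotor_comparison.csv.
"""

from pathlib import Path

import pandas as pd

import limbmoment as lm
from limbmoment import synthetic
from limbmoment.architecture import scale_architecture
from limbmoment.momentarm import SweepSpec, sweep_moment_arms
from limbmoment.torque import summed_group_curves, torque_curve

RESULTS = Path(__file__).resolve().parent.parent / "results"
SWEEPS = {
    "hip": SweepSpec("hip", -50, 50, 10),
    "knee": SweepSpec("knee", 0, 140, 10),
    "ankle": SweepSpec("ankle", 0, 110, 10),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = synthetic.make_demo_hindlimb()
    model.architecture = {
        n: scale_architecture(a, model.body_mass_kg)
        for n, a in model.architecture.items()
    }
    ranges = lm.load_ranges()

    rows = []
    for joint, spec in SWEEPS.items():
        curves = sweep_moment_arms(model, spec)
        curves = [torque_curve(c) if c.pcsa_m2 is not None else c for c in curves]
        groups = summed_group_curves(curves)
        joint_ranges = [r for r in ranges if r.joint == joint]
        for group in ("extensor", "flexor"):
            df = lm.compare_modes(groups.curve(group), joint_ranges)
            df.insert(0, "group", group)
            rows.append(df)
            ranked = ", ".join(
                f"{r['mode']} ({r.ma_mean_abs_m:.3f} m)" for _, r in df.iterrows()
            )
            print(f"{joint} {group}: {ranked}")

    out = pd.concat(rows, ignore_index=True)
    out.to_csv(RESULTS / "locomotor_comparison.csv", index=False)
    print(f"wrote {RESULTS / 'locomotor_comparison.csv'}")


if __name__ == "__main__":
    main()
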