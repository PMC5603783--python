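"""PCSA computation and geometric-similarity scaling of muscle architecture.

PCSA is muscle volume (mass / density) divided by fascicle length;
pennation is ignored because typical hind-limb pennation angles (< 30
degrees) change the result only marginally.  Scaling between donor and
model body masses assumes geometric similarity: muscle mass scales with
body mass, fibre length with body mass to the power 0.33 (the exponent is
kept literally at 0.33 rather than 1/3), hence PCSA with the power 0.67.
"""

from __future__ import annotations

from dataclasses import replace

from .core import MUSCLE_DENSITY_KG_M3, MuscleArchitecture

__all__ = ["compute_pcsa", "scale_architecture", "MASS_EXPONENT", "LENGTH_EXPONENT"]

MASS_EXPONENT = 1.0
LENGTH_EXPONENT = 0.33


def compute_pcsa(
    mass_kg: float, fl_m: float, density: float = MUSCLE_DENSITY_KG_M3
) -> float:
    """Physiological cross-sectional area (m^2) = (mass / density) / FL."""
    if not (mass_kg > 0 and fl_m > 0 and density > 0):
        raise ValueError(
            f"mass, fascicle length and density must be positive "
            f"(got {mass_kg}, {fl_m}, {density})"
        )
    return (mass_kg / density) / fl_m


def scale_architecture(
    arch: MuscleArchitecture,
    target_mass_kg: float,
    density: float = MUSCLE_DENSITY_KG_M3,
    length_exponent: float = LENGTH_EXPONENT,
) -> MuscleArchitecture:
    """Scale an architecture record to another body mass.

    mass' = mass * (M2/M1); FL' = FL * (M2/M1)**0.33; tendon length scales
    with FL; PCSA is recomputed from the scaled mass and FL (equivalently
    multiplied by (M2/M1)**0.67).  The donor mass of the returned record is
    the target mass, so scaling M1 -> M2 -> M1 is the identity.
    """
    if arch.donor_mass_kg is None or not arch.donor_mass_kg > 0:
        raise ValueError(
            f"architecture for {arch.muscle!r} has no positive donor body mass"
        )
    if not target_mass_kg > 0:
        raise ValueError("target body mass must be positive")
    ratio = target_mass_kg / arch.donor_mass_kg
    mass = arch.mass_kg * ratio if arch.mass_kg is not None else None
    fl = arch.fl_m * ratio**length_exponent if arch.fl_m is not None else None
    tendon = (
        arch.tendon_m * ratio**length_exponent if arch.tendon_m is not None else None
    )
    if mass is not None and fl is not None:
        pcsa = compute_pcsa(mass, fl, density)
    elif arch.pcsa_m2 is not None:
        pcsa = arch.pcsa_m2 * ratio ** (1.0 - length_exponent)
    else:
        pcsa = None
    return replace(
        arch, mass_kg=mass, fl_m=fl, tendon_m=tendon, pcsa_m2=pcsa,
        donor_mass_kg=target_mass_kg,
    )
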