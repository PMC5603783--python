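"""Reading and writing model definitions and result tables.

Three surfaces:

* a tolerant, read-only parser for gaitsym-style musculoskeletal XML
  (bodies, hinge joints, muscle strap points, wrap cylinders, PCSA /
  fibre-length attributes; anything else is skipped with a warning);
* a native YAML dialect (versioned, human-diffable, canonical key order,
  lossless round trip of all :class:`~limbmoment.core.LimbModel` content);
* delimited tables: the muscle-architecture CSV and the long-format
  moment-arm/torque curves CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .core import (
    MUSCLE_DENSITY_KG_M3,
    Joint,
    LimbModel,
    MuscleArchitecture,
    MusclePath,
    PathPoint,
    Segment,
    WrapCylinder,
)
from .momentarm import MomentArmCurve

__all__ = [
    "ModelFormatError",
    "read_gaitsym_xml",
    "read_native_model",
    "write_native_model",
    "read_architecture_table",
    "write_curves_csv",
    "read_model",
    "NATIVE_FORMAT_VERSION",
]

NATIVE_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """A model file is malformed or misses required content."""


# ---------------------------------------------------------------------------
# gaitsym-style XML (read only)
# ---------------------------------------------------------------------------

def _parse_vec(text: str, what: str) -> np.ndarray:
    try:
        v = np.array([float(x) for x in text.split()], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"cannot parse {what!r} as numbers: {text!r}") from exc
    if v.size != 3:
        raise ModelFormatError(f"{what} must have 3 components, got {v.size}")
    return v


def _require(elem, attr: str) -> str:
    val = elem.get(attr)
    if val is None:
        raise ModelFormatError(
            f"<{elem.tag}> element (line {elem.sourceline}) is missing "
            f"required attribute {attr!r}"
        )
    return val


def _strand_group(muscle_id: str) -> str:
    """Muscle name for a strand ID: strip a trailing strand counter."""
    return muscle_id.rstrip("0123456789").rstrip("_-") or muscle_id


def read_gaitsym_xml(
    path,
    body_mass_kg: float | None = None,
    group_strands: bool = True,
    donor_mass_kg: float | None = None,
) -> LimbModel:
    """Read the supported subset of a gaitsym-style model file.

    BODY elements become segments; hinge JOINT elements carry the parent/
    child topology, anchor and axis; MUSCLE elements carry strap points
    (Origin / ViaPointN / Insertion with their body IDs), optional
    cylinder-wrap attributes, and PCSA (``PCA``) / fibre-length data.
    Coordinates are taken as world coordinates at the file's construction
    (neutral) posture, matching the in-memory convention.  Muscles named
    like ``Muscle1``/``Muscle2`` are grouped into strands of one muscle
    when ``group_strands`` is set, with PCSA-proportional fractions.

    Unknown element kinds are skipped with a warning (tolerant-reader
    contract); malformed XML raises :class:`ModelFormatError` with the
    line number; a missing required attribute names the element.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ModelFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()

    segments: dict[str, Segment] = {}
    joints: dict[str, Joint] = {}
    raw_muscles: list[dict] = []
    body_masses: dict[str, float] = {}

    known = {"BODY", "JOINT", "MUSCLE", "GLOBAL", "IOCONTROL", "ENVIRONMENT"}
    for elem in root.iter():
        if elem is root or not isinstance(elem.tag, str):
            continue
        tag = elem.tag.upper()
        if tag not in known:
            if elem.getparent() is root:
                warnings.warn(
                    f"skipping unsupported element <{elem.tag}> "
                    f"(line {elem.sourceline})",
                    stacklevel=2,
                )
            continue
        if tag in {"GLOBAL", "IOCONTROL", "ENVIRONMENT"}:
            continue
        if tag == "BODY":
            name = _require(elem, "ID")
            segments[name] = Segment(name, None)  # parentage set from joints
            if elem.get("Mass") is not None:
                body_masses[name] = float(elem.get("Mass"))
        elif tag == "JOINT":
            jtype = elem.get("Type", "Hinge")
            name = _require(elem, "ID")
            if jtype.lower() not in {"hinge", "ball", "universal"}:
                warnings.warn(
                    f"skipping joint {name!r} of unsupported type {jtype!r}",
                    stacklevel=2,
                )
                continue
            parent = _require(elem, "Body1ID")
            child = _require(elem, "Body2ID")
            anchor = _parse_vec(
                elem.get("HingeAnchor") or _require(elem, "Anchor"), f"{name} anchor"
            )
            axis_txt = elem.get("HingeAxis") or elem.get("Axis")
            if axis_txt is not None:
                z = _parse_vec(axis_txt, f"{name} axis")
                z = z / np.linalg.norm(z)
                # complete a right-handed triad around the flexion axis
                helper = np.array([1.0, 0.0, 0.0])
                if abs(z @ helper) > 0.9:
                    helper = np.array([0.0, 1.0, 0.0])
                x = helper - (helper @ z) * z
                x /= np.linalg.norm(x)
                y = np.cross(z, x)
                axes = np.column_stack([x, y, z])
            else:
                axes = np.eye(3)
            joints[name] = Joint(name, parent, child, anchor, axes)
        elif tag == "MUSCLE":
            raw_muscles.append(dict(elem.attrib, _line=elem.sourceline))

    for j in joints.values():
        for s in (j.parent_segment, j.child_segment):
            if s not in segments:
                raise ModelFormatError(
                    f"joint {j.name!r} references unknown body {s!r}"
                )
        segments[j.child_segment].parent = j.parent_segment

    paths: list[MusclePath] = []
    arch: dict[str, MuscleArchitecture] = {}
    strand_pcsas: dict[str, list[tuple[int, float | None]]] = {}
    for attrs in raw_muscles:
        mid = attrs.get("ID")
        if mid is None:
            raise ModelFormatError(
                f"<MUSCLE> element (line {attrs['_line']}) is missing "
                "required attribute 'ID'"
            )
        muscle = _strand_group(mid) if group_strands else mid
        points = [
            PathPoint(
                attrs.get("OriginBodyID") or attrs.get("OriginBody") or "",
                _parse_vec(attrs.get("Origin", ""), f"{mid} Origin"),
                "origin",
            )
        ]
        n = 0
        while f"ViaPoint{n}" in attrs:
            points.append(
                PathPoint(
                    attrs.get(f"ViaPointBody{n}ID") or attrs.get(f"ViaPointBody{n}") or "",
                    _parse_vec(attrs[f"ViaPoint{n}"], f"{mid} ViaPoint{n}"),
                    "via",
                    f"via{n}",
                )
            )
            n += 1
        points.append(
            PathPoint(
                attrs.get("InsertionBodyID") or attrs.get("InsertionBody") or "",
                _parse_vec(attrs.get("Insertion", ""), f"{mid} Insertion"),
                "insertion",
            )
        )
        for p in points:
            if not p.segment:
                raise ModelFormatError(
                    f"muscle {mid!r} path point {p.role!r} has no body ID"
                )
        wraps = []
        if "CylinderRadius" in attrs:
            wraps.append(
                WrapCylinder(
                    segment=attrs.get("CylinderBodyID") or _require_key(attrs, mid, "CylinderBodyID"),
                    origin=_parse_vec(attrs["CylinderPosition"], f"{mid} CylinderPosition"),
                    direction=_parse_vec(attrs["CylinderAxis"], f"{mid} CylinderAxis"),
                    radius=float(attrs["CylinderRadius"]),
                    side=int(attrs["CylinderSide"]) if "CylinderSide" in attrs else None,
                )
            )
        pcsa = attrs.get("PCA") or attrs.get("PCSA")
        pcsa = float(pcsa) if pcsa is not None else None
        strand_pcsas.setdefault(muscle, []).append((len(paths), pcsa))
        paths.append(MusclePath(muscle, mid if group_strands else "s1", points, wraps))
        fl = attrs.get("FibreLength")
        tendon = attrs.get("TendonLength")
        prev = arch.get(muscle)
        total_pcsa = (pcsa or 0.0) + (prev.pcsa_m2 if prev and prev.pcsa_m2 else 0.0)
        arch[muscle] = MuscleArchitecture(
            muscle,
            fl_m=float(fl) if fl is not None else (prev.fl_m if prev else None),
            tendon_m=float(tendon) if tendon is not None else (prev.tendon_m if prev else None),
            pcsa_m2=total_pcsa if total_pcsa > 0 else None,
            donor_mass_kg=donor_mass_kg,
        )

    # strand fractions: PCSA-proportional when per-strand PCSA is present,
    # equal shares otherwise (muscle-level PCSA files)
    for muscle, entries in strand_pcsas.items():
        values = [p for _, p in entries]
        if all(v is not None for v in values) and sum(values) > 0:
            total = sum(values)
            for (idx, p) in entries:
                paths[idx].fraction = p / total
        else:
            for (idx, _) in entries:
                paths[idx].fraction = 1.0 / len(entries)

    if body_mass_kg is None and body_masses:
        body_mass_kg = float(sum(body_masses.values()))

    bone_lengths: dict[str, float] = {}
    centres = {j.name.lower(): np.asarray(j.centre) for j in joints.values()}

    def _find(substr):
        for nm, c in centres.items():
            if substr in nm:
                return c
        return None

    hip, knee, ankle = _find("hip"), _find("knee"), _find("ankle")
    if hip is not None and knee is not None:
        bone_lengths["femur"] = float(np.linalg.norm(hip - knee))
    if knee is not None and ankle is not None:
        bone_lengths["tibia"] = float(np.linalg.norm(knee - ankle))

    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=body_mass_kg,
        bone_lengths_m=bone_lengths,
        name=str(path),
    )


def _require_key(attrs, mid, key):
    raise ModelFormatError(f"muscle {mid!r} wrap is missing attribute {key!r}")


# ---------------------------------------------------------------------------
# native YAML dialect
# ---------------------------------------------------------------------------

def _point_to_dict(p: PathPoint) -> dict:
    d = {"segment": p.segment, "location": [float(x) for x in p.location],
         "role": p.role}
    if p.label:
        d["label"] = p.label
    return d


def write_native_model(model: LimbModel, path) -> None:
    """Serialise a model to the native YAML dialect (canonical ordering)."""
    doc = {
        "format": "limbmoment-model",
        "version": NATIVE_FORMAT_VERSION,
        "name": model.name,
        "body_mass_kg": model.body_mass_kg,
        "bone_lengths_m": {k: float(v) for k, v in sorted(model.bone_lengths_m.items())},
        "segments": [
            {"name": s.name, "parent": s.parent}
            for s in sorted(model.segments.values(), key=lambda s: s.name)
        ],
        "joints": [
            {
                "name": j.name,
                "parent_segment": j.parent_segment,
                "child_segment": j.child_segment,
                "centre": [float(x) for x in j.centre],
                "axes": [[float(x) for x in row] for row in j.axes],
                "limits_deg": {
                    a: [float(lo), float(hi)]
                    for a, (lo, hi) in sorted(j.limits_deg.items())
                },
            }
            for j in sorted(model.joints.values(), key=lambda j: j.name)
        ],
        "muscles": [
            {
                "muscle": p.muscle,
                "strand": p.strand,
                "fraction": float(p.fraction),
                "points": [_point_to_dict(pt) for pt in p.points],
                "wraps": [
                    {
                        "segment": w.segment,
                        "origin": [float(x) for x in w.origin],
                        "direction": [float(x) for x in w.direction],
                        "radius": float(w.radius),
                        "side": w.side,
                        "label": w.label,
                    }
                    for w in p.wraps
                ],
            }
            for p in sorted(model.paths, key=lambda p: (p.muscle, p.strand))
        ],
        "architecture": [
            {
                "muscle": a.muscle,
                "mass_kg": a.mass_kg,
                "fl_m": a.fl_m,
                "tendon_m": a.tendon_m,
                "pcsa_m2": a.pcsa_m2,
                "donor_mass_kg": a.donor_mass_kg,
            }
            for a in sorted(model.architecture.values(), key=lambda a: a.muscle)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)


def read_native_model(path) -> LimbModel:
    """Read a model written by :func:`write_native_model`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("format") != "limbmoment-model":
        raise ModelFormatError(f"{path} is not a limbmoment native model file")
    version = doc.get("version")
    if version != NATIVE_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported native model version {version!r} "
            f"(this reader supports version {NATIVE_FORMAT_VERSION})"
        )
    for field in ("body_mass_kg", "segments", "joints", "muscles"):
        if field not in doc:
            raise ModelFormatError(f"model file is missing field {field!r}")
    segments = {
        s["name"]: Segment(s["name"], s.get("parent")) for s in doc["segments"]
    }
    joints = {
        j["name"]: Joint(
            j["name"],
            j["parent_segment"],
            j["child_segment"],
            np.asarray(j["centre"], dtype=float),
            np.asarray(j["axes"], dtype=float),
            {a: (float(lo), float(hi)) for a, (lo, hi) in j.get("limits_deg", {}).items()},
        )
        for j in doc["joints"]
    }
    paths = [
        MusclePath(
            m["muscle"],
            m["strand"],
            [
                PathPoint(
                    p["segment"],
                    np.asarray(p["location"], dtype=float),
                    p.get("role", "via"),
                    p.get("label", ""),
                )
                for p in m["points"]
            ],
            [
                WrapCylinder(
                    w["segment"],
                    np.asarray(w["origin"], dtype=float),
                    np.asarray(w["direction"], dtype=float),
                    float(w["radius"]),
                    w.get("side"),
                    w.get("label", ""),
                )
                for w in m.get("wraps", [])
            ],
            float(m.get("fraction", 1.0)),
        )
        for m in doc["muscles"]
    ]
    architecture = {
        a["muscle"]: MuscleArchitecture(
            a["muscle"],
            mass_kg=a.get("mass_kg"),
            fl_m=a.get("fl_m"),
            tendon_m=a.get("tendon_m"),
            pcsa_m2=a.get("pcsa_m2"),
            donor_mass_kg=a.get("donor_mass_kg"),
        )
        for a in doc.get("architecture", [])
    }
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=architecture,
        body_mass_kg=doc["body_mass_kg"],
        bone_lengths_m={k: float(v) for k, v in doc.get("bone_lengths_m", {}).items()},
        name=doc.get("name", str(path)),
    )


def read_model(path, **kw) -> LimbModel:
    """Dispatch on extension: .xml -> gaitsym reader, else native dialect."""
    p = Path(path)
    if p.suffix.lower() == ".xml":
        return read_gaitsym_xml(p, **kw)
    return read_native_model(p)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_architecture_table(
    path, density: float = MUSCLE_DENSITY_KG_M3, prescaled: bool = False
) -> list[MuscleArchitecture]:
    """Read an architecture CSV (muscle, mass_kg, fl_m, tendon_m, pcsa_m2,
    donor_mass_kg).

    PCSA is recomputed from mass and FL when both are present: a missing
    PCSA is filled in, and a given PCSA that deviates from
    (mass/density)/FL by more than 5% triggers a warning.  ``prescaled``
    marks tables whose values are already referred to the model's body
    mass, in which case the donor-mass column is understood as that model
    mass (guards against double scaling downstream).
    """
    df = pd.read_csv(path)
    if "muscle" not in df.columns:
        raise ModelFormatError("architecture table needs a 'muscle' column")
    out: list[MuscleArchitecture] = []
    for i, row in df.iterrows():

        def val(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        mass, fl = val("mass_kg"), val("fl_m")
        pcsa = val("pcsa_m2")
        for col, v in (("mass_kg", mass), ("fl_m", fl)):
            if v is not None and v <= 0:
                raise ModelFormatError(
                    f"row {i} ({row['muscle']}): {col} must be positive, got {v}"
                )
        if mass is not None and fl is not None:
            implied = (mass / density) / fl
            if pcsa is None:
                pcsa = implied
            elif abs(pcsa - implied) > 0.05 * implied:
                warnings.warn(
                    f"{row['muscle']}: given PCSA {pcsa:.4g} m^2 deviates >5% "
                    f"from (mass/density)/FL = {implied:.4g} m^2",
                    stacklevel=2,
                )
        out.append(
            MuscleArchitecture(
                str(row["muscle"]),
                mass_kg=mass,
                fl_m=fl,
                tendon_m=val("tendon_m"),
                pcsa_m2=pcsa,
                donor_mass_kg=val("donor_mass_kg"),
            )
        )
    # prescaled tables need no transformation here; the flag exists so
    # callers don't apply scale_architecture a second time
    _ = prescaled
    return out


def write_curves_csv(curves: list[MomentArmCurve], path) -> None:
    """Write curves as a long-format table (one row per angle sample)."""
    rows = []
    for c in curves:
        for k, angle in enumerate(c.angles_deg):
            rows.append(
                {
                    "joint": c.joint,
                    "entity": c.entity,
                    "kind": c.kind,
                    "lock": c.lock,
                    "angle_deg": float(angle),
                    "ma_m": float(c.ma_m[k]),
                    "ma_norm": (
                        float(c.ma_norm[k]) if c.ma_norm is not None else np.nan
                    ),
                    "torque_nm": (
                        float(c.torque_nm[k]) if c.torque_nm is not None else np.nan
                    ),
                }
            )
    columns = ["joint", "entity", "kind", "lock", "angle_deg", "ma_m",
               "ma_norm", "torque_nm"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False,
                                               float_format="%.6g")
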