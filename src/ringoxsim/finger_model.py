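"""Parametric finger-base geometry and tissue optical data.

The finger base (the segment a ring sits on) is modelled as a nested set of
infinite-prism solids clipped to a 40 mm axial length: an elliptical outer
surface, a 0.2 mm epidermis shell, one circular bone cylinder (the proximal
phalanx) offset toward the dorsal side, a pair of digital arteries on the
palmar side beneath the bone, and several small veins around the bone.  Two
presets reproduce the two reference bounding sizes (40 x 18.4 x 22.4 mm and
40 x 22.3 x 25.8 mm); the internal layout is this package's own design and is
fully overridable.

Each model exists in two cardiac phases that differ *only* in the digital
artery diameter: 1.2 mm in diastole, 1.416 mm in systole.  The difference in
detected light between the two phases is the simulated photoplethysmographic
(PPG) signal.

Angle convention: the finger axis is x (0..length), the cross-section lives in
the (y, z) plane, 0 degrees is the dorsal top (+z) and angles increase towards
+y; 180 degrees is the palmar bottom.  Units are mm and 1/mm throughout.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TissueLabel",
    "CardiacPhase",
    "OpticalProperties",
    "SurfaceScattering",
    "Cylinder",
    "FingerGeometry",
    "GeometryError",
    "WAVELENGTHS_NM",
    "ARTERY_DIAMETER_MM",
    "optical_properties",
    "mean_free_path",
    "surface_params",
    "build_finger_model",
    "make_phantom",
    "classify_point",
    "geometry_from_config",
]

WAVELENGTHS_NM = (656, 943)


class TissueLabel(enum.IntEnum):
    """Tissue classes of the finger-base model (EXTERIOR = outside)."""

    EXTERIOR = 0
    DERMIS_PULP = 1
    EPIDERMIS = 2
    BONE = 3
    ARTERIAL_BLOOD = 4
    VENOUS_BLOOD = 5


class CardiacPhase(enum.Enum):
    DIASTOLE = "diastole"
    SYSTOLE = "systole"


#: Digital artery diameter per cardiac phase (mm).
ARTERY_DIAMETER_MM = {
    CardiacPhase.DIASTOLE: 1.2,
    CardiacPhase.SYSTOLE: 1.416,
}

#: Allowed vein diameter range (mm).
VEIN_DIAMETER_RANGE_MM = (0.4, 0.7)


class GeometryError(ValueError):
    """Raised for malformed or non-nested finger geometries."""


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue, per-wavelength bulk optical properties.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/mm).
    mu_s : float
        Scattering coefficient (1/mm).
    n : float
        Refractive index (carried as metadata; interfaces in this model are
        Lambertian, see :mod:`ringoxsim.transport`).
    g : float
        Henyey-Greenstein scattering anisotropy, the mean cosine of the
        single-scattering deflection angle.
    """

    mu_a: float
    mu_s: float
    n: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("mu_a + mu_s must be positive")
        if not (1.0 <= self.n <= 2.0):
            raise ValueError(f"refractive index {self.n} outside [1, 2]")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"anisotropy {self.g} outside (-1, 1)")


@dataclass(frozen=True)
class SurfaceScattering:
    """Lambertian interface probabilities for one tissue region."""

    reflectance: float
    transmittance: float

    def __post_init__(self) -> None:
        for p in (self.reflectance, self.transmittance):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.reflectance + self.transmittance - 1.0) > 1e-9:
            raise ValueError("reflectance + transmittance must equal 1")


# Bulk optical properties per (tissue, wavelength nm):
# (mu_a 1/mm, mu_s 1/mm, n, g).  The arterial column is 97% SaO2 blood, the
# venous column 60% SvO2 blood.
_BULK_PROPERTIES: dict[tuple[TissueLabel, int], OpticalProperties] = {
    (TissueLabel.DERMIS_PULP, 656): OpticalProperties(0.05, 8.6, 1.38, 0.91),
    (TissueLabel.DERMIS_PULP, 943): OpticalProperties(0.03, 7.0, 1.38, 0.91),
    (TissueLabel.EPIDERMIS, 656): OpticalProperties(0.05, 18.3, 1.43, 0.81),
    (TissueLabel.EPIDERMIS, 943): OpticalProperties(0.03, 12.3, 1.42, 0.89),
    (TissueLabel.BONE, 656): OpticalProperties(0.05, 33.1, 1.40, 0.92),
    (TissueLabel.BONE, 943): OpticalProperties(0.02, 26.1, 1.40, 0.94),
    (TissueLabel.ARTERIAL_BLOOD, 656): OpticalProperties(0.2, 77.5, 1.363, 0.98),
    (TissueLabel.ARTERIAL_BLOOD, 943): OpticalProperties(0.64, 65.0, 1.358, 0.99),
    (TissueLabel.VENOUS_BLOOD, 656): OpticalProperties(0.72, 77.5, 1.362, 0.98),
    (TissueLabel.VENOUS_BLOOD, 943): OpticalProperties(0.54, 65.0, 1.357, 0.99),
}

# Lambertian reflectance per surface region (transmittance is the complement).
_SURFACE_REFLECTANCE: dict[str, float] = {
    "epidermis": 0.32,
    "dermis": 0.26,
    "veins": 0.34,
    "phalanx": 0.47,
    "proximal_phalanx": 0.26,
    "digital_arteries": 0.53,
}

_LABEL_TO_SURFACE_REGION = {
    TissueLabel.EPIDERMIS: "epidermis",
    TissueLabel.DERMIS_PULP: "dermis",
    TissueLabel.VENOUS_BLOOD: "veins",
    TissueLabel.ARTERIAL_BLOOD: "digital_arteries",
}

_BONE_SURFACES = ("proximal_phalanx", "phalanx")


def optical_properties(label: TissueLabel, wavelength: int) -> OpticalProperties:
    """Bulk optical properties of a tissue at 656 or 943 nm."""
    label = TissueLabel(label)
    if label == TissueLabel.EXTERIOR:
        raise ValueError("EXTERIOR has no optical properties")
    try:
        return _BULK_PROPERTIES[(label, int(wavelength))]
    except KeyError:
        raise ValueError(
            f"unsupported wavelength {wavelength} nm; choose one of {WAVELENGTHS_NM}"
        ) from None


def mean_free_path(props: OpticalProperties) -> float:
    """Mean free path 1/(mu_a + mu_s) between photon interactions, in mm."""
    total = props.mu_a + props.mu_s
    if total <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    return 1.0 / total


def surface_params(label: TissueLabel, instance: str | None = None) -> SurfaceScattering:
    """Lambertian reflect/transmit probabilities for a region's interface.

    ``instance`` distinguishes the two bone surfaces: ``"proximal_phalanx"``
    (the default, the finger-base bone) or ``"phalanx"``.  It is ignored for
    the soft-tissue and blood regions.
    """
    label = TissueLabel(label)
    if label == TissueLabel.EXTERIOR:
        raise ValueError("EXTERIOR has no interface parameters")
    if label == TissueLabel.BONE:
        inst = instance or "proximal_phalanx"
        if inst not in _BONE_SURFACES:
            raise ValueError(f"bone surface instance must be one of {_BONE_SURFACES}")
        region = inst
    else:
        region = _LABEL_TO_SURFACE_REGION[label]
    r = _SURFACE_REFLECTANCE[region]
    return SurfaceScattering(reflectance=r, transmittance=1.0 - r)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder along the finger axis: cross-section centre and radius."""

    cy: float
    cz: float
    radius: float

    def to_dict(self) -> dict:
        return {"cy": self.cy, "cz": self.cz, "radius": self.radius}


@dataclass(frozen=True)
class FingerGeometry:
    """Nested-solid finger-base scene for one model and cardiac phase.

    The outer surface is an elliptical cylinder with semi-axes
    ``(semi_axis_y, semi_axis_z)`` clipped to ``0 <= x <= length``; the
    epidermis is an inward shell of constant nominal thickness.  All interior
    solids must be strictly inside the epidermis inner surface and mutually
    disjoint.
    """

    model_id: int
    phase: CardiacPhase
    semi_axis_y: float
    semi_axis_z: float
    length: float
    epidermis_thickness: float
    bone: Cylinder | None
    bone_surface: str
    arteries: tuple[Cylinder, ...]
    veins: tuple[Cylinder, ...]

    # -- derived ---------------------------------------------------------
    @property
    def inner_semi_axes(self) -> tuple[float, float]:
        t = self.epidermis_thickness
        return (self.semi_axis_y - t, self.semi_axis_z - t)

    @property
    def bounding_box_mm(self) -> tuple[float, float, float]:
        return (self.length, 2 * self.semi_axis_y, 2 * self.semi_axis_z)

    @property
    def solids(self) -> tuple[tuple[Cylinder, TissueLabel], ...]:
        out: list[tuple[Cylinder, TissueLabel]] = []
        out += [(a, TissueLabel.ARTERIAL_BLOOD) for a in self.arteries]
        out += [(v, TissueLabel.VENOUS_BLOOD) for v in self.veins]
        if self.bone is not None:
            out.append((self.bone, TissueLabel.BONE))
        return tuple(out)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.semi_axis_y <= 0 or self.semi_axis_z <= 0 or self.length <= 0:
            raise GeometryError("outer dimensions must be positive")
        t = self.epidermis_thickness
        if t < 0 or t >= min(self.semi_axis_y, self.semi_axis_z):
            raise GeometryError("epidermis thickness must be in [0, min semi-axis)")
        if self.bone_surface not in _BONE_SURFACES:
            raise GeometryError(f"bone_surface must be one of {_BONE_SURFACES}")
        iay, iaz = self.inner_semi_axes
        imin = min(iay, iaz)
        for cyl, lab in self.solids:
            if cyl.radius <= 0:
                raise GeometryError(f"{lab.name} solid has non-positive radius")
            # conservative inside-inner-ellipse test
            e = math.hypot(cyl.cy / iay, cyl.cz / iaz) + cyl.radius / imin
            if e >= 1.0:
                raise GeometryError(
                    f"{lab.name} solid at ({cyl.cy:.2f}, {cyl.cz:.2f}) "
                    "extends outside the dermis"
                )
        solids = self.solids
        for i in range(len(solids)):
            for j in range(i + 1, len(solids)):
                a, la = solids[i]
                b, lb = solids[j]
                if math.hypot(a.cy - b.cy, a.cz - b.cz) < a.radius + b.radius:
                    raise GeometryError(f"{la.name} and {lb.name} solids overlap")
        want_r = ARTERY_DIAMETER_MM[self.phase] / 2.0
        for a in self.arteries:
            if abs(a.radius - want_r) > 1e-9:
                raise GeometryError(
                    f"artery radius {a.radius} inconsistent with phase "
                    f"{self.phase.value} (expected {want_r})"
                )
        if self.bone is not None:
            for a in self.arteries:
                if a.cz + a.radius > self.bone.cz - self.bone.radius:
                    raise GeometryError("arteries must lie on the palmar side below the bone")
        for v in self.veins:
            d = 2 * v.radius
            lo, hi = VEIN_DIAMETER_RANGE_MM
            if not (lo - 1e-9 <= d <= hi + 1e-9):
                raise GeometryError(f"vein diameter {d:.3f} mm outside [{lo}, {hi}]")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "phase": self.phase.value,
            "semi_axis_y": self.semi_axis_y,
            "semi_axis_z": self.semi_axis_z,
            "length": self.length,
            "epidermis_thickness": self.epidermis_thickness,
            "bone": self.bone.to_dict() if self.bone else None,
            "bone_surface": self.bone_surface,
            "arteries": [a.to_dict() for a in self.arteries],
            "veins": [v.to_dict() for v in self.veins],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FingerGeometry":
        geom = cls(
            model_id=int(d["model_id"]),
            phase=CardiacPhase(d["phase"]),
            semi_axis_y=float(d["semi_axis_y"]),
            semi_axis_z=float(d["semi_axis_z"]),
            length=float(d["length"]),
            epidermis_thickness=float(d["epidermis_thickness"]),
            bone=Cylinder(**d["bone"]) if d.get("bone") else None,
            bone_surface=d.get("bone_surface", "proximal_phalanx"),
            arteries=tuple(Cylinder(**a) for a in d["arteries"]),
            veins=tuple(Cylinder(**v) for v in d["veins"]),
        )
        geom.validate()
        return geom


def _polar_to_yz(angle_deg: float, dist: float) -> tuple[float, float]:
    """Cross-section point at polar angle (0 deg = dorsal top, +y at 90 deg)."""
    a = math.radians(angle_deg)
    return (dist * math.sin(a), dist * math.cos(a))


# Preset layouts.  The fixed reference inputs are the bounding sizes, the epidermis
# thickness and the artery/vein diameters; the internal placement below is
# this package's design (see docs/methods.md) and is overridable.
_PRESETS: dict[int, dict] = {
    1: {
        "semi_axes": (18.4 / 2, 22.4 / 2),
        "length": 40.0,
        "epidermis_thickness": 0.2,
        "bone": {"cy": 0.0, "cz": 3.0, "radius": 6.0},
        "bone_surface": "proximal_phalanx",
        "artery_angles_deg": (140.0, 220.0),
        "artery_distance": 7.0,
        "vein_specs": (
            (45.0, 8.4, 0.4),
            (100.0, 8.0, 0.5),
            (260.0, 8.0, 0.6),
            (315.0, 8.4, 0.7),
        ),
    },
    2: {
        "semi_axes": (22.3 / 2, 25.8 / 2),
        "length": 40.0,
        "epidermis_thickness": 0.2,
        "bone": {"cy": 0.0, "cz": 3.5, "radius": 7.0},
        "bone_surface": "proximal_phalanx",
        "artery_angles_deg": (145.0, 215.0),
        "artery_distance": 8.3,
        "vein_specs": (
            (45.0, 9.8, 0.4),
            (100.0, 9.3, 0.5),
            (260.0, 9.3, 0.6),
            (315.0, 9.8, 0.7),
        ),
    },
}

_OVERRIDE_KEYS = {
    "semi_axes",
    "length",
    "epidermis_thickness",
    "bone",
    "bone_surface",
    "artery_angles_deg",
    "artery_distance",
    "arteries",
    "vein_specs",
    "veins",
}


def build_finger_model(
    preset: int,
    phase: CardiacPhase = CardiacPhase.DIASTOLE,
    overrides: Mapping | None = None,
) -> FingerGeometry:
    """Build one of the two finger-base models in a given cardiac phase.

    Parameters
    ----------
    preset : {1, 2}
        Model 1 has bounding box 40 x 18.4 x 22.4 mm, model 2 is the larger
        40 x 22.3 x 25.8 mm variant with proportionally scaled bone and
        slightly shifted artery placement.
    phase : CardiacPhase
        Sets the digital artery diameter (1.2 mm diastole, 1.416 mm systole);
        the two phases of a model are otherwise identical.
    overrides : mapping, optional
        Layout overrides; recognised keys are ``semi_axes``, ``length``,
        ``epidermis_thickness``, ``bone`` (dict or None), ``bone_surface``,
        ``artery_angles_deg``/``artery_distance`` or explicit ``arteries``
        ([(cy, cz), ...]), and ``vein_specs`` ([(angle_deg, dist, diameter)])
        or explicit ``veins`` ([(cy, cz, diameter), ...]).

    Geometry construction is deterministic; the result is validated (nested,
    disjoint solids; exactly two arteries; at least two veins).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(_PRESETS)}")
    phase = CardiacPhase(phase)
    p = dict(_PRESETS[preset])
    if overrides:
        unknown = set(overrides) - _OVERRIDE_KEYS
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")
        p.update(overrides)

    ay, az = p["semi_axes"]
    artery_r = ARTERY_DIAMETER_MM[phase] / 2.0
    if "arteries" in p:
        arteries = tuple(Cylinder(cy, cz, artery_r) for cy, cz in p["arteries"])
    else:
        arteries = tuple(
            Cylinder(*_polar_to_yz(a, p["artery_distance"]), artery_r)
            for a in p["artery_angles_deg"]
        )
    if "veins" in p:
        veins = tuple(Cylinder(cy, cz, d / 2.0) for cy, cz, d in p["veins"])
    else:
        veins = tuple(
            Cylinder(*_polar_to_yz(a, dist), d / 2.0) for a, dist, d in p["vein_specs"]
        )
    bone = Cylinder(**p["bone"]) if p.get("bone") else None

    geom = FingerGeometry(
        model_id=preset,
        phase=phase,
        semi_axis_y=float(ay),
        semi_axis_z=float(az),
        length=float(p["length"]),
        epidermis_thickness=float(p["epidermis_thickness"]),
        bone=bone,
        bone_surface=p.get("bone_surface", "proximal_phalanx"),
        arteries=arteries,
        veins=veins,
    )
    geom.validate()
    if len(geom.arteries) != 2:
        raise GeometryError("a finger model must have exactly 2 digital arteries")
    if len(geom.veins) < 2:
        raise GeometryError("a finger model must have at least 2 veins")
    return geom


def make_phantom(
    radius_y: float,
    radius_z: float | None = None,
    length: float = 40.0,
    epidermis_thickness: float = 0.0,
) -> FingerGeometry:
    """Homogeneous validation phantom: a bare (elliptical) dermis cylinder.

    Used for closed-form transport checks (Beer-Lambert slabs, rotational
    symmetry); it deliberately has no bone, arteries or veins and so is not a
    finger model.
    """
    geom = FingerGeometry(
        model_id=0,
        phase=CardiacPhase.DIASTOLE,
        semi_axis_y=float(radius_y),
        semi_axis_z=float(radius_z if radius_z is not None else radius_y),
        length=float(length),
        epidermis_thickness=float(epidermis_thickness),
        bone=None,
        bone_surface="proximal_phalanx",
        arteries=(),
        veins=(),
    )
    geom.validate()
    return geom


def classify_point(geom: FingerGeometry, point) -> TissueLabel | np.ndarray:
    """Map point(s) to tissue labels with innermost-region priority.

    Priority: artery/vein > bone > epidermis shell > dermis/pulp > exterior.
    ``point`` may be a single (x, y, z) triple or an (N, 3) array; the return
    is a :class:`TissueLabel` or an int array of label values respectively.
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite (x, y, z) coordinates")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    ay, az = geom.semi_axis_y, geom.semi_axis_z
    lab = np.full(len(pts), int(TissueLabel.EXTERIOR), dtype=np.int64)

    inside = (
        (x >= 0.0)
        & (x <= geom.length)
        & ((y / ay) ** 2 + (z / az) ** 2 <= 1.0)
    )
    lab[inside] = int(TissueLabel.DERMIS_PULP)
    if geom.epidermis_thickness > 0:
        iay, iaz = geom.inner_semi_axes
        shell = inside & ((y / iay) ** 2 + (z / iaz) ** 2 > 1.0)
        lab[shell] = int(TissueLabel.EPIDERMIS)
    # solids in increasing priority so later assignments win
    ordered = (
        [(geom.bone, TissueLabel.BONE)] if geom.bone is not None else []
    )
    ordered += [(v, TissueLabel.VENOUS_BLOOD) for v in geom.veins]
    ordered += [(a, TissueLabel.ARTERIAL_BLOOD) for a in geom.arteries]
    for cyl, clab in ordered:
        m = inside & ((y - cyl.cy) ** 2 + (z - cyl.cz) ** 2 <= cyl.radius**2)
        lab[m] = int(clab)
    if single:
        return TissueLabel(int(lab[0]))
    return lab


def geometry_from_config(source) -> FingerGeometry:
    """Build a geometry from a YAML/JSON text config (path, stream or dict).

    The config must contain ``preset`` and ``phase`` and may contain an
    ``overrides`` mapping passed through to :func:`build_finger_model`.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        if hasattr(source, "read"):
            cfg = yaml.safe_load(source.read())
        else:
            with open(source, "r") as fh:
                cfg = yaml.safe_load(fh)
    phase = CardiacPhase(str(cfg.get("phase", "diastole")).lower())
    return build_finger_model(int(cfg["preset"]), phase, cfg.get("overrides"))
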