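"""Analog Monte Carlo photon transport through a finger-base scene.

Photons are launched from a surface source, take exponential free flights with
mean 1/(mu_a + mu_s), survive each collision as a Henyey-Greenstein scatter
with probability mu_s/(mu_a + mu_s), and undergo Lambertian reflect/transmit
events at internal tissue interfaces with the entered region's tabulated
probabilities.  Crossing the outer lateral surface terminates the walk and is
tallied on 48 equiangular detector bins; end-cap crossings and event-cap
terminations are tallied separately, so integer conservation

    detected + missed + absorbed + end_cap + capped == launched

holds exactly for every run (``missed`` is zero unless a detector axial
window narrower than the finger is configured).

Refractive indices are carried as metadata only: interfaces are described by
the Lambertian probabilities alone and the outer epidermis-air surface
transmits totally.  See docs/methods.md for the reasoning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .finger_model import (
    CardiacPhase,
    FingerGeometry,
    OpticalProperties,
    SurfaceScattering,
    TissueLabel,
    classify_point,
    mean_free_path,
    optical_properties,
    surface_params,
)

__all__ = [
    "Photon",
    "SourceSpec",
    "DetectorArray",
    "SimResult",
    "TerminalEvent",
    "sample_free_path",
    "sample_hg_cos",
    "deflect",
    "lambertian_direction",
    "boundary_event",
    "propagate",
    "run_simulation",
]

logger = logging.getLogger(__name__)

DEFAULT_EVENT_CAP = 10_000


# --------------------------------------------------------------------------
# elementary samplers (vectorized; the numba kernel carries scalar twins)
# --------------------------------------------------------------------------


def sample_free_path(props: OpticalProperties, u):
    """Exponential free-flight length(s) -MFP * ln(u) in mm, for u in (0, 1]."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u > 1.0):
        raise ValueError("uniform variates must lie in (0, 1]")
    return -mean_free_path(props) * np.log(u)


def sample_hg_cos(g: float, u):
    """Deflection-angle cosine(s) from the Henyey-Greenstein inverse CDF.

    For anisotropy g != 0,
    ``cos(theta) = (1 + g^2 - ((1 - g^2) / (1 - g + 2 g u))^2) / (2 g)``;
    for g = 0 the distribution is isotropic, ``cos(theta) = 2 u - 1``.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie in (-1, 1)")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - f * f) / (2.0 * g), -1.0, 1.0)


def hg_pdf_cos(g: float, cos_theta):
    """Henyey-Greenstein density of cos(theta) (normalized on [-1, 1])."""
    c = np.asarray(cos_theta, dtype=float)
    return 0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * c) ** 1.5


def deflect(direction, cos_theta, phi):
    """Rotate unit direction(s) by deflection cosine and azimuth.

    Accepts a single 3-vector or an (N, 3) array; returns unit vectors whose
    angle to the input has cosine ``cos_theta``.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    ct = np.broadcast_to(np.asarray(cos_theta, dtype=float), d.shape[:1]).astype(float)
    ph = np.broadcast_to(np.asarray(phi, dtype=float), d.shape[:1]).astype(float)
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    cp, sp = np.cos(ph), np.sin(ph)
    ux, uy, uz = d[:, 0], d[:, 1], d[:, 2]
    out = np.empty_like(d)
    steep = np.abs(uz) > 0.99999
    den = np.sqrt(np.clip(1.0 - uz**2, 1e-30, None))
    out[:, 0] = st * (ux * uz * cp - uy * sp) / den + ux * ct
    out[:, 1] = st * (uy * uz * cp + ux * sp) / den + uy * ct
    out[:, 2] = -st * cp * den + uz * ct
    if np.any(steep):
        sign = np.where(uz[steep] >= 0.0, 1.0, -1.0)
        out[steep, 0] = st[steep] * cp[steep]
        out[steep, 1] = st[steep] * sp[steep]
        out[steep, 2] = sign * ct[steep]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if single else out


def lambertian_direction(normal, u1, u2):
    """Cosine-weighted unit direction(s) about a unit axis ``normal``."""
    m = np.asarray(normal, dtype=float)
    single = np.ndim(u1) == 0
    u1 = np.atleast_1d(np.asarray(u1, dtype=float))
    u2 = np.atleast_1d(np.asarray(u2, dtype=float))
    ct = np.sqrt(u1)
    st = np.sqrt(1.0 - u1)
    phi = 2.0 * np.pi * u2
    helper = np.array([1.0, 0.0, 0.0]) if abs(m[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(helper, m)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(m, t1)
    out = (
        ct[:, None] * m[None, :]
        + (st * np.cos(phi))[:, None] * t1[None, :]
        + (st * np.sin(phi))[:, None] * t2[None, :]
    )
    return out[0] if single else out


def boundary_event(surface: SurfaceScattering, normal, u_choice, u1, u2):
    """Lambertian interface event(s): reflect or transmit plus new direction.

    ``normal`` is the unit interface normal pointing back toward the side the
    photon arrived from.  With probability ``surface.reflectance`` the photon
    reflects (cosine-weighted about ``+normal``); otherwise it transmits
    (cosine-weighted about ``-normal``).

    Returns ``(reflected, directions)`` where ``reflected`` is a boolean
    array (or scalar) and ``directions`` the outgoing unit vectors.
    """
    uc = np.atleast_1d(np.asarray(u_choice, dtype=float))
    u1 = np.atleast_1d(np.asarray(u1, dtype=float))
    u2 = np.atleast_1d(np.asarray(u2, dtype=float))
    reflected = uc < surface.reflectance
    m = np.asarray(normal, dtype=float)
    dirs_r = lambertian_direction(m, u1, u2)
    dirs_t = lambertian_direction(-m, u1, u2)
    dirs = np.where(np.atleast_2d(reflected).T, np.atleast_2d(dirs_r), np.atleast_2d(dirs_t))
    if np.isscalar(u_choice):
        return bool(reflected[0]), dirs[0]
    return reflected, dirs


# --------------------------------------------------------------------------
# run configuration and results
# --------------------------------------------------------------------------


@dataclass
class Photon:
    """Random-walk state of a single photon (used by :func:`propagate`)."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    wavelength: int = 943
    tissue: TissueLabel | None = None
    event_count: int = 0
    alive: bool = True


@dataclass(frozen=True)
class SourceSpec:
    """Surface light source: a point emitter on the outer lateral surface.

    ``theta_deg`` follows the study convention (0 deg = dorsal top).  The
    emitter radiates into the tissue in a cosine-weighted cone of
    ``half_angle_deg`` about the inward surface normal (an LED-like profile);
    ``half_angle_deg = 0`` gives a pencil beam.
    """

    theta_deg: float
    wavelength: int = 943
    n_photons: int = 1_000_000
    seed: int = 0
    axial_mm: float | None = None
    half_angle_deg: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_deg < 360.0):
            raise ValueError("source angle must lie in [0, 360)")
        if self.n_photons < 1:
            raise ValueError("photon budget must be >= 1")
        if not (0.0 <= self.half_angle_deg <= 90.0):
            raise ValueError("emission half-angle must lie in [0, 90] degrees")


@dataclass(frozen=True)
class DetectorArray:
    """Equiangular detector bins on the outer lateral surface.

    48 bins of 7.5 degrees by default, spanning the full axial length; an
    axial window (mm) can restrict detection, in which case lateral exits
    outside the window are tallied as ``missed``.
    """

    n_bins: int = 48
    axial_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("need at least one detector bin")

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_deg


@dataclass
class SimResult:
    """Tallies and metadata of one seeded transport run."""

    model_id: int
    phase: str
    wavelength: int
    source_theta_deg: float
    seed: int
    n_launched: int
    bin_counts: np.ndarray
    absorbed: int
    end_cap: int
    capped: int
    missed: int
    n_bins: int = 48
    event_cap: int = DEFAULT_EVENT_CAP
    mean_events: float = 0.0

    @property
    def detected_total(self) -> int:
        return int(self.bin_counts.sum())

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return np.arange(self.n_bins) * (360.0 / self.n_bins)

    def check_conservation(self) -> None:
        total = self.detected_total + self.missed + self.absorbed + self.end_cap + self.capped
        if total != self.n_launched:
            raise AssertionError(
                f"photon conservation violated: {total} != {self.n_launched}"
            )

    # -- serialization ---------------------------------------------------
    def meta_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "phase": self.phase,
            "wavelength": self.wavelength,
            "source_theta_deg": self.source_theta_deg,
            "seed": self.seed,
            "n_launched": self.n_launched,
            "detected_total": self.detected_total,
            "absorbed": self.absorbed,
            "end_cap": self.end_cap,
            "capped": self.capped,
            "missed": self.missed,
            "n_bins": self.n_bins,
            "event_cap": self.event_cap,
            "mean_events": self.mean_events,
        }

    def save(self, directory, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}.json").write_text(
            json.dumps(self.meta_dict(), indent=2, sort_keys=True) + "\n"
        )
        df = pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "bin_center_deg": self.bin_centers_deg,
                "detected": self.bin_counts,
            }
        )
        df.to_csv(directory / f"{stem}_bins.csv", index=False)

    @classmethod
    def load(cls, directory, stem: str) -> "SimResult":
        directory = Path(directory)
        meta = json.loads((directory / f"{stem}.json").read_text())
        df = pd.read_csv(directory / f"{stem}_bins.csv")
        counts = df["detected"].to_numpy(dtype=np.int64)
        meta.pop("detected_total", None)
        return cls(bin_counts=counts, **meta)


@dataclass(frozen=True)
class TerminalEvent:
    """Outcome of a single-photon walk: EXITED, ABSORBED, END_CAP or CAPPED."""

    kind: str
    exit_angle_deg: float | None
    exit_axial_mm: float | None
    n_events: int


_CODE_TO_KIND = {
    _kernel.CODE_DETECTED: "EXITED",
    _kernel.CODE_MISSED: "EXITED",
    _kernel.CODE_ABSORBED: "ABSORBED",
    _kernel.CODE_ENDCAP: "END_CAP",
    _kernel.CODE_CAPPED: "CAPPED",
}


# --------------------------------------------------------------------------
# scene packing and simulation drivers
# --------------------------------------------------------------------------


def _scene_arrays(geom: FingerGeometry):
    """Flatten a validated geometry into kernel-ready arrays."""
    circles = []  # (cy, cz, r, label, reflectance-entering)
    for a in geom.arteries:
        circles.append(
            (a.cy, a.cz, a.radius, int(TissueLabel.ARTERIAL_BLOOD),
             surface_params(TissueLabel.ARTERIAL_BLOOD).reflectance)
        )
    for v in geom.veins:
        circles.append(
            (v.cy, v.cz, v.radius, int(TissueLabel.VENOUS_BLOOD),
             surface_params(TissueLabel.VENOUS_BLOOD).reflectance)
        )
    if geom.bone is not None:
        circles.append(
            (geom.bone.cy, geom.bone.cz, geom.bone.radius, int(TissueLabel.BONE),
             surface_params(TissueLabel.BONE, geom.bone_surface).reflectance)
        )
    ncirc = len(circles)
    ccy = np.array([c[0] for c in circles], dtype=np.float64)
    ccz = np.array([c[1] for c in circles], dtype=np.float64)
    cr = np.array([c[2] for c in circles], dtype=np.float64)
    clabel = np.array([c[3] for c in circles], dtype=np.int64)
    crefl = np.array([c[4] for c in circles], dtype=np.float64)
    if ncirc == 0:
        ccy = ccy.reshape(0)
        ccz = ccz.reshape(0)
        cr = cr.reshape(0)
        clabel = clabel.reshape(0)
        crefl = crefl.reshape(0)
    has_inner = geom.epidermis_thickness > 0.0
    iay, iaz = geom.inner_semi_axes if has_inner else (geom.semi_axis_y, geom.semi_axis_z)
    return (
        geom.length,
        geom.semi_axis_y,
        geom.semi_axis_z,
        has_inner,
        iay,
        iaz,
        ccy,
        ccz,
        cr,
        clabel,
        crefl,
        surface_params(TissueLabel.DERMIS_PULP).reflectance,
        surface_params(TissueLabel.EPIDERMIS).reflectance,
    )


def _resolve_bulk(geom: FingerGeometry, wavelength: int, properties=None):
    """Label-indexed (mu_t, albedo, g) arrays for the kernel."""
    mu_t = np.ones(6, dtype=np.float64)
    albedo = np.zeros(6, dtype=np.float64)
    gpar = np.zeros(6, dtype=np.float64)
    override = properties or {}
    for lab in (
        TissueLabel.DERMIS_PULP,
        TissueLabel.EPIDERMIS,
        TissueLabel.BONE,
        TissueLabel.ARTERIAL_BLOOD,
        TissueLabel.VENOUS_BLOOD,
    ):
        p = override.get(lab) or optical_properties(lab, wavelength)
        total = p.mu_a + p.mu_s
        mu_t[int(lab)] = total
        albedo[int(lab)] = p.mu_s / total
        gpar[int(lab)] = p.g
    return mu_t, albedo, gpar


def _surface_point_and_normal(geom: FingerGeometry, theta_deg: float):
    th = math.radians(theta_deg)
    ay, az = geom.semi_axis_y, geom.semi_axis_z
    r = 1.0 / math.sqrt((math.sin(th) / ay) ** 2 + (math.cos(th) / az) ** 2)
    sy, sz = r * math.sin(th), r * math.cos(th)
    ny, nz = sy / ay**2, sz / az**2
    nn = math.hypot(ny, nz)
    return sy, sz, ny / nn, nz / nn  # outward normal


def _trace(geom, bulk, pos, dirs, labs, cids, seed, event_cap, detector):
    scene = _scene_arrays(geom)
    mu_t, albedo, gpar = bulk
    n = pos.shape[0]
    det = detector or DetectorArray()
    if det.axial_window is None:
        det_lo, det_hi = 0.0, geom.length
    else:
        det_lo, det_hi = det.axial_window
    bins = np.zeros(det.n_bins, dtype=np.int64)
    code = np.empty(n, dtype=np.int8)
    exit_angle = np.empty(n, dtype=np.float64)
    exit_axial = np.empty(n, dtype=np.float64)
    nevents = np.empty(n, dtype=np.int32)
    _kernel.trace(
        *scene,
        mu_t,
        albedo,
        gpar,
        pos[:, 0].copy(),
        pos[:, 1].copy(),
        pos[:, 2].copy(),
        dirs[:, 0].copy(),
        dirs[:, 1].copy(),
        dirs[:, 2].copy(),
        labs,
        cids,
        np.uint64(seed),
        event_cap,
        det_lo,
        det_hi,
        det.n_bins,
        bins,
        code,
        exit_angle,
        exit_axial,
        nevents,
    )
    return det, bins, code, exit_angle, exit_axial, nevents


def run_simulation(
    geom: FingerGeometry,
    source: SourceSpec,
    detectors: DetectorArray | None = None,
    n_photons: int | None = None,
    seed: int | None = None,
    properties: dict | None = None,
    event_cap: int = DEFAULT_EVENT_CAP,
) -> SimResult:
    """Run one seeded transport configuration and return detector tallies.

    Identical ``(geom, source, seed)`` yield bitwise-identical results.  Runs
    sharing a seed but differing only in geometry (e.g. the two cardiac
    phases) share per-photon random-number streams, which is the common
    random-numbers pairing used for PPG extraction.

    ``properties`` optionally overrides bulk optical properties per tissue
    label (used for validation phantoms).
    """
    n = int(n_photons if n_photons is not None else source.n_photons)
    if n < 1:
        raise ValueError("photon budget must be >= 1")
    run_seed = int(source.seed if seed is None else seed)

    # source samples are drawn from the run seed so a phase pair with equal
    # seeds launches identical photons
    rng = np.random.default_rng(np.random.SeedSequence([run_seed, 0x51DE]))
    sy, sz, ony, onz = _surface_point_and_normal(geom, source.theta_deg)
    my, mz = -ony, -onz  # inward normal
    x0 = geom.length / 2.0 if source.axial_mm is None else float(source.axial_mm)
    if not (0.0 <= x0 <= geom.length):
        raise ValueError("source axial position outside the finger")
    psi = math.radians(source.half_angle_deg)
    if psi <= 0.0:
        dirs = np.tile(np.array([0.0, my, mz]), (n, 1))
    else:
        cos2 = math.cos(psi) ** 2
        ct = np.sqrt(1.0 - rng.random(n) * (1.0 - cos2))
        st = np.sqrt(1.0 - ct**2)
        phi = 2.0 * np.pi * rng.random(n)
        # frame about the inward normal: t1 = x-axis, t2 = (0, -mz, my)
        dirs = np.empty((n, 3))
        dirs[:, 0] = st * np.cos(phi)
        dirs[:, 1] = ct * my + st * np.sin(phi) * (-mz)
        dirs[:, 2] = ct * mz + st * np.sin(phi) * my
    eps_in = 1e-6
    pos = np.empty((n, 3))
    pos[:, 0] = x0
    pos[:, 1] = sy + eps_in * my
    pos[:, 2] = sz + eps_in * mz
    start_label = (
        TissueLabel.EPIDERMIS if geom.epidermis_thickness > 0 else TissueLabel.DERMIS_PULP
    )
    labs = np.full(n, int(start_label), dtype=np.int64)
    cids = np.full(n, -1, dtype=np.int64)

    bulk = _resolve_bulk(geom, source.wavelength, properties)
    det, bins, code, _, _, nevents = _trace(
        geom, bulk, pos, dirs, labs, cids, run_seed, event_cap, detectors
    )
    result = SimResult(
        model_id=geom.model_id,
        phase=geom.phase.value,
        wavelength=source.wavelength,
        source_theta_deg=source.theta_deg,
        seed=run_seed,
        n_launched=n,
        bin_counts=bins,
        absorbed=int(np.count_nonzero(code == _kernel.CODE_ABSORBED)),
        end_cap=int(np.count_nonzero(code == _kernel.CODE_ENDCAP)),
        capped=int(np.count_nonzero(code == _kernel.CODE_CAPPED)),
        missed=int(np.count_nonzero(code == _kernel.CODE_MISSED)),
        n_bins=det.n_bins,
        event_cap=event_cap,
        mean_events=float(nevents.mean()),
    )
    result.check_conservation()
    logger.info(
        "run model=%s phase=%s wl=%d src=%.1f seed=%d: launched=%d detected=%d "
        "absorbed=%d end_cap=%d capped=%d",
        result.model_id,
        result.phase,
        result.wavelength,
        result.source_theta_deg,
        result.seed,
        result.n_launched,
        result.detected_total,
        result.absorbed,
        result.end_cap,
        result.capped,
    )
    return result


def propagate(
    photon: Photon,
    geom: FingerGeometry,
    seed: int = 0,
    event_cap: int = DEFAULT_EVENT_CAP,
    properties: dict | None = None,
) -> TerminalEvent:
    """Trace a single photon to its terminal event.

    The photon must start inside the geometry; its tissue label is inferred
    from the position when not set.  The terminal event is one of EXITED
    (with surface angle and axial coordinate), ABSORBED, END_CAP or CAPPED.
    """
    pos = np.asarray(photon.position, dtype=float).reshape(1, 3)
    d = np.asarray(photon.direction, dtype=float)
    nrm = np.linalg.norm(d)
    if not np.isfinite(nrm) or abs(nrm - 1.0) > 1e-6:
        raise ValueError("photon direction must be a unit vector")
    dirs = (d / nrm).reshape(1, 3)
    label = photon.tissue
    if label is None:
        label = classify_point(geom, pos[0])
    if label == TissueLabel.EXTERIOR:
        raise ValueError("photon must start inside the geometry")
    cid = -1
    solids = geom.solids
    for k, (cyl, lab) in enumerate(solids):
        if (pos[0, 1] - cyl.cy) ** 2 + (pos[0, 2] - cyl.cz) ** 2 <= cyl.radius**2:
            cid = k
            break
    labs = np.array([int(label)], dtype=np.int64)
    cids = np.array([cid], dtype=np.int64)
    bulk = _resolve_bulk(geom, photon.wavelength, properties)
    _, bins, code, exit_angle, exit_axial, nevents = _trace(
        geom, bulk, pos, dirs, labs, cids, seed, event_cap, None
    )
    kind = _CODE_TO_KIND[int(code[0])]
    photon.event_count = int(nevents[0])
    photon.alive = False
    return TerminalEvent(
        kind=kind,
        exit_angle_deg=float(exit_angle[0]) if kind == "EXITED" else None,
        exit_axial_mm=float(exit_axial[0]) if kind == "EXITED" else None,
        n_events=int(nevents[0]),
    )
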