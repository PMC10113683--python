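"""Imaging geometry of an orthogonal kV fluoroscopy system.

The room coordinate frame has its origin at the treatment isocenter with
``+x`` toward the patient's left (LR), ``+y`` posterior-to-anterior (AP)
and ``+z`` inferior-to-superior (SI).  All lengths are in millimetres and
all angles in degrees at the interface (radians internally).

A kV tube / flat-panel detector pair is described by the azimuth of its
central beam axis in the axial plane (``tube_angle``) plus two small rigid
tilts of the whole source+panel assembly about the isocenter
(``perturb_si``, ``perturb_ap``) used for training-set augmentation.  The
two tubes of the orthogonal pair sit at gantry angle +45 deg (clockwise
tube) and -45 deg (counterclockwise tube), so their beam axes are always
90 deg apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_SID_MM",
    "DEFAULT_SDD_MM",
    "DEFAULT_PIXEL_PITCH_MM",
    "DEFAULT_N_U",
    "DEFAULT_N_V",
    "TUBE_OFFSET_DEG",
    "PanelSpec",
    "ImagingGeometry",
    "Ray",
    "tube_angles_for_gantry",
    "tube_angle_models_for_plan",
    "build_geometry",
    "ray_through_pixel",
    "pixel_rays",
    "project_point",
]

#: source-to-isocenter distance of the clinical system [mm]
DEFAULT_SID_MM = 1000.0
#: source-to-detector distance of the clinical system [mm]
DEFAULT_SDD_MM = 1836.0
#: physical pixel pitch at the panel [mm]; chosen so the isocenter-plane
#: pixel scale is 0.211 mm (pitch * SID / SDD).
DEFAULT_PIXEL_PITCH_MM = 0.211 * DEFAULT_SDD_MM / DEFAULT_SID_MM
DEFAULT_N_U = 1024
DEFAULT_N_V = 768

#: beam-azimuth offset of each tube relative to the gantry angle [deg]
TUBE_OFFSET_DEG = {"CW": 45.0, "CCW": -45.0}

_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    a = _unit(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


@dataclass(frozen=True)
class PanelSpec:
    """Flat-panel detector description: pitch [mm] and pixel counts."""

    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM
    n_u: int = DEFAULT_N_U
    n_v: int = DEFAULT_N_V

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_u <= 0 or self.n_v <= 0:
            raise ValueError("pixel counts must be positive")


@dataclass(frozen=True, eq=False)
class ImagingGeometry:
    """One kV tube / panel pose.

    ``source`` and ``detector_center`` are room-frame points; ``u_axis`` and
    ``v_axis`` are orthonormal panel axes, both perpendicular to the central
    beam axis.  Pixel ``(u, v)`` has its center at
    ``detector_center + (u - (n_u-1)/2) * pixel_pitch * u_axis
    + (v - (n_v-1)/2) * pixel_pitch * v_axis``.
    """

    tube_angle: float
    perturb_si: float
    perturb_ap: float
    source: np.ndarray
    detector_center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    sid: float
    sdd: float
    pixel_pitch: float
    n_u: int
    n_v: int
    tube_label: str = "CW"

    def __post_init__(self) -> None:
        for name in ("source", "detector_center", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (0 < self.sid < self.sdd):
            raise ValueError("require 0 < sid < sdd")
        axis = self.beam_axis
        if abs(float(self.u_axis @ self.v_axis)) > 1e-6:
            raise ValueError("panel axes not orthogonal")
        if abs(float(self.u_axis @ axis)) > 1e-6 or abs(float(self.v_axis @ axis)) > 1e-6:
            raise ValueError("panel axes not perpendicular to the beam axis")
        if abs(np.linalg.norm(self.source) - self.sid) > 1e-6 * self.sid:
            raise ValueError("|source| must equal sid")
        if abs(np.linalg.norm(self.detector_center - self.source) - self.sdd) > 1e-6 * self.sdd:
            raise ValueError("source-to-detector distance must equal sdd")

    @property
    def beam_axis(self) -> np.ndarray:
        """Unit vector from the source toward the detector center."""
        return (self.detector_center - self.source) / self.sdd

    @property
    def isocenter_pixel_mm(self) -> float:
        """Pixel scale demagnified to the isocenter plane [mm]."""
        return self.pixel_pitch * self.sid / self.sdd

    def downsampled(self, factor: int) -> "ImagingGeometry":
        """Equivalent geometry with ``factor`` x ``factor`` pixel binning.

        ``factor`` must divide both pixel counts; binned pixel centers
        coincide with the mean of the covered full-resolution centers.
        """
        factor = int(factor)
        if factor < 1:
            raise ValueError("downsample factor must be >= 1")
        if self.n_u % factor or self.n_v % factor:
            raise ValueError(f"downsample factor {factor} does not divide panel {self.n_u}x{self.n_v}")
        if factor == 1:
            return self
        return replace(
            self,
            pixel_pitch=self.pixel_pitch * factor,
            n_u=self.n_u // factor,
            n_v=self.n_v // factor,
        )

    def to_dict(self) -> dict:
        return {
            "tube_angle": self.tube_angle,
            "perturb_si": self.perturb_si,
            "perturb_ap": self.perturb_ap,
            "source": self.source.tolist(),
            "detector_center": self.detector_center.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "sid": self.sid,
            "sdd": self.sdd,
            "pixel_pitch": self.pixel_pitch,
            "n_u": self.n_u,
            "n_v": self.n_v,
            "tube_label": self.tube_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingGeometry":
        return cls(**d)


@dataclass(frozen=True, eq=False)
class Ray:
    """Half-line from ``origin`` along unit ``direction`` (room frame, mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))


def tube_angles_for_gantry(gantry_angle: float) -> tuple[float, float]:
    """Map a gantry angle to the (CW, CCW) tube beam azimuths.

    The clockwise and counterclockwise tubes sit at the gantry angle plus
    and minus 45 deg; results are normalized to [0, 360).
    """
    cw = (gantry_angle + TUBE_OFFSET_DEG["CW"]) % 360.0
    ccw = (gantry_angle + TUBE_OFFSET_DEG["CCW"]) % 360.0
    return cw, ccw


def tube_angle_models_for_plan(gantry_angles) -> list[tuple[float, str, float]]:
    """Enumerate the tube-angle-specific models a treatment plan requires.

    One contour-prediction model is trained per (port, tube) combination, so
    a plan with ``n`` ports needs ``2 n`` models.  Returns a list of
    ``(gantry_angle, tube_label, tube_angle)`` tuples.
    """
    out: list[tuple[float, str, float]] = []
    for g in gantry_angles:
        cw, ccw = tube_angles_for_gantry(g)
        out.append((float(g), "CW", cw))
        out.append((float(g), "CCW", ccw))
    return out


def build_geometry(
    tube_angle: float,
    perturb_si: float = 0.0,
    perturb_ap: float = 0.0,
    panel: PanelSpec | None = None,
    *,
    sid: float = DEFAULT_SID_MM,
    sdd: float = DEFAULT_SDD_MM,
    tube_label: str = "CW",
) -> ImagingGeometry:
    """Construct a tube/panel pose at a beam azimuth with optional tilts.

    The unperturbed source lies in the axial (z = 0) plane at radius ``sid``
    with the beam pointing through the isocenter; at ``tube_angle`` 0 the
    source is at (0, -sid, 0) and the beam axis is +y.  The whole
    source+panel assembly is then rotated rigidly about the isocenter,
    first by ``perturb_si`` about the in-plane axis perpendicular to the
    beam (tilting the beam toward SI), then by ``perturb_ap`` about the z
    axis (tilting it toward AP).
    """
    if abs(perturb_si) > 10.0 or abs(perturb_ap) > 10.0:
        raise ValueError("perturbation angles must satisfy |angle| <= 10 deg")
    panel = panel or PanelSpec()
    theta = np.deg2rad(tube_angle)
    beam0 = np.array([-np.sin(theta), np.cos(theta), 0.0])
    u0 = np.array([np.cos(theta), np.sin(theta), 0.0])
    v0 = np.array([0.0, 0.0, 1.0])
    rot = _rotation_about(np.array([0.0, 0.0, 1.0]), perturb_ap) @ _rotation_about(u0, perturb_si)
    return ImagingGeometry(
        tube_angle=float(tube_angle) % 360.0,
        perturb_si=float(perturb_si),
        perturb_ap=float(perturb_ap),
        source=rot @ (-sid * beam0),
        detector_center=rot @ ((sdd - sid) * beam0),
        u_axis=rot @ u0,
        v_axis=rot @ v0,
        sid=float(sid),
        sdd=float(sdd),
        pixel_pitch=panel.pixel_pitch,
        n_u=panel.n_u,
        n_v=panel.n_v,
        tube_label=tube_label,
    )


def _pixel_point(geom: ImagingGeometry, u, v) -> np.ndarray:
    du = (np.asarray(u, dtype=float) - (geom.n_u - 1) / 2.0) * geom.pixel_pitch
    dv = (np.asarray(v, dtype=float) - (geom.n_v - 1) / 2.0) * geom.pixel_pitch
    return geom.detector_center + np.multiply.outer(du, geom.u_axis) + np.multiply.outer(dv, geom.v_axis)


def ray_through_pixel(geom: ImagingGeometry, u: float, v: float, margin: float = 2.0) -> Ray:
    """Ray from the source through the center of (sub-)pixel ``(u, v)``.

    Continuous sub-pixel coordinates are allowed; coordinates farther than
    ``margin`` pixels outside the panel raise ``ValueError``.
    """
    if not (-margin <= u <= geom.n_u - 1 + margin) or not (-margin <= v <= geom.n_v - 1 + margin):
        raise ValueError(f"pixel ({u}, {v}) outside panel (+{margin} px margin)")
    point = _pixel_point(geom, float(u), float(v))
    return Ray(origin=geom.source, direction=point - geom.source)


def pixel_rays(geom: ImagingGeometry) -> np.ndarray:
    """Unit ray directions through every pixel center, shape (n_u, n_v, 3)."""
    du = (np.arange(geom.n_u) - (geom.n_u - 1) / 2.0) * geom.pixel_pitch
    dv = (np.arange(geom.n_v) - (geom.n_v - 1) / 2.0) * geom.pixel_pitch
    points = (
        geom.detector_center[None, None, :]
        + du[:, None, None] * geom.u_axis[None, None, :]
        + dv[None, :, None] * geom.v_axis[None, None, :]
    )
    dirs = points - geom.source[None, None, :]
    return dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)


def project_point(geom: ImagingGeometry, point) -> tuple[float, float]:
    """Perspective-project a room-frame point onto the panel, in pixels.

    Returns continuous ``(u, v)`` panel coordinates (possibly outside the
    physical pixel range).  Points at or behind the source plane raise
    ``ValueError``.
    """
    p = np.asarray(point, dtype=float)
    d = p - geom.source
    axis = geom.beam_axis
    depth = float(d @ axis)
    if depth <= 1e-9:
        raise ValueError("point is not in front of the source")
    hit = geom.source + (geom.sdd / depth) * d
    off = hit - geom.detector_center
    u = float(off @ geom.u_axis) / geom.pixel_pitch + (geom.n_u - 1) / 2.0
    v = float(off @ geom.v_axis) / geom.pixel_pitch + (geom.n_v - 1) / 2.0
    return u, v
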