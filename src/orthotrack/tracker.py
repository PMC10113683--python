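"""3D tumor positioning from orthogonal 2D detections.

The 3D position is the midpoint of the shortest segment between the two
rays that connect each kV source to the detected centroid on its panel —
the same construction the clinical system uses for the fiducial-marker
center of mass.  For the markerless chain the detected centroid is the
centroid of the predicted GTV contour; for the marker-based ground-truth
chain it is the mean of the marker centroids, and the GTV position is the
triangulated marker center of mass plus the marker-to-GTV offset frozen at
the reference 4DCT phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImagingGeometry, Ray, ray_through_pixel

__all__ = [
    "Track3D",
    "MarkerSet",
    "TriangulationError",
    "mask_centroid",
    "triangulate_midpoint",
    "position_from_pair",
    "marker_ground_truth",
]


class TriangulationError(ValueError):
    """Rays are (near-)parallel: no stable closest-point solution."""


@dataclass(eq=False)
class Track3D:
    """Timestamped 3D positions with a per-entry source tag."""

    timestamps: np.ndarray  # (n,) strictly increasing
    positions: np.ndarray  # (n, 3) mm
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.timestamps) != len(self.positions):
            raise ValueError("timestamps and positions disagree in length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.sources:
            self.sources = ["markerless"] * len(self.timestamps)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_ms": self.timestamps,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "source": self.sources,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)

    @classmethod
    def from_csv(cls, path) -> "Track3D":
        df = pd.read_csv(Path(path))
        return cls(
            timestamps=df["timestamp_ms"].to_numpy(),
            positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            sources=list(df["source"].astype(str)),
        )


@dataclass(eq=False)
class MarkerSet:
    """Per-tube marker detector centroids plus the reference GTV offset.

    ``centroids_cw`` / ``centroids_ccw`` are (n, 2) arrays of (u, v) pixel
    coordinates of the same implanted markers seen on the two panels;
    ``reference_offset`` is the marker-COM-to-GTV shift [mm] at the
    reference 4DCT phase.
    """

    centroids_cw: np.ndarray
    centroids_ccw: np.ndarray
    reference_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.centroids_cw = np.asarray(self.centroids_cw, dtype=float).reshape(-1, 2)
        self.centroids_ccw = np.asarray(self.centroids_ccw, dtype=float).reshape(-1, 2)
        self.reference_offset = np.asarray(self.reference_offset, dtype=float)
        if len(self.centroids_cw) < 1 or len(self.centroids_ccw) < 1:
            raise ValueError("need at least one marker centroid per tube")


def mask_centroid(prediction) -> tuple[float, float]:
    """Sub-pixel centroid (u, v) of a predicted contour's mask."""
    mask = np.asarray(prediction.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty prediction mask")
    uu, vv = np.nonzero(mask)
    return float(uu.mean()), float(vv.mean())


def triangulate_midpoint(ray_a: Ray, ray_b: Ray) -> np.ndarray:
    """Midpoint of the shortest segment between two skew rays.

    Solves the closed-form 2x2 system from perpendicularity of the
    connecting segment to both directions; raises
    :class:`TriangulationError` for near-parallel rays.
    """
    da, db = ray_a.direction, ray_b.direction
    if np.linalg.norm(np.cross(da, db)) <= 1e-9:
        raise TriangulationError("rays are (near-)parallel")
    w0 = ray_a.origin - ray_b.origin
    b = float(da @ db)
    d = float(da @ w0)
    e = float(db @ w0)
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    pa = ray_a.origin + s * da
    pb = ray_b.origin + t * db
    return (pa + pb) / 2.0


def _check_orthogonal_pair(geom_cw: ImagingGeometry, geom_ccw: ImagingGeometry) -> None:
    cos = abs(float(geom_cw.beam_axis @ geom_ccw.beam_axis))
    if cos > 0.5:  # beam axes must be within 60-120 deg of each other
        raise ValueError("geometries do not form an orthogonal imaging pair")


def position_from_pair(
    pred_cw,
    pred_ccw,
    geom_cw: ImagingGeometry,
    geom_ccw: ImagingGeometry,
) -> np.ndarray | None:
    """3D GTV position from one orthogonal pair of contour predictions.

    Returns ``None`` when either prediction is missing (the frame then
    counts as "no prediction") or when triangulation degenerates.
    """
    _check_orthogonal_pair(geom_cw, geom_ccw)
    if pred_cw is None or pred_ccw is None:
        return None
    u_cw, v_cw = mask_centroid(pred_cw)
    u_ccw, v_ccw = mask_centroid(pred_ccw)
    ray_cw = ray_through_pixel(geom_cw, u_cw, v_cw)
    ray_ccw = ray_through_pixel(geom_ccw, u_ccw, v_ccw)
    try:
        return triangulate_midpoint(ray_cw, ray_ccw)
    except TriangulationError:
        import warnings

        warnings.warn("triangulation failed for an orthogonal pair; frame dropped")
        return None


def marker_ground_truth(
    markers: MarkerSet,
    geom_cw: ImagingGeometry,
    geom_ccw: ImagingGeometry,
) -> np.ndarray:
    """GTV position from fiducial markers, as the clinical system computes it.

    The per-tube 2D centroid of the marker polyhedron (mean of the marker
    centroids) is triangulated to the 3D marker center of mass, then the
    reference-phase marker-to-GTV offset is added.
    """
    _check_orthogonal_pair(geom_cw, geom_ccw)
    u_cw, v_cw = markers.centroids_cw.mean(axis=0)
    u_ccw, v_ccw = markers.centroids_ccw.mean(axis=0)
    ray_cw = ray_through_pixel(geom_cw, float(u_cw), float(v_cw), margin=8.0)
    ray_ccw = ray_through_pixel(geom_ccw, float(u_ccw), float(v_ccw), margin=8.0)
    com = triangulate_midpoint(ray_cw, ray_ccw)
    return com + markers.reference_offset
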