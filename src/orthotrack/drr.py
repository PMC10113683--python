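"""Digitally reconstructed radiographs by Siddon ray tracing.

A DRR pixel stores the radiological path: the line integral of the linear
attenuation coefficient mu along the ray from the source to that pixel,
computed exactly as ``sum_i mu_i * l_i`` over the voxels the ray traverses
(Siddon's parametric voxel traversal).  Scatter is not modelled.  HU map to
attenuation linearly through the water coefficient: ``mu = mu_water * (1 +
HU/1000)``, clamped at zero.

For display, images are mapped through ``exp(-path)`` and min-max rescaled
to 8 bit per image; the raw path grid is kept for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter

from .ct_io import CTVolume
from .geometry import ImagingGeometry, Ray, pixel_rays

__all__ = [
    "MU_WATER_MM",
    "ProjectionImage",
    "hu_to_mu",
    "radiological_path",
    "render_drr",
    "gaussian_prefilter",
    "display_from_path",
    "save_projection",
]

#: linear attenuation coefficient of water [1/mm] (~70 keV effective energy)
MU_WATER_MM = 0.02


def hu_to_mu(hu, mu_water: float = MU_WATER_MM):
    """Map Hounsfield units to linear attenuation [1/mm], clamped at 0."""
    return np.maximum(mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0), 0.0)


@njit(cache=True)
def _trace_rays(mu, bmin, spacing, shape, src, dirs, out):  # pragma: no cover - jitted
    n = dirs.shape[0]
    for r in range(n):
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        # clip the ray to the volume bounding box
        tmin, tmax = 0.0, 1.0e30
        miss = False
        for a in range(3):
            d = dirs[r, a]
            lo = bmin[a]
            hi = bmin[a] + shape[a] * spacing[a]
            if abs(d) > 1e-12:
                t1 = (lo - src[a]) / d
                t2 = (hi - src[a]) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
            elif src[a] <= lo or src[a] >= hi:
                miss = True
        if miss or tmax <= tmin:
            out[r] = 0.0
            continue
        # initial voxel index, nudged just inside the entry face
        i = np.empty(3, dtype=np.int64)
        tn = np.empty(3)
        step = np.empty(3, dtype=np.int64)
        for a in range(3):
            pos = src[a] + (tmin + 1e-9) * dirs[r, a]
            ia = int(np.floor((pos - bmin[a]) / spacing[a]))
            if ia < 0:
                ia = 0
            elif ia >= shape[a]:
                ia = shape[a] - 1
            i[a] = ia
            d = dirs[r, a]
            if d > 1e-12:
                step[a] = 1
                tn[a] = (bmin[a] + (ia + 1) * spacing[a] - src[a]) / d
            elif d < -1e-12:
                step[a] = -1
                tn[a] = (bmin[a] + ia * spacing[a] - src[a]) / d
            else:
                step[a] = 0
                tn[a] = 1.0e30
        t = tmin
        total = 0.0
        while t < tmax - 1e-12:
            # axis of the next voxel-plane crossing
            a = 0
            if tn[1] < tn[a]:
                a = 1
            if tn[2] < tn[a]:
                a = 2
            tnext = tn[a]
            if tnext > tmax:
                tnext = tmax
            total += mu[i[0], i[1], i[2]] * (tnext - t)
            t = tnext
            if tn[a] > tmax:
                break
            i[a] += step[a]
            if i[a] < 0 or i[a] >= shape[a]:
                break
            tn[a] += spacing[a] / abs(dirs[r, a])
        out[r] = total


def _volume_mu_and_bounds(volume: CTVolume, mu_water: float):
    mu = np.ascontiguousarray(hu_to_mu(volume.voxels, mu_water))
    bmin = volume.origin - volume.spacing / 2.0
    shape = np.asarray(volume.shape, dtype=np.int64)
    return mu, np.asarray(bmin, dtype=float), np.asarray(volume.spacing, dtype=float), shape


def radiological_path(volume: CTVolume, ray: Ray, mu_water: float = MU_WATER_MM) -> float:
    """Exact radiological path of one ray through the volume (0 if it misses)."""
    mu, bmin, spacing, shape = _volume_mu_and_bounds(volume, mu_water)
    dirs = np.asarray(ray.direction, dtype=float)[None, :]
    out = np.empty(1)
    _trace_rays(mu, bmin, spacing, shape, np.asarray(ray.origin, dtype=float), dirs, out)
    return float(out[0])


def display_from_path(path: np.ndarray) -> np.ndarray:
    """8-bit display image: ``exp(-path)`` min-max rescaled per image."""
    transmission = np.exp(-np.asarray(path, dtype=float))
    lo, hi = transmission.min(), transmission.max()
    if hi - lo < 1e-12:
        return np.zeros(path.shape, dtype=np.uint8)
    return np.rint(255.0 * (transmission - lo) / (hi - lo)).astype(np.uint8)


@dataclass(eq=False)
class ProjectionImage:
    """One projection: radiological-path grid plus its display rendering.

    Arrays are indexed ``[u, v]`` (panel axes), shape ``(n_u, n_v)`` of the
    attached (possibly downsampled) geometry.
    """

    path: np.ndarray
    display: np.ndarray
    geometry: ImagingGeometry
    phase_or_timestamp: float | int | None = None

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.shape != (self.geometry.n_u, self.geometry.n_v):
            raise ValueError("path grid shape does not match geometry pixel counts")
        if np.any(self.path < 0):
            raise ValueError("radiological path must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.path.shape  # type: ignore[return-value]


def render_drr(
    volume: CTVolume,
    geom: ImagingGeometry,
    downsample: int = 1,
    mu_water: float = MU_WATER_MM,
    phase_or_timestamp: float | int | None = None,
) -> ProjectionImage:
    """Render a DRR: one Siddon path per (downsampled) pixel center."""
    g = geom.downsampled(downsample)
    dirs = pixel_rays(g).reshape(-1, 3)
    mu, bmin, spacing, shape = _volume_mu_and_bounds(volume, mu_water)
    out = np.empty(dirs.shape[0])
    _trace_rays(mu, bmin, spacing, shape, np.asarray(g.source, dtype=float), np.ascontiguousarray(dirs), out)
    path = out.reshape(g.n_u, g.n_v)
    ts = volume.phase if phase_or_timestamp is None else phase_or_timestamp
    return ProjectionImage(path=path, display=display_from_path(path), geometry=g, phase_or_timestamp=ts)


def gaussian_prefilter(image: ProjectionImage, sigma_mm: float) -> ProjectionImage:
    """Blur a projection with a 2D Gaussian of ``sigma_mm`` at the panel.

    Used to match the spatial resolution of measured projection images to
    that of the rendered DRRs before contour prediction.  ``sigma_mm`` is
    converted to pixels through the panel pixel pitch; sigma 0 is the
    identity.  Both the path and the display grids are filtered.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_mm == 0:
        return ProjectionImage(
            path=image.path.copy(),
            display=image.display.copy(),
            geometry=image.geometry,
            phase_or_timestamp=image.phase_or_timestamp,
        )
    sigma_px = sigma_mm / image.geometry.pixel_pitch
    path = gaussian_filter(image.path, sigma_px, mode="nearest")
    display = gaussian_filter(image.display.astype(float), sigma_px, mode="nearest")
    return ProjectionImage(
        path=np.maximum(path, 0.0),
        display=np.clip(np.rint(display), 0, 255).astype(np.uint8),
        geometry=image.geometry,
        phase_or_timestamp=image.phase_or_timestamp,
    )


def save_projection(image: ProjectionImage, basepath) -> None:
    """Write a projection as 16-bit TIFF (path) + 8-bit PNG (display) + JSON."""
    import json
    from pathlib import Path

    import imageio.v3 as iio
    import tifffile

    base = Path(basepath)
    peak = float(image.path.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(str(base.with_suffix(".tif")), np.rint(image.path.T * scale).astype(np.uint16))
    iio.imwrite(str(base.with_suffix(".png")), image.display.T)
    sidecar = {
        "path_scale": scale,
        "phase_or_timestamp": image.phase_or_timestamp,
        "geometry": image.geometry.to_dict(),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
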