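"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they verify: dense numerical ray
integration instead of voxel traversal, brute-force grid search instead of
the closed-form triangulation, and a from-scratch interpolated quantile.
"""

import numpy as np

from orthotrack.drr import hu_to_mu


def dense_path(volume, ray, step: float = 0.01) -> float:
    """Radiological path by dense midpoint-rule sampling along the ray."""
    bmin = volume.origin - volume.spacing / 2.0
    bmax = bmin + np.asarray(volume.shape) * volume.spacing
    o, d = ray.origin, ray.direction
    tmin, tmax = 0.0, np.inf
    for a in range(3):
        if abs(d[a]) > 1e-12:
            t1, t2 = (bmin[a] - o[a]) / d[a], (bmax[a] - o[a]) / d[a]
            tmin, tmax = max(tmin, min(t1, t2)), min(tmax, max(t1, t2))
        elif not (bmin[a] < o[a] < bmax[a]):
            return 0.0
    if tmax <= tmin:
        return 0.0
    length = tmax - tmin
    n = int(length / step)
    rem = length - n * step
    ts = np.concatenate([tmin + (np.arange(n) + 0.5) * step, [tmin + n * step + rem / 2.0]])
    weights = np.concatenate([np.full(n, step), [rem]])
    pts = o[None, :] + ts[:, None] * d[None, :]
    idx = np.clip(
        np.floor((pts - bmin) / volume.spacing).astype(int), 0, np.asarray(volume.shape) - 1
    )
    mu = hu_to_mu(volume.voxels)
    return float(np.sum(mu[idx[:, 0], idx[:, 1], idx[:, 2]] * weights))


def closest_point_grid_search(ray_a, ray_b, span=10.0, coarse=401, refine=3):
    """Brute-force minimizer of inter-point distance over (s, t) parameters."""
    s0 = float(ray_a.direction @ (np.zeros(3) - ray_a.origin))
    t0 = float(ray_b.direction @ (np.zeros(3) - ray_b.origin))
    s_lo, s_hi = s0 - span, s0 + span
    t_lo, t_hi = t0 - span, t0 + span
    best = None
    for _ in range(refine):
        ss = np.linspace(s_lo, s_hi, coarse)
        tt = np.linspace(t_lo, t_hi, coarse)
        pa = ray_a.origin[None, :] + ss[:, None] * ray_a.direction[None, :]
        pb = ray_b.origin[None, :] + tt[:, None] * ray_b.direction[None, :]
        d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=2)
        i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
        best = (pa[i] + pb[j]) / 2.0
        half = (s_hi - s_lo) / (coarse - 1) * 4
        s_lo, s_hi = ss[i] - half, ss[i] + half
        t_lo, t_hi = tt[j] - half, tt[j] + half
    return best


def interpolated_quantile(values, q: float) -> float:
    """Linear-interpolation quantile between order statistics (from scratch)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = q * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def sphere_silhouette_area_px(center, radius, geom, voxel_inflation: float = 0.0) -> float:
    """Approximate pixel area of a sphere's silhouette on the panel.

    The tangent cone from the source scales the sphere radius by
    ``sdd / sqrt(d^2 - r^2)`` at the detector plane, with ``d`` the
    source-to-center distance (valid near the central axis).
    ``voxel_inflation`` adds the half-voxel radius growth of a
    voxel-center-rasterized sphere, whose boundary cubes protrude about
    half a voxel beyond the analytic surface.
    """
    r = radius + voxel_inflation
    d = float(np.linalg.norm(np.asarray(center, float) - geom.source))
    r_det = r * geom.sdd / np.sqrt(d * d - r * r)
    return np.pi * r_det**2 / geom.pixel_pitch**2
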