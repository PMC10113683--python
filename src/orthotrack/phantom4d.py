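"""Synthetic 10-phase breathing thorax phantom with exact ground truth.

The phantom is a body ellipsoid of soft tissue enclosing two lung
ellipsoids, an ellipsoidal tumor (the GTV) inside one lung, and optional
small high-density fiducial marker spheres rigidly co-moving with the
tumor.  The tumor translates along a fixed motion vector with a cos-power
respiratory waveform

    w(p) = [(1 - cos(2 pi p / n_phases)) / 2] ** power,

so phase 0 is the end-exhale reference (w = 0), the peak displacement is
reached mid-cycle, and power > 1 produces the clinically typical dwell
near end-exhale.  The defaults emulate the study cohort: a 7.42 cm^3 GTV
(cohort median; cohort range 1.18-25.74 cm^3), a 22 mm 3D motion range
(cohort median; range 11-28 mm), tumor mean HU in the observed -346 to -20
band, and 4 implanted markers (cohort mode of 2-5).

Because tumor and marker centers are known analytically at every phase,
the phantom provides an exact ground-truth track against which both the
markerless and the marker-based positioning chains can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_io import AIR_HU, CTVolume, GTVMask
from .tracker import Track3D

__all__ = [
    "PhantomSpec",
    "Phantom4D",
    "breathing_displacement",
    "generate_phantom",
    "ground_truth_track",
    "table1_like_spec",
]

_DEFAULT_MARKER_OFFSETS = (
    (17.0, 6.0, 9.0),
    (-15.0, 9.0, -8.0),
    (9.0, -16.0, 7.0),
    (-11.0, -12.0, -13.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and motion parameters of the synthetic thorax.

    ``motion_vector`` is the peak-to-peak tumor displacement, so the 3D
    motion range equals its norm.  ``tumor_semi_axes`` of 12.1 mm give the
    cohort-median GTV volume of 7.42 cm^3.
    """

    grid_shape: tuple[int, int, int] = (192, 192, 96)
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.0)
    body_hu: float = 0.0
    lung_hu: float = -750.0
    tumor_hu: float = -176.0
    tumor_semi_axes: tuple[float, float, float] = (12.1, 12.1, 12.1)
    tumor_center_ref: tuple[float, float, float] = (-45.0, 0.0, -20.0)
    motion_vector: tuple[float, float, float] = (2.0, 5.0, 21.33)
    n_phases: int = 10
    waveform_power: float = 2.0
    marker_offsets: tuple[tuple[float, float, float], ...] = _DEFAULT_MARKER_OFFSETS
    marker_radius_mm: float = 0.75
    marker_hu: float = 3000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("need at least 2 respiratory phases")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0 <= len(self.marker_offsets) <= 5:
            raise ValueError("marker count must be 0-5")
        half = self.half_extent_mm
        for p in range(self.n_phases):
            c = self.tumor_center(p)
            for a in range(3):
                if abs(c[a]) + self.tumor_semi_axes[a] >= half[a]:
                    raise ValueError(f"tumor leaves the grid at phase {p}")
            for off in self.marker_offsets:
                m = c + np.asarray(off)
                if np.any(np.abs(m) + self.marker_radius_mm >= half):
                    raise ValueError(f"marker leaves the grid at phase {p}")

    @property
    def half_extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing) / 2.0

    @property
    def motion_range_mm(self) -> float:
        return float(np.linalg.norm(self.motion_vector))

    @property
    def analytic_gtv_volume_cm3(self) -> float:
        a, b, c = self.tumor_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def displacement(self, phase: int) -> float:
        return breathing_displacement(phase, self.n_phases, self.waveform_power)

    def tumor_center(self, phase: int) -> np.ndarray:
        return np.asarray(self.tumor_center_ref) + self.displacement(phase) * np.asarray(self.motion_vector)


@dataclass(eq=False)
class Phantom4D:
    """Generated per-phase volumes, masks and analytic ground truth."""

    spec: PhantomSpec
    volumes: list[CTVolume]
    masks: list[GTVMask]
    gtv_centroids: list[np.ndarray]  # analytic tumor centers, mm
    marker_positions: list[list[np.ndarray]]  # per phase, per marker, mm
    reference_phase: int = 0

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    def phases(self) -> list[tuple[CTVolume, GTVMask]]:
        return list(zip(self.volumes, self.masks))

    def marker_com(self, phase: int) -> np.ndarray:
        """Analytic center of mass of the markers at a phase."""
        if not self.marker_positions[phase]:
            raise ValueError("phantom has no markers")
        return np.mean(self.marker_positions[phase], axis=0)

    def gtv_reference_offset(self) -> np.ndarray:
        """Marker-COM-to-GTV shift at the reference phase (mm)."""
        p = self.reference_phase
        return self.gtv_centroids[p] - self.marker_com(p)


def breathing_displacement(phase: int, n_phases: int = 10, power: float = 2.0) -> float:
    """Fractional tumor displacement at a respiratory phase, in [0, 1].

    ``w(p) = [(1 - cos(2 pi p / n_phases)) / 2] ** power``; phase 0 is the
    end-exhale reference (0), the maximum (1 at even ``n_phases``) occurs
    mid-cycle, and larger ``power`` lengthens the end-exhale dwell.
    """
    if not 0 <= phase < n_phases:
        raise ValueError(f"phase {phase} outside 0..{n_phases - 1}")
    return float(((1.0 - np.cos(2.0 * np.pi * phase / n_phases)) / 2.0) ** power)


def _ellipsoid_mask(centers, center, semi_axes) -> np.ndarray:
    """Voxel-center-inside rasterization of an ellipsoid (no partial volume)."""
    xs, ys, zs = centers
    q = (
        ((xs - center[0]) / semi_axes[0])[:, None, None] ** 2
        + ((ys - center[1]) / semi_axes[1])[None, :, None] ** 2
        + ((zs - center[2]) / semi_axes[2])[None, None, :] ** 2
    )
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom4D:
    """Rasterize all respiratory phases of the phantom.

    A voxel belongs to a structure iff its center lies inside the analytic
    shape; structures are painted in the order body, lungs, tumor, markers.
    Deterministic for a given spec.
    """
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing)
    origin = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * spacing  # grid centered on isocenter
    centers = tuple(origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3))

    half = spec.half_extent_mm
    body_semi = (0.88 * half[0], 0.80 * half[1], 0.95 * half[2])
    lung_semi = (0.28 * half[0], 0.40 * half[1], 0.75 * half[2])
    lung_centers = ((-0.35 * half[0], 0.0, 0.0), (0.35 * half[0], 0.0, 0.0))

    body = _ellipsoid_mask(centers, (0.0, 0.0, 0.0), body_semi)
    lungs = _ellipsoid_mask(centers, lung_centers[0], lung_semi) | _ellipsoid_mask(
        centers, lung_centers[1], lung_semi
    )
    lungs &= body
    base = np.full(shape, AIR_HU, dtype=np.float32)
    base[body] = spec.body_hu
    base[lungs] = spec.lung_hu

    volumes, masks, centroids, markers = [], [], [], []
    for p in range(spec.n_phases):
        c = spec.tumor_center(p)
        tumor = _ellipsoid_mask(centers, c, spec.tumor_semi_axes)
        if not tumor.any():
            raise ValueError(f"tumor rasterizes to no voxels at phase {p}")
        vox = base.copy()
        vox[tumor] = spec.tumor_hu
        marker_pos = [c + np.asarray(off, dtype=float) for off in spec.marker_offsets]
        r = spec.marker_radius_mm
        for m in marker_pos:
            sphere = _ellipsoid_mask(centers, m, (r, r, r))
            vox[sphere] = spec.marker_hu
        volumes.append(CTVolume(voxels=vox, spacing=spacing, origin=origin, phase=p))
        masks.append(GTVMask(voxels=tumor, phase=p))
        centroids.append(c)
        markers.append(marker_pos)
    return Phantom4D(
        spec=spec,
        volumes=volumes,
        masks=masks,
        gtv_centroids=centroids,
        marker_positions=markers,
        reference_phase=0,
    )


def ground_truth_track(phantom: Phantom4D, phase_sequence) -> Track3D:
    """Exact tumor-track for a timestamped phase sequence.

    ``phase_sequence`` is an iterable of ``(timestamp, phase)``; the
    position at each entry is the phantom's analytic GTV center for that
    phase.
    """
    timestamps, positions = [], []
    for t, p in phase_sequence:
        timestamps.append(float(t))
        positions.append(phantom.gtv_centroids[int(p)])
    return Track3D(
        timestamps=np.asarray(timestamps, dtype=float),
        positions=np.asarray(positions, dtype=float),
        sources=["truth"] * len(timestamps),
    )


def table1_like_spec(rng: np.random.Generator | int | None = None) -> PhantomSpec:
    """Random phantom spec sampled from the study-cohort ranges.

    GTV volume uniform in [1.18, 25.74] cm^3, 3D motion range uniform in
    [11, 28] mm (predominantly SI), tumor mean HU in [-346, -20], and 2-5
    markers.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    volume_cm3 = rng.uniform(1.18, 25.74)
    radius = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    motion = rng.uniform(11.0, 28.0)
    lateral = rng.uniform(0.05, 0.25, size=2) * motion  # mostly SI excursion
    si = np.sqrt(max(motion**2 - np.sum(lateral**2), 0.0))
    n_markers = int(rng.integers(2, 6))
    offsets = []
    for _ in range(n_markers):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        offsets.append(tuple(d * (radius + rng.uniform(4.0, 10.0))))
    return PhantomSpec(
        tumor_semi_axes=(radius, radius, radius),
        tumor_hu=float(rng.uniform(-346.0, -20.0)),
        motion_vector=(float(lateral[0]), float(lateral[1]), float(si)),
        marker_offsets=tuple(offsets),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
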