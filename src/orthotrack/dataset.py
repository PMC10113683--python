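"""Per-patient, per-tube-angle training-set factory.

Training data for the contour predictor are generated rather than
collected: for every respiratory phase of the 4DCT and every entry of a
small angular perturbation grid, the original CT volume and its GTV-only
companion are both projected under the identical perturbed geometry.  The
GTV mask is extracted from the GTV-only projection (any pixel with a
strictly positive radiological path) and overlaid on the original
projection as its label.

The default grid tilts the beam from -3.5 to +3.5 deg in 0.5 deg steps in
both the superior-inferior and the anterior-posterior direction: 15 angles
per direction, a 225-fold augmentation, hence 2250 labeled samples from a
10-phase 4DCT per tube angle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .ct_io import CTVolume, GTVMask, gtv_only_volume
from .drr import ProjectionImage, render_drr
from .geometry import PanelSpec, build_geometry

__all__ = [
    "PerturbationGrid",
    "LabeledSample",
    "SampleInvalidError",
    "make_grid",
    "gtv_mask_from_gtv_drr",
    "mask_boundary_polygon",
    "build_training_set",
    "export_annotations",
    "load_annotations",
]

#: radiological-path threshold defining the projected GTV footprint
MASK_PATH_EPS = 1e-6


class SampleInvalidError(ValueError):
    """The GTV projects outside the field of view for this geometry."""


@dataclass(frozen=True)
class PerturbationGrid:
    """Cartesian grid of (SI, AP) beam tilts, inclusive and symmetric."""

    range_deg: float
    step_deg: float
    entries: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.entries)


def make_grid(range_deg: float = 3.5, step_deg: float = 0.5) -> PerturbationGrid:
    """Build the augmentation grid {-range..+range} x {-range..+range}.

    ``range_deg`` must be an integer multiple of ``step_deg``; the grid has
    ``(2 * range/step + 1)**2`` entries, contains (0, 0) and is symmetric.
    Grid values are exact integer multiples of the step to avoid
    floating-point accumulation.
    """
    if step_deg <= 0:
        raise ValueError("step must be positive")
    n = range_deg / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError("range must be an integer multiple of step")
    n = int(round(n))
    values = [i * step_deg for i in range(-n, n + 1)]
    entries = tuple((si, ap) for si in values for ap in values)
    return PerturbationGrid(range_deg=float(range_deg), step_deg=float(step_deg), entries=entries)


@dataclass(eq=False)
class LabeledSample:
    """One training sample: original-volume DRR with its GTV label."""

    image: ProjectionImage
    gtv_mask: np.ndarray  # bool, same (n_u, n_v) shape as the image
    gtv_polygon: np.ndarray  # (n, 2) float (u, v) outer-boundary vertices
    phase: int
    perturbation: tuple[float, float]


def gtv_mask_from_gtv_drr(gtv_drr: ProjectionImage, eps: float = MASK_PATH_EPS) -> np.ndarray:
    """Binary GTV footprint of a GTV-only projection.

    Pixels with radiological path above ``eps``; when the footprint has
    several connected components only the largest is kept (one GTV is
    assumed).  Raises :class:`SampleInvalidError` if the footprint is
    empty.
    """
    mask = gtv_drr.path > eps
    if not mask.any():
        raise SampleInvalidError("GTV outside the field of view")
    labels, n = ndimage.label(mask)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    return mask


def mask_boundary_polygon(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of a binary mask as a counterclockwise (u, v) polygon.

    Vertices are at pixel resolution (the 0.5 iso-contour of the mask);
    for multi-component masks the longest contour is returned.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    poly = max(contours, key=len) - 1.0  # undo padding offset
    # counterclockwise orientation by the shoelace formula
    u, v = poly[:, 0], poly[:, 1]
    area2 = float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))
    if area2 < 0:
        poly = poly[::-1]
    return poly


def build_training_set(
    phases: list[tuple[CTVolume, GTVMask]],
    tube_angle: float,
    grid: PerturbationGrid | None = None,
    *,
    downsample: int = 8,
    panel: PanelSpec | None = None,
    mu_water: float | None = None,
    tube_label: str = "CW",
) -> list[LabeledSample]:
    """Render the labeled DRR set for one patient and one tube angle.

    One sample per (phase x grid entry): the original and the GTV-only
    volume are rendered under the same perturbed geometry, the mask and its
    boundary polygon are extracted from the GTV-only projection and
    attached to the original projection.  Samples whose GTV leaves the
    field of view are skipped with a warning.
    """
    if not phases:
        raise ValueError("need at least one phase")
    grid = grid or make_grid()
    render_kwargs = {} if mu_water is None else {"mu_water": mu_water}
    samples: list[LabeledSample] = []
    for volume, mask in phases:
        gtv_vol = gtv_only_volume(volume, mask)
        for si, ap in grid.entries:
            geom = build_geometry(tube_angle, si, ap, panel, tube_label=tube_label)
            original = render_drr(volume, geom, downsample, **render_kwargs)
            gtv_proj = render_drr(gtv_vol, geom, downsample, **render_kwargs)
            try:
                m = gtv_mask_from_gtv_drr(gtv_proj)
            except SampleInvalidError:
                warnings.warn(
                    f"phase {volume.phase}, perturbation ({si}, {ap}): GTV out of view; sample skipped"
                )
                continue
            samples.append(
                LabeledSample(
                    image=original,
                    gtv_mask=m,
                    gtv_polygon=mask_boundary_polygon(m),
                    phase=volume.phase,
                    perturbation=(si, ap),
                )
            )
    return samples


def export_annotations(samples: list[LabeledSample], out_dir) -> Path:
    """Write samples as PNG images plus COCO-style instance annotations.

    One image record and one polygon annotation (category "GTV") per
    sample; polygon coordinates are (u, v) pixels.  Returns the path of the
    JSON file.  The export round-trips losslessly through
    :func:`load_annotations`.
    """
    import imageio.v3 as iio

    if not samples:
        raise ValueError("no samples to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    for i, s in enumerate(samples):
        fname = f"sample_{i:05d}.png"
        iio.imwrite(str(out_dir / fname), s.image.display.T)  # rows = v
        n_u, n_v = s.image.shape
        images.append(
            {
                "id": i,
                "file_name": fname,
                "width": n_u,
                "height": n_v,
                "phase": s.phase,
                "perturb_si": s.perturbation[0],
                "perturb_ap": s.perturbation[1],
            }
        )
        poly = s.gtv_polygon
        u0, v0 = poly.min(axis=0)
        u1, v1 = poly.max(axis=0)
        annotations.append(
            {
                "id": i,
                "image_id": i,
                "category_id": 1,
                "segmentation": [[float(x) for x in poly.ravel()]],
                "bbox": [float(u0), float(v0), float(u1 - u0), float(v1 - v0)],
                "area": float(s.gtv_mask.sum()),
                "iscrowd": 0,
            }
        )
    coco = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "GTV"}],
    }
    path = out_dir / "annotations.json"
    path.write_text(json.dumps(coco, indent=1))
    return path


def load_annotations(path) -> tuple[list[dict], list[np.ndarray]]:
    """Read a COCO-style annotation file back: (image records, polygons)."""
    coco = json.loads(Path(path).read_text())
    polygons = [
        np.asarray(a["segmentation"][0], dtype=float).reshape(-1, 2) for a in coco["annotations"]
    ]
    return coco["images"], polygons
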