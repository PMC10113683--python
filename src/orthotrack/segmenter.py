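"""Pluggable per-patient, per-tube-angle GTV contour predictors.

Two backends share one contract (fit on labeled DRR samples, predict
contours on projection images):

* ``template`` — the deterministic reference backend.  Fitting stores a
  bank of image patches (the mask bounding box of each training sample,
  dilated by a margin) together with their label polygons.  Prediction
  slides every template over the query image maximizing the zero-normalized
  cross-correlation (ZNCC) and emits the best-scoring placement per
  template; the ZNCC peak ``c`` is mapped to a confidence ``(c + 1) / 2``.
  It is exact on translated noiseless inputs and makes the whole pipeline
  testable on a desktop.

* ``neural`` — an optional instance-segmentation model (ResNet + feature
  pyramid backbone with classification, box and contour losses) behind the
  identical contract.  It requires the optional ``torch`` dependency and is
  not needed by the rest of the pipeline.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import match_template

from .dataset import LabeledSample
from .drr import ProjectionImage

__all__ = [
    "BackendConfig",
    "ContourPrediction",
    "Template",
    "TrainedModel",
    "fit",
    "predict",
    "select_prediction",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BackendConfig:
    """Predictor configuration shared by both backends.

    ``confidence_threshold`` drops predictions whose mapped ZNCC score is
    below it; the default 0.8 (ZNCC 0.6) rejects the null distribution of
    correlation maxima on structureless images while true matches on
    projections of the planning anatomy score close to 1.
    ``search_window`` restricts matching to +- that many pixels around each
    template's training position (None = whole image).
    ``template_stride`` keeps every k-th training sample as a template.
    ``iterations`` and ``seed`` configure the optional neural backend.
    """

    kind: str = "template"
    confidence_threshold: float = 0.8
    search_window: int | None = None
    template_stride: int = 1
    margin_px: int = 4
    iterations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("template", "neural"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.template_stride < 1:
            raise ValueError("template_stride must be >= 1")


@dataclass(eq=False)
class ContourPrediction:
    """A predicted GTV instance on one projection image."""

    polygon: np.ndarray  # (n, 2) float (u, v)
    mask: np.ndarray  # bool, image-shaped
    confidence: float

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        u, v = self.polygon[:, 0], self.polygon[:, 1]
        area2 = abs(float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v)))
        if area2 <= 0:
            raise ValueError("degenerate prediction polygon")


@dataclass(eq=False)
class Template:
    """One stored exemplar: image patch, mask patch and label polygon.

    ``origin`` is the (u, v) pixel of the patch's top-left corner in the
    training image; the polygon is stored relative to that origin.
    """

    patch: np.ndarray  # float
    mask_patch: np.ndarray  # bool
    polygon: np.ndarray  # (n, 2) relative to patch origin
    origin: tuple[int, int]
    phase: int


@dataclass(eq=False)
class TrainedModel:
    config: BackendConfig
    tube_angle: float
    image_shape: tuple[int, int]
    templates: list[Template] = field(default_factory=list)


def _crop_template(sample: LabeledSample, margin: int) -> Template:
    mask = sample.gtv_mask
    uu, vv = np.nonzero(mask)
    n_u, n_v = mask.shape
    u0 = max(int(uu.min()) - margin, 0)
    u1 = min(int(uu.max()) + margin + 1, n_u)
    v0 = max(int(vv.min()) - margin, 0)
    v1 = min(int(vv.max()) + margin + 1, n_v)
    return Template(
        patch=sample.image.display[u0:u1, v0:v1].astype(float),
        mask_patch=mask[u0:u1, v0:v1].copy(),
        polygon=sample.gtv_polygon - np.array([u0, v0], dtype=float),
        origin=(u0, v0),
        phase=sample.phase,
    )


def fit(config: BackendConfig, samples: list[LabeledSample]) -> TrainedModel:
    """Train a contour predictor from one tube angle's labeled samples."""
    if not samples:
        raise ValueError("no training samples")
    angles = {s.image.geometry.tube_angle for s in samples}
    if len(angles) != 1:
        raise ValueError(f"samples mix tube angles {sorted(angles)}; train one model per angle")
    if config.kind == "neural":
        return _fit_neural(config, samples)
    shape = samples[0].image.shape
    templates = [_crop_template(s, config.margin_px) for s in samples[:: config.template_stride]]
    return TrainedModel(config=config, tube_angle=angles.pop(), image_shape=shape, templates=templates)


def _fit_neural(config: BackendConfig, samples):  # pragma: no cover - optional extra
    try:
        import torch  # noqa: F401
    except ImportError as err:
        raise ImportError(
            "the neural backend needs the optional 'torch' dependency; "
            "use the template backend otherwise"
        ) from err
    raise NotImplementedError("neural backend training is not bundled")


def predict(model: TrainedModel, image: ProjectionImage) -> list[ContourPrediction]:
    """Predict GTV contours on a projection image.

    For each template the ZNCC is maximized over the search region; the
    template's mask and polygon are translated to the argmax and emitted
    with confidence ``(zncc + 1) / 2``.  Predictions below the confidence
    threshold are dropped; the rest are sorted by confidence descending
    (stable, so ties keep template order).
    """
    if image.shape != model.image_shape:
        raise ValueError(f"image shape {image.shape} differs from training shape {model.image_shape}")
    img = image.display.astype(float)
    n_u, n_v = image.shape
    w = model.config.search_window
    predictions: list[ContourPrediction] = []
    for tmpl in model.templates:
        tu, tv = tmpl.patch.shape
        if w is None:
            ru0, rv0 = 0, 0
            region = img
        else:
            ru0 = max(tmpl.origin[0] - w, 0)
            rv0 = max(tmpl.origin[1] - w, 0)
            region = img[ru0 : min(tmpl.origin[0] + tu + w, n_u), rv0 : min(tmpl.origin[1] + tv + w, n_v)]
        if region.shape[0] < tu or region.shape[1] < tv:
            continue
        corr = match_template(region, tmpl.patch)
        peak = int(np.argmax(corr))
        du, dv = np.unravel_index(peak, corr.shape)
        c = float(corr[du, dv])
        confidence = (c + 1.0) / 2.0
        if confidence < model.config.confidence_threshold:
            continue
        u0, v0 = ru0 + int(du), rv0 + int(dv)
        mask = np.zeros(model.image_shape, dtype=bool)
        mask[u0 : u0 + tu, v0 : v0 + tv] = tmpl.mask_patch
        predictions.append(
            ContourPrediction(
                polygon=tmpl.polygon + np.array([u0, v0], dtype=float),
                mask=mask,
                confidence=confidence,
            )
        )
    predictions.sort(key=lambda p: -p.confidence)  # stable: ties keep template order
    return predictions


def select_prediction(predictions: list[ContourPrediction]) -> ContourPrediction | None:
    """Highest-confidence prediction, or None (one GTV instance per image)."""
    return predictions[0] if predictions else None


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to a single archive file."""
    Path(path).write_bytes(pickle.dumps(model))


def load_model(path) -> TrainedModel:
    return pickle.loads(Path(path).read_bytes())
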