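"""End-to-end simulation: phantom -> training sets -> models -> tracking -> report.

One run emulates a treatment course on the synthetic phantom: per tube
angle a labeled DRR training set is built and a contour predictor fitted;
then, frame by frame, orthogonal projections of the breathing phantom are
rendered, contours predicted on both tubes, the 3D position triangulated,
and the marker-based chain simulated by forward-projecting the analytic
marker positions (optionally quantized to whole detector pixels).  The
per-frame outcome log is aggregated into an :class:`EvaluationReport`.

All randomness (only the optional projection noise) derives from the
single ``rng_seed`` fanned out per stage by stable hashing, so a run is
fully reproducible from its config.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import dataset as ds
from . import segmenter as seg
from .drr import ProjectionImage, display_from_path, render_drr
from .evalstats import EvaluationReport, build_report, plot_cumulative
from .geometry import PanelSpec, build_geometry, project_point, tube_angles_for_gantry
from .phantom4d import Phantom4D, PhantomSpec, generate_phantom, ground_truth_track
from .segmenter import select_prediction
from .tracker import MarkerSet, Track3D, marker_ground_truth, position_from_pair

__all__ = ["RunConfig", "RunResult", "stage_seed", "run_end_to_end"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PhantomSettings(BaseModel):
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
    n_markers: int = 4

    def to_spec(self, rng_seed: int = 0) -> PhantomSpec:
        from .phantom4d import _DEFAULT_MARKER_OFFSETS

        return PhantomSpec(
            grid_shape=self.grid_shape,
            spacing=self.spacing,
            body_hu=self.body_hu,
            lung_hu=self.lung_hu,
            tumor_hu=self.tumor_hu,
            tumor_semi_axes=self.tumor_semi_axes,
            tumor_center_ref=self.tumor_center_ref,
            motion_vector=self.motion_vector,
            n_phases=self.n_phases,
            waveform_power=self.waveform_power,
            marker_offsets=_DEFAULT_MARKER_OFFSETS[: self.n_markers],
            rng_seed=rng_seed,
        )


class GridSettings(BaseModel):
    range_deg: float = 3.5
    step_deg: float = 0.5


class RenderSettings(BaseModel):
    downsample: int = 8
    mu_water: float = 0.02


class BackendSettings(BaseModel):
    kind: str = "template"
    confidence_threshold: float = 0.8
    search_window: int | None = 24
    template_stride: int = 1
    margin_px: int = 4

    def to_config(self) -> seg.BackendConfig:
        return seg.BackendConfig(
            kind=self.kind,
            confidence_threshold=self.confidence_threshold,
            search_window=self.search_window,
            template_stride=self.template_stride,
            margin_px=self.margin_px,
        )


class TestSettings(BaseModel):
    n_cycles: int = 1
    noise_sigma: float = 0.0  # additive Gaussian noise on the 8-bit display
    quantize_markers: bool = True


class RunConfig(BaseModel):
    """Validated configuration of one end-to-end run."""

    phantom: PhantomSettings = Field(default_factory=PhantomSettings)
    gantry_angles: list[float] = Field(default_factory=lambda: [0.0])
    grid: GridSettings = Field(default_factory=GridSettings)
    render: RenderSettings = Field(default_factory=RenderSettings)
    backend: BackendSettings = Field(default_factory=BackendSettings)
    test: TestSettings = Field(default_factory=TestSettings)
    thresholds_mm: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0, 5.0])
    patient: int = 1
    n_fractions: int = 1
    output_dir: str | None = None
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


@dataclass(eq=False)
class RunResult:
    report: EvaluationReport
    markerless_track: Track3D
    marker_track: Track3D
    truth_track: Track3D
    frames: pd.DataFrame
    models: dict
    phantom: Phantom4D


def _add_noise(image: ProjectionImage, sigma: float, rng: np.random.Generator) -> ProjectionImage:
    if sigma <= 0:
        return image
    noisy = image.display.astype(float) + rng.normal(0.0, sigma, size=image.display.shape)
    return ProjectionImage(
        path=image.path,
        display=np.clip(np.rint(noisy), 0, 255).astype(np.uint8),
        geometry=image.geometry,
        phase_or_timestamp=image.phase_or_timestamp,
    )


def _simulate_markers(
    phantom: Phantom4D, phase: int, geom_cw, geom_ccw, quantize: bool
) -> MarkerSet | None:
    """Forward-project the analytic marker positions onto both panels."""
    if not phantom.marker_positions[phase]:
        return None
    per_tube = []
    for geom in (geom_cw, geom_ccw):
        uv = []
        for m in phantom.marker_positions[phase]:
            u, v = project_point(geom, m)
            if not (0 <= u <= geom.n_u - 1 and 0 <= v <= geom.n_v - 1):
                return None  # marker off-panel: frame not detected
            uv.append((round(u), round(v)) if quantize else (u, v))
        per_tube.append(np.asarray(uv, dtype=float))
    return MarkerSet(
        centroids_cw=per_tube[0],
        centroids_ccw=per_tube[1],
        reference_offset=phantom.gtv_reference_offset(),
    )


def run_end_to_end(config: RunConfig) -> RunResult:
    """Run the full workflow on the synthetic phantom and score it.

    Returns the evaluation report plus the markerless, marker-based and
    analytic ground-truth tracks; artifacts are written under
    ``config.output_dir`` when set.  Deviations in the report compare the
    markerless against the marker-based positions, mirroring the clinical
    accounting; the analytic track allows both chains to be scored
    absolutely.
    """
    spec = config.phantom.to_spec(rng_seed=config.rng_seed)
    phantom = generate_phantom(spec)
    phases = phantom.phases()
    grid = ds.make_grid(config.grid.range_deg, config.grid.step_deg)
    panel = PanelSpec()
    backend = config.backend.to_config()

    models: dict[tuple[float, str], seg.TrainedModel] = {}
    for g in config.gantry_angles:
        cw, ccw = tube_angles_for_gantry(g)
        for label, angle in (("CW", cw), ("CCW", ccw)):
            samples = ds.build_training_set(
                phases,
                angle,
                grid,
                downsample=config.render.downsample,
                panel=panel,
                mu_water=config.render.mu_water,
                tube_label=label,
            )
            models[(g, label)] = seg.fit(backend, samples)

    rng = np.random.default_rng(stage_seed(config.rng_seed, "projection-noise"))
    rows = []
    track_t, track_p = [], []
    marker_t, marker_p = [], []
    truth_entries = []
    t_idx = 0
    for fraction in range(1, config.n_fractions + 1):
        for g in config.gantry_angles:
            cw, ccw = tube_angles_for_gantry(g)
            geom_cw = build_geometry(cw, panel=panel, tube_label="CW")
            geom_ccw = build_geometry(ccw, panel=panel, tube_label="CCW")
            geom_cw_ds = geom_cw.downsampled(config.render.downsample)
            geom_ccw_ds = geom_ccw.downsampled(config.render.downsample)
            for _cycle in range(config.test.n_cycles):
                for phase in range(spec.n_phases):
                    timestamp = 100.0 * t_idx
                    t_idx += 1
                    volume = phantom.volumes[phase]
                    preds = {}
                    for label, geom in (("CW", geom_cw), ("CCW", geom_ccw)):
                        img = render_drr(
                            volume,
                            geom,
                            config.render.downsample,
                            mu_water=config.render.mu_water,
                            phase_or_timestamp=timestamp,
                        )
                        img = _add_noise(img, config.test.noise_sigma, rng)
                        preds[label] = select_prediction(seg.predict(models[(g, label)], img))
                    pos = position_from_pair(preds["CW"], preds["CCW"], geom_cw_ds, geom_ccw_ds)
                    markers = _simulate_markers(
                        phantom, phase, geom_cw, geom_ccw, config.test.quantize_markers
                    )
                    gt = None if markers is None else marker_ground_truth(markers, geom_cw, geom_ccw)
                    deviation = float(np.linalg.norm(pos - gt)) if pos is not None and gt is not None else np.nan
                    rows.append(
                        {
                            "patient": config.patient,
                            "fraction": fraction,
                            "timestamp": timestamp,
                            "gantry_angle": g,
                            "phase": phase,
                            "marker_detected": gt is not None,
                            "markerless_predicted": pos is not None,
                            "deviation": deviation,
                        }
                    )
                    truth_entries.append((timestamp, phase))
                    if pos is not None:
                        track_t.append(timestamp)
                        track_p.append(pos)
                    if gt is not None:
                        marker_t.append(timestamp)
                        marker_p.append(gt)

    frames = pd.DataFrame(rows)
    patient_meta = pd.DataFrame(
        {
            "gtv_volume_cm3": [spec.analytic_gtv_volume_cm3],
            "motion_range_mm": [spec.motion_range_mm],
        },
        index=pd.Index([config.patient], name="patient"),
    )
    report = build_report(frames, patient_meta=patient_meta, thresholds=tuple(config.thresholds_mm))
    result = RunResult(
        report=report,
        markerless_track=Track3D(np.asarray(track_t), np.asarray(track_p).reshape(-1, 3)),
        marker_track=Track3D(
            np.asarray(marker_t), np.asarray(marker_p).reshape(-1, 3), sources=["marker"] * len(marker_t)
        ),
        truth_track=ground_truth_track(phantom, truth_entries),
        frames=frames,
        models=models,
        phantom=phantom,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_csv_tables(out)
        result.markerless_track.to_csv(out / "markerless_track.csv")
        result.marker_track.to_csv(out / "marker_track.csv")
        result.truth_track.to_csv(out / "truth_track.csv")
        frames.to_csv(out / "frames.csv", index=False)
        if report.n_compared:
            plot_cumulative(report, out / "cumulative.png")
    return result
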