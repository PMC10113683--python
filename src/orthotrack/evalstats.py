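"""Tracking evaluation statistics.

Deviation distributions, cumulative percentage curves, prediction /
detection rates and Pearson correlations, with the frame accounting used
clinically: a stored orthogonal image pair counts as *predicted* when the
markerless chain produced a 3D position (valid contours on both tubes), as
*detected* when the marker-based chain produced one, and enters the
deviation comparison only when both did.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracker import Track3D

__all__ = [
    "EvaluationReport",
    "deviations",
    "summarize",
    "prediction_rate",
    "pearson",
    "build_report",
    "plot_cumulative",
]

DEFAULT_THRESHOLDS_MM = (1.0, 2.0, 3.0, 5.0)


def deviations(pred: Track3D, truth: Track3D) -> np.ndarray:
    """3D deviations [mm] between two tracks at their common timestamps.

    Euclidean norm of the position difference per timestamp present in both
    tracks (inner join); raises if the tracks share no timestamps.
    """
    common, ia, ib = np.intersect1d(pred.timestamps, truth.timestamps, return_indices=True)
    if len(common) == 0:
        raise ValueError("tracks share no timestamps")
    return np.linalg.norm(pred.positions[ia] - truth.positions[ib], axis=1)


def summarize(
    devs, thresholds=DEFAULT_THRESHOLDS_MM
) -> tuple[float, tuple[float, float], list[tuple[float, float]]]:
    """Median, interquartile range and cumulative percentages of deviations.

    Quartiles use linear interpolation between order statistics; the
    cumulative value at threshold ``t`` is ``100 * |{d <= t}| / n``.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.size == 0:
        raise ValueError("no deviations to summarize")
    median = float(np.median(devs))
    q1, q3 = (float(q) for q in np.percentile(devs, [25.0, 75.0]))
    cumulative = [(float(t), float(100.0 * np.mean(devs <= t))) for t in thresholds]
    return median, (q1, q3), cumulative


def prediction_rate(n_predicted: int, n_total: int) -> float:
    """Percentage of stored frame pairs that yielded a 3D position."""
    if n_total <= 0:
        raise ValueError("total frame count must be positive")
    if not 0 <= n_predicted <= n_total:
        raise ValueError("predicted count outside [0, total]")
    return 100.0 * n_predicted / n_total


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("degenerate (zero-variance) sample")
    return float((xc @ yc) / (sx * sy))


@dataclass(eq=False)
class EvaluationReport:
    """Full evaluation of a tracking run.

    Frame accounting: ``n_compared <= min(n_marker_detected,
    n_markerless_predicted) <= n_pairs_total``.  ``correlations`` holds
    Pearson r of (median deviation, prediction rate) against (GTV volume,
    motion range, fraction index); ``correlations_excluded`` repeats the
    analysis with one patient left out (NaN where fewer than 3 groups or
    degenerate).
    """

    n_pairs_total: int
    n_marker_detected: int
    n_markerless_predicted: int
    n_compared: int
    deviations: np.ndarray
    median: float
    iqr_low: float
    iqr_high: float
    cumulative: list[tuple[float, float]]
    per_patient: pd.DataFrame
    per_fraction: pd.DataFrame
    correlations: pd.DataFrame
    correlations_excluded: pd.DataFrame | None = None
    excluded_patient: object = None

    @property
    def overall_prediction_rate(self) -> float:
        return prediction_rate(self.n_markerless_predicted, self.n_pairs_total)

    @property
    def marker_detection_rate(self) -> float:
        return prediction_rate(self.n_marker_detected, self.n_pairs_total)

    def to_dict(self) -> dict:
        return {
            "n_pairs_total": self.n_pairs_total,
            "n_marker_detected": self.n_marker_detected,
            "n_markerless_predicted": self.n_markerless_predicted,
            "n_compared": self.n_compared,
            "median_mm": self.median,
            "iqr_mm": [self.iqr_low, self.iqr_high],
            "cumulative_pct": {f"{t:g}": p for t, p in self.cumulative},
            "prediction_rate_pct": self.overall_prediction_rate,
            "marker_detection_rate_pct": self.marker_detection_rate,
            "per_patient": self.per_patient.to_dict(orient="index"),
            "per_fraction": self.per_fraction.to_dict(orient="index"),
            "correlations": _corr_to_dict(self.correlations),
            "correlations_excluded": _corr_to_dict(self.correlations_excluded),
            "excluded_patient": self.excluded_patient,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def to_csv_tables(self, out_dir) -> None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_patient.to_csv(out_dir / "per_patient.csv")
        self.per_fraction.to_csv(out_dir / "per_fraction.csv")
        self.correlations.to_csv(out_dir / "correlations.csv")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _corr_to_dict(df: pd.DataFrame | None):
    if df is None:
        return None
    out = df.to_dict(orient="index")
    return {k: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()} for k, row in out.items()}


def _group_table(frames: pd.DataFrame, key: str) -> pd.DataFrame:
    rows = {}
    for g, grp in frames.groupby(key, sort=True):
        devs = grp.loc[grp["compared"], "deviation"].to_numpy(dtype=float)
        if devs.size:
            median, (q1, q3), _ = summarize(devs)
        else:
            median = q1 = q3 = float("nan")
        rows[g] = {
            "n_pairs": int(len(grp)),
            "n_compared": int(grp["compared"].sum()),
            "median_mm": median,
            "iqr_low_mm": q1,
            "iqr_high_mm": q3,
            "prediction_rate_pct": prediction_rate(int(grp["markerless_predicted"].sum()), len(grp)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _safe_pearson(x, y) -> float:
    try:
        return pearson(x, y)
    except ValueError:
        return float("nan")


def _correlation_table(
    per_patient: pd.DataFrame, per_fraction: pd.DataFrame, patient_meta: pd.DataFrame | None
) -> pd.DataFrame:
    cols = {"gtv_volume_cm3": float("nan"), "motion_range_mm": float("nan"), "fraction_index": float("nan")}
    table = {"median_3d_deviation": dict(cols), "prediction_rate": dict(cols)}
    if patient_meta is not None and len(per_patient):
        meta = patient_meta.loc[patient_meta.index.intersection(per_patient.index)]
        pp = per_patient.loc[meta.index]
        for col, name in (("gtv_volume_cm3", "gtv_volume_cm3"), ("motion_range_mm", "motion_range_mm")):
            if name in meta.columns:
                table["median_3d_deviation"][col] = _safe_pearson(meta[name], pp["median_mm"])
                table["prediction_rate"][col] = _safe_pearson(meta[name], pp["prediction_rate_pct"])
    if len(per_fraction):
        idx = per_fraction.index.to_numpy(dtype=float)
        table["median_3d_deviation"]["fraction_index"] = _safe_pearson(idx, per_fraction["median_mm"])
        table["prediction_rate"]["fraction_index"] = _safe_pearson(idx, per_fraction["prediction_rate_pct"])
    return pd.DataFrame.from_dict(table, orient="index")


def build_report(
    frames: pd.DataFrame,
    patient_meta: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS_MM,
    exclude_patient=None,
) -> EvaluationReport:
    """Aggregate a per-frame outcome log into an evaluation report.

    ``frames`` needs columns ``patient``, ``fraction``, ``timestamp``,
    ``marker_detected`` (bool), ``markerless_predicted`` (bool) and
    ``deviation`` (mm; NaN where no comparison exists).  ``patient_meta``,
    indexed by patient, may carry ``gtv_volume_cm3`` and
    ``motion_range_mm`` for the correlation analysis.  When
    ``exclude_patient`` is given, the correlations are also recomputed with
    that patient's frames removed.
    """
    required = {"patient", "fraction", "timestamp", "marker_detected", "markerless_predicted", "deviation"}
    missing = required - set(frames.columns)
    if missing:
        raise ValueError(f"frame log misses columns {sorted(missing)}")
    frames = frames.copy()
    frames["compared"] = (
        frames["marker_detected"] & frames["markerless_predicted"] & frames["deviation"].notna()
    )
    devs = frames.loc[frames["compared"], "deviation"].to_numpy(dtype=float)
    if devs.size:
        median, (q1, q3), cumulative = summarize(devs, thresholds)
    else:
        median = q1 = q3 = float("nan")
        cumulative = [(float(t), float("nan")) for t in thresholds]
    per_patient = _group_table(frames, "patient")
    per_fraction = _group_table(frames, "fraction")
    correlations = _correlation_table(per_patient, per_fraction, patient_meta)
    correlations_excluded = None
    if exclude_patient is not None:
        kept = frames[frames["patient"] != exclude_patient]
        meta = None if patient_meta is None else patient_meta.drop(index=exclude_patient, errors="ignore")
        correlations_excluded = _correlation_table(
            _group_table(kept, "patient"), _group_table(kept, "fraction"), meta
        )
    return EvaluationReport(
        n_pairs_total=int(len(frames)),
        n_marker_detected=int(frames["marker_detected"].sum()),
        n_markerless_predicted=int(frames["markerless_predicted"].sum()),
        n_compared=int(frames["compared"].sum()),
        deviations=devs,
        median=median,
        iqr_low=q1,
        iqr_high=q3,
        cumulative=cumulative,
        per_patient=per_patient,
        per_fraction=per_fraction,
        correlations=correlations,
        correlations_excluded=correlations_excluded,
        excluded_patient=exclude_patient,
    )


def plot_cumulative(report: EvaluationReport, path) -> None:
    """Cumulative percentage curve of the 3D deviation (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    devs = np.sort(report.deviations)
    pct = 100.0 * np.arange(1, devs.size + 1) / devs.size
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(devs, pct, where="post")
    ax.set_xlabel("3D deviation [mm]")
    ax.set_ylabel("cumulative percentage [%]")
    ax.set_ylim(0, 100)
    ax.grid(True, alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
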