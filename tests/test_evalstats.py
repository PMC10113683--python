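import numpy as np
import pandas as pd
import pytest
from _oracles import interpolated_quantile
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from orthotrack.evalstats import (
    build_report,
    deviations,
    pearson,
    prediction_rate,
    summarize,
)
from orthotrack.tracker import Track3D


def _track(ts, pos):
    return Track3D(timestamps=np.asarray(ts, float), positions=np.asarray(pos, float))


def test_identical_tracks_deviate_by_zero():
    t = _track([0, 1, 2], np.arange(9.0).reshape(3, 3))
    np.testing.assert_array_equal(deviations(t, t), [0, 0, 0])


def test_constant_shift_is_345():
    ts = [0, 1, 2, 3]
    pos = np.arange(12.0).reshape(4, 3)
    truth = _track(ts, pos)
    pred = _track(ts, pos + np.array([3.0, 4.0, 0.0]))
    np.testing.assert_allclose(deviations(pred, truth), [5.0] * 4)


def test_deviations_inner_join_and_oracle(rng):
    pa = rng.normal(size=(6, 3))
    pb = rng.normal(size=(6, 3))
    a = _track([0, 1, 2, 3, 4, 5], pa)
    b = _track([2, 3, 4, 5, 6, 7], pb)
    devs = deviations(a, b)
    assert len(devs) == 4  # timestamps 2..5
    expected = [np.sqrt(np.sum((pa[2 + i] - pb[i]) ** 2)) for i in range(4)]
    np.testing.assert_allclose(devs, expected)
    with pytest.raises(ValueError):
        deviations(a, _track([100.0], [[0, 0, 0]]))


def test_summarize_small_sample():
    median, (q1, q3), cum = summarize([1.0, 2.0, 3.0, 4.0, 5.0], thresholds=(3.0,))
    assert median == 3.0 and (q1, q3) == (2.0, 4.0)
    assert cum == [(3.0, 60.0)]


def test_summarize_step_behavior_at_threshold():
    devs = [2.0] * 7
    _, _, cum = summarize(devs, thresholds=(1.99, 2.0))
    assert cum == [(1.99, 0.0), (2.0, 100.0)]


def test_summarize_matches_independent_quantile_oracle(rng):
    devs = rng.lognormal(0.5, 0.6, size=1000)
    median, (q1, q3), _ = summarize(devs)
    assert median == pytest.approx(interpolated_quantile(devs, 0.5), abs=1e-9)
    assert q1 == pytest.approx(interpolated_quantile(devs, 0.25), abs=1e-9)
    assert q3 == pytest.approx(interpolated_quantile(devs, 0.75), abs=1e-9)


@given(st.lists(st.floats(min_value=0, max_value=50, allow_nan=False), min_size=2, max_size=40))
def test_summarize_permutation_invariant_and_cumulative_monotone(devs):
    a = summarize(devs, thresholds=(1.0, 2.0, 3.0, 5.0))
    b = summarize(list(reversed(devs)), thresholds=(1.0, 2.0, 3.0, 5.0))
    assert a == b
    pct = [p for _, p in a[2]]
    assert pct == sorted(pct)
    _, _, at_max = summarize(devs, thresholds=(max(devs),))
    assert at_max[0][1] == 100.0


@pytest.mark.parametrize(
    "n_pred,n_total,expected",
    [(10242, 15140, 67.6), (13244, 15140, 87.5), (0, 100, 0.0)],
)
def test_prediction_rate_reproduces_clinical_ratios(n_pred, n_total, expected):
    assert round(prediction_rate(n_pred, n_total), 1) == expected


def test_prediction_rate_guards():
    with pytest.raises(ValueError):
        prediction_rate(1, 0)
    with pytest.raises(ValueError):
        prediction_rate(5, 4)


def test_pearson_exact_cases_and_oracle(rng):
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson(x, -x) == pytest.approx(-1.0)
    a, b = rng.normal(size=50), rng.normal(size=50)
    assert pearson(a, b) == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])


def _frames(rng, n_patients=2, n_fractions=2, n=25):
    rows = []
    t = 0.0
    for p in range(1, n_patients + 1):
        for f in range(1, n_fractions + 1):
            for _ in range(n):
                detected = rng.random() < 0.9
                predicted = rng.random() < 0.7
                dev = abs(rng.normal(2.0, 1.0)) if (detected and predicted) else np.nan
                rows.append(
                    {
                        "patient": p,
                        "fraction": f,
                        "timestamp": t,
                        "marker_detected": detected,
                        "markerless_predicted": predicted,
                        "deviation": dev,
                    }
                )
                t += 1.0
    return pd.DataFrame(rows)


def test_report_schema_and_counting_invariants(rng):
    frames = _frames(rng)
    report = build_report(frames, exclude_patient=2)
    assert report.n_compared <= min(report.n_marker_detected, report.n_markerless_predicted)
    assert min(report.n_marker_detected, report.n_markerless_predicted) <= report.n_pairs_total
    assert list(report.per_patient.index) == [1, 2]
    assert list(report.per_fraction.index) == [1, 2]
    for col in ("median_mm", "iqr_low_mm", "iqr_high_mm", "prediction_rate_pct"):
        assert col in report.per_patient.columns
    assert report.iqr_low <= report.median <= report.iqr_high
    assert report.correlations.shape == (2, 3)
    assert report.correlations_excluded is not None
    # counting oracle straight from the log
    assert report.n_compared == int(
        (frames.marker_detected & frames.markerless_predicted & frames.deviation.notna()).sum()
    )
    assert report.overall_prediction_rate == pytest.approx(
        100.0 * frames.markerless_predicted.mean()
    )


def test_fraction_index_correlation_is_one_for_linear_medians():
    rows = []
    t = 0.0
    for f, dev in [(1, 1.0), (2, 2.0), (3, 3.0), (4, 4.0)]:
        for _ in range(5):
            rows.append(
                {
                    "patient": 1,
                    "fraction": f,
                    "timestamp": t,
                    "marker_detected": True,
                    "markerless_predicted": True,
                    "deviation": dev,
                }
            )
            t += 1.0
    report = build_report(pd.DataFrame(rows))
    assert report.correlations.loc["median_3d_deviation", "fraction_index"] == pytest.approx(1.0)


def test_report_json_round_trip_is_deterministic(rng):
    import json

    frames = _frames(rng, n=10)
    a = build_report(frames).to_json()
    b = build_report(frames).to_json()
    assert a == b
    payload = json.loads(a)
    assert payload["n_pairs_total"] == len(frames)


def test_report_requires_columns():
    with pytest.raises(ValueError, match="columns"):
        build_report(pd.DataFrame({"patient": [1]}))
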