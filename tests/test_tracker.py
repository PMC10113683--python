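import numpy as np
import pytest
from _oracles import closest_point_grid_search
from hypothesis import given
from hypothesis import strategies as st

from orthotrack.geometry import Ray, build_geometry, project_point, ray_through_pixel
from orthotrack.tracker import (
    MarkerSet,
    Track3D,
    TriangulationError,
    marker_ground_truth,
    mask_centroid,
    position_from_pair,
    triangulate_midpoint,
)


class _Pred:
    def __init__(self, mask):
        self.mask = mask


def test_mask_centroid_single_pixel_and_block():
    m = np.zeros((64, 64), bool)
    m[10, 20] = True
    assert mask_centroid(_Pred(m)) == (10.0, 20.0)
    m2 = np.zeros((64, 64), bool)
    m2[0:2, 0:2] = True
    assert mask_centroid(_Pred(m2)) == (0.5, 0.5)


def test_mask_centroid_of_rasterized_disc():
    uu, vv = np.meshgrid(np.arange(64, dtype=float), np.arange(80, dtype=float), indexing="ij")
    disc = (uu - 30.25) ** 2 + (vv - 40.75) ** 2 <= 12.0**2
    cu, cv = mask_centroid(_Pred(disc))
    assert abs(cu - 30.25) < 0.1 and abs(cv - 40.75) < 0.1


def test_mask_centroid_empty_rejected():
    with pytest.raises(ValueError):
        mask_centroid(_Pred(np.zeros((4, 4), bool)))


def test_intersecting_rays_triangulate_to_intersection():
    a = Ray(origin=(-1000.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0))
    b = Ray(origin=(0.0, -1000.0, 0.0), direction=(0.0, 1.0, 0.0))
    np.testing.assert_allclose(triangulate_midpoint(a, b), [0, 0, 0], atol=1e-12)


def test_skew_lines_match_grid_search_oracle():
    a = Ray(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0))  # the x axis
    b = Ray(origin=(0.0, 1.0, 2.0), direction=(1.0, 0.0, -1.0))  # {(t, 1, 2 - t)}
    closed_form = triangulate_midpoint(a, b)
    brute = closest_point_grid_search(a, b, span=6.0)
    np.testing.assert_allclose(closed_form, brute, atol=1e-3)


def test_parallel_rays_rejected():
    a = Ray(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0))
    b = Ray(origin=(0.0, 5.0, 0.0), direction=(1.0, 0.0, 0.0))
    with pytest.raises(TriangulationError):
        triangulate_midpoint(a, b)


vec = st.floats(min_value=-1.0, max_value=1.0, allow_nan=False)


@given(
    oa=st.tuples(vec, vec, vec),
    ob=st.tuples(vec, vec, vec),
    da=st.tuples(vec, vec, vec),
    db=st.tuples(vec, vec, vec),
)
def test_midpoint_symmetric_under_ray_swap(oa, ob, da, db):
    try:
        a = Ray(origin=np.asarray(oa) * 100, direction=da)
        b = Ray(origin=np.asarray(ob) * 100 + 7.0, direction=db)
        m1 = triangulate_midpoint(a, b)
        m2 = triangulate_midpoint(b, a)
    except (ValueError, TriangulationError):
        return
    np.testing.assert_allclose(m1, m2, atol=1e-9)


def _pair():
    return build_geometry(45.0, tube_label="CW"), build_geometry(315.0, tube_label="CCW")


def test_noiseless_point_targets_recovered_exactly(rng):
    g_cw, g_ccw = _pair()
    for _ in range(200):
        p = rng.uniform(-30, 30, size=3)
        r1 = ray_through_pixel(g_cw, *project_point(g_cw, p))
        r2 = ray_through_pixel(g_ccw, *project_point(g_ccw, p))
        assert np.linalg.norm(triangulate_midpoint(r1, r2) - p) < 1e-6


def test_pixel_quantization_error_bounded(rng):
    """Whole-pixel centroids stay within sqrt(2) * isocenter pixel scale in 3D."""
    g_cw, g_ccw = _pair()
    bound = np.sqrt(2) * g_cw.isocenter_pixel_mm
    for _ in range(1000):
        p = rng.uniform(-30, 30, size=3)
        uv1 = np.rint(project_point(g_cw, p))
        uv2 = np.rint(project_point(g_ccw, p))
        r1 = ray_through_pixel(g_cw, *uv1)
        r2 = ray_through_pixel(g_ccw, *uv2)
        assert np.linalg.norm(triangulate_midpoint(r1, r2) - p) <= bound


def test_position_from_pair_requires_both_predictions():
    g_cw, g_ccw = _pair()
    mask = np.zeros((64, 48), bool)
    mask[30, 20] = True
    assert position_from_pair(None, _Pred(mask), g_cw, g_ccw) is None
    assert position_from_pair(_Pred(mask), None, g_cw, g_ccw) is None


def test_position_from_pair_rejects_same_tube():
    g = build_geometry(45.0)
    with pytest.raises(ValueError):
        position_from_pair(None, None, g, g)


def test_position_from_pair_recovers_projected_target(rng):
    g_cw, g_ccw = _pair()
    g_cw8, g_ccw8 = g_cw.downsampled(8), g_ccw.downsampled(8)
    p = np.array([5.0, -8.0, 12.0])
    masks = []
    for g in (g_cw8, g_ccw8):
        u, v = project_point(g, p)
        m = np.zeros((g.n_u, g.n_v), bool)
        m[int(round(u)), int(round(v))] = True
        masks.append(m)
    pos = position_from_pair(_Pred(masks[0]), _Pred(masks[1]), g_cw8, g_ccw8)
    assert np.linalg.norm(pos - p) <= np.sqrt(2) * g_cw8.isocenter_pixel_mm


def test_marker_ground_truth_symmetric_markers_recover_center():
    g_cw, g_ccw = _pair()
    center = np.array([3.0, -4.0, 10.0])
    offsets = [np.array([10.0, 0, 0]), np.array([-10.0, 0, 0]), np.array([0, 8.0, 0]), np.array([0, -8.0, 0])]
    uv_cw = [project_point(g_cw, center + o) for o in offsets]
    uv_ccw = [project_point(g_ccw, center + o) for o in offsets]
    ms = MarkerSet(centroids_cw=uv_cw, centroids_ccw=uv_ccw)
    got = marker_ground_truth(ms, g_cw, g_ccw)
    # the mean of projected points equals the projection of the mean only to
    # first order; sub-0.05 mm agreement at these offsets
    assert np.linalg.norm(got - center) < 0.05


def test_marker_reference_offset_is_additive():
    g_cw, g_ccw = _pair()
    center = np.zeros(3)
    uv_cw = [project_point(g_cw, center)]
    uv_ccw = [project_point(g_ccw, center)]
    ms = MarkerSet(centroids_cw=uv_cw, centroids_ccw=uv_ccw, reference_offset=(0.0, 0.0, 5.0))
    np.testing.assert_allclose(marker_ground_truth(ms, g_cw, g_ccw), [0, 0, 5.0], atol=1e-9)


def test_marker_quantized_detection_error_bounded(small_phantom):
    """Quantized marker detections locate the GTV within ~2x the isocenter pixel scale."""
    g_cw, g_ccw = _pair()
    phase = 4
    uv_cw = [np.rint(project_point(g_cw, m)) for m in small_phantom.marker_positions[phase]]
    uv_ccw = [np.rint(project_point(g_ccw, m)) for m in small_phantom.marker_positions[phase]]
    ms = MarkerSet(
        centroids_cw=uv_cw, centroids_ccw=uv_ccw, reference_offset=small_phantom.gtv_reference_offset()
    )
    got = marker_ground_truth(ms, g_cw, g_ccw)
    assert np.linalg.norm(got - small_phantom.gtv_centroids[phase]) <= 2 * g_cw.isocenter_pixel_mm


def test_markerset_requires_markers():
    with pytest.raises(ValueError):
        MarkerSet(centroids_cw=np.empty((0, 2)), centroids_ccw=[(1.0, 2.0)])


def test_track_requires_increasing_timestamps(tmp_path):
    with pytest.raises(ValueError):
        Track3D(timestamps=[0.0, 0.0], positions=np.zeros((2, 3)))
    t = Track3D(timestamps=[0.0, 1.0, 2.0], positions=np.arange(9.0).reshape(3, 3))
    t.to_csv(tmp_path / "t.csv")
    back = Track3D.from_csv(tmp_path / "t.csv")
    np.testing.assert_allclose(back.positions, t.positions)
    assert back.sources == t.sources
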