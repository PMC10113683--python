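import numpy as np
import pytest
from _oracles import dense_path

from orthotrack.ct_io import CTVolume, gtv_only_volume
from orthotrack.drr import (
    ProjectionImage,
    display_from_path,
    gaussian_prefilter,
    hu_to_mu,
    radiological_path,
    render_drr,
)
from orthotrack.geometry import Ray, build_geometry
from orthotrack.phantom4d import PhantomSpec, generate_phantom


@pytest.mark.parametrize("hu,mu", [(0.0, 0.02), (-1000.0, 0.0), (500.0, 0.03), (-2000.0, 0.0)])
def test_hu_to_mu_linear_map_with_clamp(hu, mu):
    assert hu_to_mu(hu) == pytest.approx(mu, abs=1e-15)


def test_ray_missing_volume_gives_zero():
    vol = CTVolume(voxels=np.zeros((8, 8, 8), np.float32), spacing=(2, 2, 2), origin=(-7, -7, -7))
    ray = Ray(origin=(-100.0, 100.0, 0.0), direction=(0.0, 0.0, 1.0))
    assert radiological_path(vol, ray) == 0.0


def test_water_cube_chord():
    """Axis-aligned ray through a 100 mm water cube: path = 0.02 * 100 = 2.0."""
    vol = CTVolume(voxels=np.zeros((10, 10, 10), np.float32), spacing=(10, 10, 10), origin=(-45, -45, -45))
    ray = Ray(origin=(-300.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0))
    assert radiological_path(vol, ray) == pytest.approx(2.0, abs=1e-9)


def test_oblique_rays_match_dense_sampling_oracle(rng):
    for _ in range(10):
        hu = rng.uniform(-500, 500, size=(16, 16, 16)).astype(np.float32)
        vol = CTVolume(voxels=hu, spacing=(4, 4, 4), origin=(-30, -30, -30))
        src = rng.normal(size=3)
        src *= 200.0 / np.linalg.norm(src)
        ray = Ray(origin=src, direction=rng.uniform(-10, 10, size=3) - src)
        siddon = radiological_path(vol, ray)
        oracle = dense_path(vol, ray)
        assert siddon == pytest.approx(oracle, rel=1e-3)


def test_time_reversal_symmetry(rng):
    """Tracing the same line from the other side gives the identical path."""
    hu = rng.uniform(-800, 800, size=(12, 12, 12)).astype(np.float32)
    vol = CTVolume(voxels=hu, spacing=(3, 3, 3), origin=(-16, -16, -16))
    for _ in range(20):
        src = rng.normal(size=3)
        src *= 150.0 / np.linalg.norm(src)
        tgt = rng.uniform(-8, 8, size=3)
        fwd = Ray(origin=src, direction=tgt - src)
        back_origin = src + 300.0 * fwd.direction
        rev = Ray(origin=back_origin, direction=-fwd.direction)
        assert radiological_path(vol, fwd) == pytest.approx(radiological_path(vol, rev), abs=1e-9)


def test_empty_volume_renders_zero_image():
    vol = CTVolume(voxels=np.full((8, 8, 8), -1000, np.float32), spacing=(4, 4, 4), origin=(-14, -14, -14))
    img = render_drr(vol, build_geometry(10.0), downsample=32)
    assert img.path.max() == 0.0
    assert img.display.max() == 0  # degenerate constant image maps to zeros


def test_path_linear_in_attenuation(rng):
    """mu-additivity: merging two attenuation maps adds the per-pixel paths."""
    g = build_geometry(45.0)
    base = dict(spacing=(4, 4, 4), origin=(-30, -30, -30))
    hu_a = rng.uniform(-500, 500, size=(16, 16, 16)).astype(np.float32)
    hu_b = rng.uniform(-500, 500, size=(16, 16, 16)).astype(np.float32)
    vol_a = CTVolume(voxels=hu_a, **base)
    vol_b = CTVolume(voxels=hu_b, **base)
    vol_sum = CTVolume(voxels=hu_a + hu_b + 1000.0, **base)  # mu_sum = mu_a + mu_b
    pa = render_drr(vol_a, g, downsample=64).path
    pb = render_drr(vol_b, g, downsample=64).path
    ps = render_drr(vol_sum, g, downsample=64).path
    np.testing.assert_allclose(ps, pa + pb, atol=1e-9)


def test_raising_hu_never_decreases_path(rng):
    hu = rng.uniform(-500, 500, size=(12, 12, 12)).astype(np.float32)
    base = dict(spacing=(5, 5, 5), origin=(-27, -27, -27))
    g = build_geometry(200.0)
    before = render_drr(CTVolume(voxels=hu, **base), g, downsample=64).path
    hu2 = hu.copy()
    hu2[6, 6, 6] += 800.0
    after = render_drr(CTVolume(voxels=hu2, **base), g, downsample=64).path
    assert np.all(after >= before - 1e-12)


def test_gtv_silhouette_shrinks_with_tumor(small_spec):
    areas = []
    g = build_geometry(45.0)
    for semi in (12.1, 9.0, 6.0):
        spec = PhantomSpec(
            grid_shape=small_spec.grid_shape,
            spacing=small_spec.spacing,
            tumor_semi_axes=(semi, semi, semi),
        )
        ph = generate_phantom(spec)
        only = gtv_only_volume(ph.volumes[0], ph.masks[0])
        img = render_drr(only, g, downsample=8)
        areas.append(int((img.path > 1e-6).sum()))
    assert areas[0] > areas[1] > areas[2] > 0


def test_gaussian_prefilter_identity_and_dc():
    g = build_geometry(0.0).downsampled(16)
    path = np.full((g.n_u, g.n_v), 0.5)
    img = ProjectionImage(path=path, display=display_from_path(path), geometry=g)
    same = gaussian_prefilter(img, 0.0)
    np.testing.assert_array_equal(same.path, img.path)
    blurred = gaussian_prefilter(img, 3.0)
    np.testing.assert_allclose(blurred.path, img.path, atol=1e-12)  # constant is preserved


def test_gaussian_prefilter_impulse_matches_kernel():
    g = build_geometry(0.0).downsampled(16)
    path = np.zeros((g.n_u, g.n_v))
    path[g.n_u // 2, g.n_v // 2] = 1.0
    img = ProjectionImage(path=path, display=display_from_path(path), geometry=g)
    sigma_px = 2.0
    out = gaussian_prefilter(img, sigma_px * g.pixel_pitch)
    uu, vv = np.meshgrid(np.arange(g.n_u), np.arange(g.n_v), indexing="ij")
    r2 = (uu - g.n_u // 2) ** 2.0 + (vv - g.n_v // 2) ** 2.0
    kernel = np.exp(-r2 / (2 * sigma_px**2)) / (2 * np.pi * sigma_px**2)
    np.testing.assert_allclose(out.path, kernel, atol=5e-5)


def test_gaussian_prefilter_rejects_negative_sigma():
    g = build_geometry(0.0).downsampled(64)
    img = ProjectionImage(path=np.zeros((g.n_u, g.n_v)), display=np.zeros((g.n_u, g.n_v), np.uint8), geometry=g)
    with pytest.raises(ValueError):
        gaussian_prefilter(img, -1.0)


def test_display_is_rescaled_transmission(rng):
    path = rng.uniform(0, 3, size=(16, 12))
    disp = display_from_path(path)
    tr = np.exp(-path)
    expected = np.rint(255 * (tr - tr.min()) / (tr.max() - tr.min()))
    np.testing.assert_array_equal(disp, expected.astype(np.uint8))
    assert disp.min() == 0 and disp.max() == 255
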