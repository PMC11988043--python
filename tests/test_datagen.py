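"""Synthetic scene generator: closed-form weight labels, determinism,
file round trips, preprocessing and augmentation geometry."""

import dataclasses
import hashlib

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest

from rgbdweight import datagen
from rgbdweight.datagen import (AugmentConfig, DatasetManifest,
                                HALF_ELLIPSOID_VOLUME, RGBDPair, SceneParams,
                                augment_pair, density_to_hue, generate_dataset,
                                hue_to_density, load_pair, preprocess_pair,
                                render_scene, sample_scene_params,
                                silhouette_from_depth, silhouette_from_rgb,
                                split_manifest)


# ----------------------------------------------------------------- rendering
def test_weight_equals_closed_form_half_ellipsoid_volume():
    density = 5.5 / ((2.0 / 3.0) * np.pi * 1.0e6)
    p = SceneParams(semi_axis_x=100.0, semi_axis_y=100.0, semi_axis_z=100.0,
                    density=density)
    pair = render_scene(p)
    assert pair.weight == pytest.approx(density * (2.0 / 3.0) * np.pi * 1e6,
                                        rel=1e-9)


def test_render_is_deterministic_under_seed():
    p = SceneParams(semi_axis_x=120.0, semi_axis_y=110.0, semi_axis_z=70.0,
                    density=9e-7, noise_sigma_depth=5.0, noise_sigma_rgb=4.0,
                    rng_seed=42, resolution=96)
    a, b = render_scene(p), render_scene(p)
    assert np.array_equal(a.rgb, b.rgb)
    assert np.array_equal(a.depth, b.depth)
    assert a.weight == b.weight


def test_weight_matches_riemann_sum_of_height_field():
    """Label equals pixel-wise integration of the rendered height field."""
    p = SceneParams(semi_axis_x=147.0, semi_axis_y=122.0, semi_axis_z=83.0,
                    center_xy=(25.0, -30.0), density=1e-6, resolution=240)
    pair = render_scene(p)
    mm_per_px = datagen.FIELD_MM / p.resolution
    height = p.camera_height - pair.depth.astype(float)
    riemann = height[height > 0].sum() * mm_per_px ** 2 * p.density
    assert riemann == pytest.approx(pair.weight, rel=5e-3)


def test_depth_within_sensor_range_and_invariants():
    p = SceneParams(semi_axis_x=170.0, semi_axis_y=170.0, semi_axis_z=119.0,
                    density=2e-6, noise_sigma_depth=20.0, rng_seed=5,
                    resolution=96)
    pair = render_scene(p)
    assert pair.depth.min() >= datagen.DEPTH_MIN_MM
    assert pair.depth.max() <= datagen.DEPTH_MAX_MM
    assert pair.rgb.shape[:2] == pair.depth.shape


def test_body_must_fit_in_frame():
    with pytest.raises(ValueError, match="frame"):
        render_scene(SceneParams(semi_axis_x=400.0, semi_axis_y=100.0,
                                 semi_axis_z=80.0, density=1e-6))
    with pytest.raises(ValueError, match="semi-axes"):
        SceneParams(semi_axis_x=-1.0, semi_axis_y=100.0, semi_axis_z=80.0)
    with pytest.raises(ValueError, match="camera_height"):
        SceneParams(semi_axis_x=100.0, semi_axis_y=100.0, semi_axis_z=80.0,
                    camera_height=50.0)


def test_hue_encoding_round_trips_density():
    for d in np.geomspace(datagen.DENSITY_MIN, datagen.DENSITY_MAX, 7):
        assert hue_to_density(density_to_hue(d)) == pytest.approx(d, rel=1e-9)


def test_silhouettes_from_both_modalities_agree(clean_pair):
    m_depth = silhouette_from_depth(clean_pair.depth)
    m_rgb = silhouette_from_rgb(clean_pair.rgb)
    iou = (m_depth & m_rgb).sum() / (m_depth | m_rgb).sum()
    assert iou > 0.95


# ------------------------------------------------------------------- dataset
def test_generate_dataset_deterministic_and_in_range(tmp_path):
    m1 = generate_dataset(10, seed=7, out_dir=tmp_path / "a", resolution=64)
    m2 = generate_dataset(10, seed=7, out_dir=tmp_path / "b", resolution=64)
    assert np.array_equal(m1.frame["weight_kg"], m2.frame["weight_kg"])
    for f1, f2 in zip(sorted((tmp_path / "a").rglob("*.png")),
                      sorted((tmp_path / "b").rglob("*.png"))):
        assert (hashlib.sha256(f1.read_bytes()).hexdigest()
                == hashlib.sha256(f2.read_bytes()).hexdigest())
    m1.validate_files()
    assert len(m1) == 10


def test_generated_weights_cover_range():
    rng = np.random.default_rng(99)
    weights = np.array([sample_scene_params(rng).weight_kg for _ in range(1000)])
    assert weights.min() >= 0.50 and weights.max() <= 5.50
    # approximately uniform: decent coverage at both ends
    assert weights.min() < 0.75 and weights.max() > 5.25
    assert abs(weights.mean() - 3.0) < 0.2


def test_weight_conservation_on_sampled_scenes():
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = sample_scene_params(rng)
        v = HALF_ELLIPSOID_VOLUME(p.semi_axis_x, p.semi_axis_y, p.semi_axis_z)
        assert p.weight_kg == pytest.approx(p.density * v, rel=1e-12)


def test_modality_separation_by_construction():
    """Weight is uncorrelated with body volume (depth alone cannot predict
    it) while the colour hue determines density exactly."""
    rng = np.random.default_rng(12)
    params = [sample_scene_params(rng) for _ in range(1000)]
    w = np.array([p.weight_kg for p in params])
    v = np.array([p.volume_mm3 for p in params])
    assert abs(np.corrcoef(w, v)[0, 1]) < 0.1
    for p in params[:20]:
        assert hue_to_density(density_to_hue(p.density)) == pytest.approx(
            p.density, rel=1e-9)


def test_image_files_round_trip_losslessly(tmp_path, noisy_pair):
    iio.imwrite(tmp_path / "rgb.png", noisy_pair.rgb)
    iio.imwrite(tmp_path / "depth.png", noisy_pair.depth)
    assert np.array_equal(iio.imread(tmp_path / "rgb.png"), noisy_pair.rgb)
    depth_back = iio.imread(tmp_path / "depth.png")
    assert depth_back.dtype == np.uint16
    assert np.array_equal(depth_back, noisy_pair.depth)


def test_load_pair_by_index_and_id(tmp_path):
    m = generate_dataset(3, seed=1, out_dir=tmp_path, resolution=64)
    by_idx = load_pair(m, 1)
    by_id = load_pair(m, by_idx.sample_id)
    assert np.array_equal(by_idx.rgb, by_id.rgb)
    assert by_idx.weight == by_id.weight
    with pytest.raises(KeyError):
        load_pair(m, "nope")


# --------------------------------------------------------------------- split
def _frame(n):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "rgb_path": [f"rgb/{i}.png" for i in range(n)],
        "depth_path": [f"depth/{i}.png" for i in range(n)],
        "weight_kg": np.linspace(0.5, 5.5, n),
        "split": ["train"] * n,
    })


def test_split_follows_protocol_counts():
    m = split_manifest(DatasetManifest(frame=_frame(2865)), 2325, 540, seed=0)
    assert (m.frame["split"] == "train").sum() == 2325
    assert (m.frame["split"] == "test").sum() == 540


def test_split_all_train_and_validation():
    m = split_manifest(DatasetManifest(frame=_frame(20)), 20, 0, seed=3)
    assert (m.frame["split"] == "train").all()
    with pytest.raises(ValueError, match="rows"):
        split_manifest(DatasetManifest(frame=_frame(20)), 15, 10, seed=3)


def test_split_reproducible_and_seed_sensitive():
    base = DatasetManifest(frame=_frame(100))
    a = split_manifest(base, 70, 30, seed=5)
    b = split_manifest(base, 70, 30, seed=5)
    c = split_manifest(base, 70, 30, seed=6)
    assert (a.frame["split"] == b.frame["split"]).all()
    assert (a.frame["split"] != c.frame["split"]).any()


def test_manifest_rejects_duplicate_ids():
    f = _frame(4)
    f.loc[1, "sample_id"] = "s0"
    with pytest.raises(ValueError, match="unique"):
        DatasetManifest(frame=f)


# ------------------------------------------------------------- preprocessing
def _gauss_kernel(sigma, truncate=4.0):
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _hand_gaussian2d(img, sigma):
    """Separable convolution with the sampled kernel, reflect boundary."""
    k = _gauss_kernel(sigma)
    r = len(k) // 2
    padded = np.pad(img, r, mode="symmetric")
    rows = np.apply_along_axis(lambda v: np.convolve(v, k, "valid"), 1, padded)
    out = np.apply_along_axis(lambda v: np.convolve(v, k, "valid"), 0, rows)
    return out


def test_gaussian_smoothing_matches_hand_convolution(rng):
    img = rng.uniform(0, 255, (5, 5))
    pair = RGBDPair(rgb=np.stack([img] * 3, axis=2).astype(np.uint8),
                    depth=np.full((5, 5), 900, dtype=np.uint16), weight=2.0)
    out = preprocess_pair(pair, gaussian_sigma=1.0, color_norm=False)
    expected = _hand_gaussian2d(pair.rgb[:, :, 0].astype(float), 1.0)
    assert np.allclose(out.rgb[:, :, 0], expected, atol=1e-10)


def test_tiny_sigma_approximates_identity(noisy_pair):
    out = preprocess_pair(noisy_pair, gaussian_sigma=1e-3, color_norm=False)
    assert np.abs(out.rgb - noisy_pair.rgb).max() < 1.0  # within quantisation
    with pytest.raises(ValueError, match="sigma"):
        preprocess_pair(noisy_pair, gaussian_sigma=0.0)


def test_color_norm_zero_means_channels(noisy_pair):
    out = preprocess_pair(noisy_pair, gaussian_sigma=1.0, color_norm=True)
    assert np.allclose(out.rgb.mean(axis=(0, 1)), 0.0, atol=1e-9)
    assert np.allclose(out.rgb.std(axis=(0, 1)), 1.0, atol=1e-6)


def test_depth_smoothing_respects_invalid_pixels():
    depth = np.full((20, 20), 1000.0)
    depth[:10] = 0.0  # invalid half
    pair = RGBDPair(rgb=np.zeros((20, 20, 3), np.uint8),
                    depth=depth.astype(np.uint16), weight=1.0)
    out = preprocess_pair(pair, gaussian_sigma=2.0)
    assert np.all(out.depth[:10] == 0.0)
    assert np.allclose(out.depth[10:], 1000.0)  # no bleed from the hole


# -------------------------------------------------------------- augmentation
class _StubRng:
    """Forces deterministic draws for targeted augmentation cases."""

    def __init__(self, uniform_value=0.0, random_value=1.0):
        self.uniform_value = uniform_value
        self.random_value = random_value

    def uniform(self, lo, hi=None):
        return self.uniform_value

    def random(self):
        return self.random_value

    def integers(self, lo, hi):
        return lo


def test_disabled_augmentation_is_resize_only(noisy_pair, rng):
    cfg = AugmentConfig.disabled(out_size=64)
    out = augment_pair(noisy_pair, cfg, rng)
    from skimage.transform import resize
    expected = resize(noisy_pair.rgb.astype(float), (64, 64, 3), order=1,
                      mode="edge", anti_aliasing=True, preserve_range=True)
    assert np.allclose(out.rgb, np.clip(expected, 0, 255), atol=1e-9)
    assert out.weight == noisy_pair.weight


def test_horizontal_flip_is_involution(noisy_pair):
    size = noisy_pair.depth.shape[0]
    cfg = dataclasses.replace(AugmentConfig.disabled(out_size=size),
                              hflip_prob=1.0)
    flip_rng = _StubRng(random_value=0.0)  # < prob -> flip fires
    once = augment_pair(noisy_pair, cfg, flip_rng)
    assert not np.array_equal(once.rgb, noisy_pair.rgb.astype(float))
    twice = augment_pair(once, cfg, flip_rng)
    assert np.allclose(twice.rgb, noisy_pair.rgb.astype(float))
    assert np.allclose(twice.depth, noisy_pair.depth.astype(float))


def test_full_rotation_returns_resize_only(noisy_pair, rng):
    size = 64
    base = AugmentConfig.disabled(out_size=size)
    cfg = dataclasses.replace(base, rotate_max_deg=360.0)
    out = augment_pair(noisy_pair, cfg, _StubRng(uniform_value=360.0))
    ref = augment_pair(noisy_pair, base, _StubRng())
    assert np.abs(out.rgb - ref.rgb).max() < 1e-6
    assert np.abs(out.depth - ref.depth).max() < 1e-6


def test_geometric_transforms_move_both_modalities_identically(rng):
    """Silhouette IoU across modalities stays ~1 under full augmentation."""
    yy, xx = np.mgrid[0:128, 0:128]
    mask = ((yy - 64) / 40.0) ** 2 + ((xx - 64) / 30.0) ** 2 < 1.0
    pair = RGBDPair(rgb=(np.stack([mask] * 3, 2) * 200).astype(np.uint8),
                    depth=(500 + mask * 300).astype(np.uint16), weight=2.0)
    cfg = AugmentConfig(out_size=96)
    for _ in range(5):
        out = augment_pair(pair, cfg, rng)
        m_rgb = out.rgb[:, :, 0] > 100
        m_depth = out.depth > 650
        iou = (m_rgb & m_depth).sum() / max((m_rgb | m_depth).sum(), 1)
        assert iou > 0.99


def test_photometric_changes_leave_depth_untouched(noisy_pair, rng):
    cfg = AugmentConfig(out_size=64, hflip_prob=0.0, vflip_prob=0.0,
                        rotate_max_deg=0.0, crop_scale=(1.0, 1.0),
                        crop_ratio=(1.0, 1.0), jitter_brightness=0.4,
                        jitter_contrast=0.4, jitter_saturation=0.4,
                        blur_prob=1.0)
    out = augment_pair(noisy_pair, cfg, rng)
    ref = augment_pair(noisy_pair, AugmentConfig.disabled(out_size=64), rng)
    assert np.allclose(out.depth, ref.depth)
    assert not np.allclose(out.rgb, ref.rgb)
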