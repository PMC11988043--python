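"""Synthetic top-view RGB-D scenes with closed-form weight labels.

Each scene is a single convex body — the upper half of an ellipsoid with
semi-axes (a, b, c) mm — resting on a flat ground plane, viewed by a
fixed-height depth camera pointing straight down.  The depth map is

    depth(x, y) = camera_height - h(x, y) + noise,

where ``h`` is the ellipsoid height field (zero outside the silhouette).
The colour image shows the silhouette tinted by a hue code on a textured
grey background.  True weight is exactly

    weight = density * V,   V = (2/3) * pi * a * b * c,

the volume under the height field.  Density is encoded *only* in the hue of
the colour texture, and the vertical semi-axis c is visible *only* in the
depth map (colour shading is normalised by c), so neither modality alone
determines the weight — the same confound the two-stream network is meant
to resolve.

Weights are drawn approximately uniformly over a configurable range
(default 0.50-5.50 kg); the density implied by a drawn weight is clamped to
the representable hue range.  Depth values stay inside a 500-5000 mm sensor
range.  Files go to disk as 8-bit PNG (colour), 16-bit PNG (depth, one unit
= 1 mm, 0 = invalid), and a CSV manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "SceneParams", "RGBDPair", "DatasetManifest", "AugmentConfig",
    "render_scene", "generate_dataset", "split_manifest",
    "preprocess_pair", "augment_pair", "load_pair",
    "silhouette_from_depth", "silhouette_from_rgb",
    "HALF_ELLIPSOID_VOLUME",
]

# Rendered field of view (mm) mapped onto a square image.  The default image
# resolution is 480 px, i.e. 1.25 mm/px, comparable to a ~1 m rig over a
# half-metre shooting area.
FIELD_MM = 600.0
DEFAULT_RESOLUTION = 480
DEPTH_MIN_MM, DEPTH_MAX_MM = 500.0, 5000.0

# Parameter ranges for dataset generation (mm).
SEMI_AXIS_XY_RANGE = (100.0, 180.0)
SEMI_AXIS_Z_RANGE = (60.0, 120.0)
CENTER_JITTER_MM = 40.0
DEFAULT_CAMERA_HEIGHT_MM = 1000.0
DEFAULT_WEIGHT_RANGE = (0.50, 5.50)

_V_MIN = (2.0 / 3.0) * np.pi * SEMI_AXIS_XY_RANGE[0] ** 2 * SEMI_AXIS_Z_RANGE[0]
_V_MAX = (2.0 / 3.0) * np.pi * SEMI_AXIS_XY_RANGE[1] ** 2 * SEMI_AXIS_Z_RANGE[1]
# Density bounds chosen so every weight in the default range is reachable at
# every sampled volume; hue encodes log-density over exactly this interval.
DENSITY_MIN = DEFAULT_WEIGHT_RANGE[0] / _V_MAX
DENSITY_MAX = DEFAULT_WEIGHT_RANGE[1] / _V_MIN

_BACKGROUND_GREY = 170.0
_BODY_SAT, _BODY_VAL = 0.70, 0.85
_HUE_SPAN = 0.83  # avoid the red/red wrap at hue 0 == hue 1


def HALF_ELLIPSOID_VOLUME(a: float, b: float, c: float) -> float:
    """Volume (mm^3) under the upper-half-ellipsoid height field."""
    return (2.0 / 3.0) * np.pi * a * b * c


def density_to_hue(density: float) -> float:
    """Log-scale encoding of density onto [0, 1]."""
    d = np.clip(density, DENSITY_MIN, DENSITY_MAX)
    return float(np.log(d / DENSITY_MIN) / np.log(DENSITY_MAX / DENSITY_MIN))


def hue_to_density(hue_code: float) -> float:
    return float(DENSITY_MIN * (DENSITY_MAX / DENSITY_MIN) ** np.clip(hue_code, 0, 1))


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic scene (lengths in mm)."""

    semi_axis_x: float
    semi_axis_y: float
    semi_axis_z: float
    center_xy: tuple[float, float] = (0.0, 0.0)
    density: float = 1.0e-6            # kg / mm^3
    hue_code: float | None = None      # derived from density when None
    camera_height: float = DEFAULT_CAMERA_HEIGHT_MM
    noise_sigma_depth: float = 0.0     # mm
    noise_sigma_rgb: float = 0.0       # 8-bit intensity units
    rng_seed: int = 0
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if min(self.semi_axis_x, self.semi_axis_y, self.semi_axis_z) <= 0:
            raise ValueError("all semi-axes must be positive")
        if self.camera_height <= self.semi_axis_z:
            raise ValueError("camera_height must exceed the body height")

    @property
    def volume_mm3(self) -> float:
        return HALF_ELLIPSOID_VOLUME(self.semi_axis_x, self.semi_axis_y,
                                     self.semi_axis_z)

    @property
    def weight_kg(self) -> float:
        return self.density * self.volume_mm3


@dataclass
class RGBDPair:
    """One sample: colour image, aligned depth map, scalar weight label.

    ``rgb`` is H x W x 3 (uint8 on disk; float after preprocessing) and
    ``depth`` is H x W in mm (uint16 on disk, 0 = invalid)."""

    rgb: np.ndarray
    depth: np.ndarray
    weight: float
    sample_id: str = ""

    def __post_init__(self):
        if self.rgb.shape[:2] != self.depth.shape[:2]:
            raise ValueError(
                f"rgb {self.rgb.shape[:2]} and depth {self.depth.shape[:2]} "
                "must share spatial extent")
        if not self.weight > 0:
            raise ValueError("weight must be positive")


# --------------------------------------------------------------------- scene
def render_scene(params: SceneParams) -> RGBDPair:
    """Render one noise-seeded RGB-D pair; fully determined by `rng_seed`."""
    n = params.resolution
    mm_per_px = FIELD_MM / n
    half = FIELD_MM / 2.0
    cx, cy = params.center_xy
    a, b, c = params.semi_axis_x, params.semi_axis_y, params.semi_axis_z
    if abs(cx) + a > half or abs(cy) + b > half:
        raise ValueError(
            f"body footprint (center {params.center_xy}, semi-axes {a}x{b}) "
            f"exceeds the {FIELD_MM:.0f} mm frame; the rig frames the whole body")

    rng = np.random.default_rng(params.rng_seed)
    # ground-plane coordinates of pixel centres (mm), origin at image centre
    xs = (np.arange(n) + 0.5) * mm_per_px - half
    ys = (np.arange(n) + 0.5) * mm_per_px - half
    X, Y = np.meshgrid(xs, ys)          # row-major: Y varies along rows
    r2 = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2
    h = c * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    inside = r2 < 1.0

    depth = params.camera_height - h
    if params.noise_sigma_depth > 0:
        depth = depth + rng.normal(0.0, params.noise_sigma_depth, depth.shape)
    depth = np.clip(np.rint(depth), DEPTH_MIN_MM, DEPTH_MAX_MM).astype(np.uint16)

    hue = params.hue_code if params.hue_code is not None \
        else density_to_hue(params.density)
    body_rgb = hsv_to_rgb([hue * _HUE_SPAN, _BODY_SAT, _BODY_VAL]) * 255.0
    # shading normalised by c: reveals shape, not absolute height
    shade = 0.75 + 0.25 * (h / c)
    rgb = np.empty((n, n, 3))
    texture = _background_texture(n, rng)
    for ch in range(3):
        rgb[:, :, ch] = np.where(inside, body_rgb[ch] * shade,
                                 _BACKGROUND_GREY + texture)
    if params.noise_sigma_rgb > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sigma_rgb, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return RGBDPair(rgb=rgb, depth=depth, weight=params.weight_kg)


def _background_texture(n: int, rng: np.random.Generator) -> np.ndarray:
    """Low-amplitude smooth procedural texture (shared across channels)."""
    coarse = rng.normal(0.0, 1.0, (max(n // 32, 2),) * 2)
    tex = _sk_resize(coarse, (n, n), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return 8.0 * tex


def silhouette_from_depth(depth: np.ndarray, margin_mm: float = 15.0) -> np.ndarray:
    """Body mask: pixels clearly above the dominant ground plane."""
    d = np.asarray(depth, dtype=float)
    ground = np.median(d[d > 0])
    return (d > 0) & (d < ground - margin_mm)


def silhouette_from_rgb(rgb: np.ndarray, chroma_threshold: float = 25.0) -> np.ndarray:
    """Body mask from colour saturation (background is near-grey)."""
    x = np.asarray(rgb, dtype=float)
    chroma = x.max(axis=2) - x.min(axis=2)
    return chroma > chroma_threshold


# ------------------------------------------------------------------ manifest
@dataclass
class DatasetManifest:
    """Table of (sample_id, rgb_path, depth_path, weight_kg, split) rows.

    Paths are stored relative to ``root``; split tags partition the rows."""

    frame: pd.DataFrame
    root: Path = field(default_factory=Path)

    COLUMNS = ("sample_id", "rgb_path", "depth_path", "weight_kg", "split")

    def __post_init__(self):
        self.root = Path(self.root)
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            raise ValueError("sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        sub = self.frame[self.frame["split"] == split]
        return sub.reset_index(drop=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        frame = pd.read_csv(path, dtype={"sample_id": str})
        return cls(frame=frame, root=path.parent)

    def validate_files(self):
        for _, row in self.frame.iterrows():
            for col in ("rgb_path", "depth_path"):
                p = self.root / row[col]
                if not p.exists():
                    raise FileNotFoundError(f"{row['sample_id']}: missing {p}")


def load_pair(manifest: DatasetManifest, index_or_id) -> RGBDPair:
    """Read one sample's images from disk."""
    if isinstance(index_or_id, str):
        sel = manifest.frame[manifest.frame["sample_id"] == index_or_id]
        if sel.empty:
            raise KeyError(f"sample_id {index_or_id!r} not in manifest")
        row = sel.iloc[0]
    else:
        row = manifest.frame.iloc[index_or_id]
    rgb = iio.imread(manifest.root / row["rgb_path"])
    depth = iio.imread(manifest.root / row["depth_path"])
    return RGBDPair(rgb=np.asarray(rgb), depth=np.asarray(depth),
                    weight=float(row["weight_kg"]), sample_id=str(row["sample_id"]))


def sample_scene_params(rng: np.random.Generator, *,
                        weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
                        camera_height: float = DEFAULT_CAMERA_HEIGHT_MM,
                        noise_sigma_depth: float = 5.0,
                        noise_sigma_rgb: float = 4.0,
                        resolution: int = DEFAULT_RESOLUTION) -> SceneParams:
    """Draw one scene: geometry and weight independent, density = weight/V."""
    a = rng.uniform(*SEMI_AXIS_XY_RANGE)
    b = rng.uniform(*SEMI_AXIS_XY_RANGE)
    c = rng.uniform(*SEMI_AXIS_Z_RANGE)
    cx = rng.uniform(-CENTER_JITTER_MM, CENTER_JITTER_MM)
    cy = rng.uniform(-CENTER_JITTER_MM, CENTER_JITTER_MM)
    w = rng.uniform(*weight_range)
    volume = HALF_ELLIPSOID_VOLUME(a, b, c)
    density = float(np.clip(w / volume, DENSITY_MIN, DENSITY_MAX))
    seed = int(rng.integers(0, 2 ** 31 - 1))
    return SceneParams(semi_axis_x=a, semi_axis_y=b, semi_axis_z=c,
                       center_xy=(cx, cy), density=density,
                       camera_height=camera_height,
                       noise_sigma_depth=noise_sigma_depth,
                       noise_sigma_rgb=noise_sigma_rgb,
                       rng_seed=seed, resolution=resolution)


def generate_dataset(n: int, seed: int, out_dir: str | Path,
                     weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE,
                     resolution: int = DEFAULT_RESOLUTION,
                     noise_sigma_depth: float = 5.0,
                     noise_sigma_rgb: float = 4.0) -> DatasetManifest:
    """Render `n` scenes to `out_dir` and return the written manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "rgb").mkdir(parents=True, exist_ok=True)
    (out_dir / "depth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        params = sample_scene_params(
            rng, weight_range=weight_range, resolution=resolution,
            noise_sigma_depth=noise_sigma_depth, noise_sigma_rgb=noise_sigma_rgb)
        pair = render_scene(params)
        sid = f"s{i:05d}"
        rgb_rel, depth_rel = f"rgb/{sid}.png", f"depth/{sid}.png"
        iio.imwrite(out_dir / rgb_rel, pair.rgb)
        iio.imwrite(out_dir / depth_rel, pair.depth)
        records.append({"sample_id": sid, "rgb_path": rgb_rel,
                        "depth_path": depth_rel,
                        "weight_kg": round(pair.weight, 6), "split": "train"})
    frame = pd.DataFrame.from_records(records, columns=DatasetManifest.COLUMNS)
    manifest = DatasetManifest(frame=frame, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def split_manifest(manifest: DatasetManifest, n_train: int, n_test: int,
                   seed: int) -> DatasetManifest:
    """Randomly tag `n_train` rows as train and the rest as test."""
    n = len(manifest)
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} != {n} rows")
    perm = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:]] = "test"
    frame = manifest.frame.copy()
    frame["split"] = split
    return DatasetManifest(frame=frame, root=manifest.root)


# ------------------------------------------------------------- preprocessing
def preprocess_pair(pair: RGBDPair, gaussian_sigma: float = 1.0,
                    color_norm: bool = True) -> RGBDPair:
    """Gaussian smoothing on both modalities; optional per-channel colour
    standardisation.  Depth smoothing ignores invalid (zero) pixels via
    normalised convolution.  Output arrays are float."""
    if gaussian_sigma <= 0:
        raise ValueError("gaussian_sigma must be positive")
    rgb = np.asarray(pair.rgb, dtype=float)
    rgb = np.stack([ndimage.gaussian_filter(rgb[:, :, ch], gaussian_sigma)
                    for ch in range(rgb.shape[2])], axis=2)
    if color_norm:
        mu = rgb.mean(axis=(0, 1))
        sd = rgb.std(axis=(0, 1))
        rgb = (rgb - mu) / np.where(sd > 0, sd, 1.0)

    depth = np.asarray(pair.depth, dtype=float)
    valid = depth > 0
    if valid.any():
        sm = ndimage.gaussian_filter(np.where(valid, depth, 0.0), gaussian_sigma)
        norm = ndimage.gaussian_filter(valid.astype(float), gaussian_sigma)
        depth = np.where(valid, sm / np.where(norm > 0, norm, 1.0), 0.0)
    return RGBDPair(rgb=rgb, depth=depth, weight=pair.weight,
                    sample_id=pair.sample_id)


# -------------------------------------------------------------- augmentation
@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation; geometric transforms hit both modalities with the
    same draw, photometric ones (jitter, blur) hit the colour image only."""

    out_size: int = 224
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotate_max_deg: float = 15.0
    crop_scale: tuple[float, float] = (0.7, 1.0)   # area fraction
    crop_ratio: tuple[float, float] = (0.85, 1.18)
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    jitter_saturation: float = 0.1
    blur_prob: float = 0.2
    blur_sigma: tuple[float, float] = (0.3, 1.2)

    @classmethod
    def disabled(cls, out_size: int = 224) -> "AugmentConfig":
        return cls(out_size=out_size, hflip_prob=0.0, vflip_prob=0.0,
                   rotate_max_deg=0.0, crop_scale=(1.0, 1.0),
                   crop_ratio=(1.0, 1.0), jitter_brightness=0.0,
                   jitter_contrast=0.0, jitter_saturation=0.0, blur_prob=0.0)


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[:2] == (size, size):
        return img.astype(float)
    return _sk_resize(img.astype(float), (size, size) + img.shape[2:],
                      order=1, mode="edge", anti_aliasing=img.shape[0] > size,
                      preserve_range=True)


def augment_pair(pair: RGBDPair, config: AugmentConfig,
                 rng: np.random.Generator) -> RGBDPair:
    """Apply one random augmentation draw; the weight label is untouched."""
    rgb = np.asarray(pair.rgb, dtype=float)
    depth = np.asarray(pair.depth, dtype=float)
    H, W = depth.shape

    # rotation about the image centre
    angle = rng.uniform(-config.rotate_max_deg, config.rotate_max_deg) \
        if config.rotate_max_deg else 0.0
    if angle:
        rgb = ndimage.rotate(rgb, angle, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
        depth = ndimage.rotate(depth, angle, axes=(1, 0), reshape=False,
                               order=1, mode="nearest")

    # random area/aspect crop (window always inside the frame)
    if config.crop_scale != (1.0, 1.0) or config.crop_ratio != (1.0, 1.0):
        for _ in range(10):
            scale = rng.uniform(*config.crop_scale)
            ratio = np.exp(rng.uniform(np.log(config.crop_ratio[0]),
                                       np.log(config.crop_ratio[1])))
            ch = int(round(np.sqrt(scale * H * W / ratio)))
            cw = int(round(np.sqrt(scale * H * W * ratio)))
            if 0 < ch <= H and 0 < cw <= W:
                top = rng.integers(0, H - ch + 1)
                left = rng.integers(0, W - cw + 1)
                rgb = rgb[top:top + ch, left:left + cw]
                depth = depth[top:top + ch, left:left + cw]
                break

    if rng.random() < config.hflip_prob:
        rgb, depth = rgb[:, ::-1], depth[:, ::-1]
    if rng.random() < config.vflip_prob:
        rgb, depth = rgb[::-1], depth[::-1]

    rgb = _resize(rgb, config.out_size)
    depth = _resize(depth, config.out_size)

    # photometric (colour only)
    if config.jitter_brightness:
        rgb = rgb * (1.0 + rng.uniform(-config.jitter_brightness,
                                       config.jitter_brightness))
    if config.jitter_contrast:
        f = 1.0 + rng.uniform(-config.jitter_contrast, config.jitter_contrast)
        rgb = (rgb - rgb.mean()) * f + rgb.mean()
    if config.jitter_saturation:
        f = 1.0 + rng.uniform(-config.jitter_saturation, config.jitter_saturation)
        grey = rgb.mean(axis=2, keepdims=True)
        rgb = grey + (rgb - grey) * f
    if config.blur_prob and rng.random() < config.blur_prob:
        sigma = rng.uniform(*config.blur_sigma)
        rgb = np.stack([ndimage.gaussian_filter(rgb[:, :, ch], sigma)
                        for ch in range(3)], axis=2)
    rgb = np.clip(rgb, 0.0, 255.0)

    return RGBDPair(rgb=rgb, depth=depth, weight=pair.weight,
                    sample_id=pair.sample_id)
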