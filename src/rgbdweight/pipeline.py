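"""Training, evaluation, ablation and visualisation orchestration.

The flow mirrors the experimental protocol end to end: load a manifest,
smooth the raw pairs, standardise each modality with statistics computed on
the training split only, train with AdamW at a constant learning rate
(default 1e-3, weight decay 0.05, batch 32), and report MAE / RMSE / R2 on
the held-out split with augmentation disabled.

One master seed fans out, via ``numpy.random.SeedSequence``, into three
independent streams: parameter initialisation, batch shuffling, and
augmentation draws — so a run is reproducible end to end on one machine.
Training runs in float32; verification-grade code elsewhere defaults to
float64.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import __version__, nn
from .config import ModelConfig, TrainConfig
from .datagen import (AugmentConfig, DatasetManifest, RGBDPair, augment_pair,
                      load_pair, preprocess_pair)
from .metrics import MetricsReport, compute_report
from .model import build_model
from .nn import Tensor
from .nn.tensor import get_default_dtype, set_default_dtype
from .regression import make_loss

__all__ = ["NormStats", "InMemoryDataset", "TrainResult", "train", "evaluate",
           "run_ablation", "gradcam", "save_checkpoint", "load_checkpoint",
           "architecture_hash"]

PREPROCESS_SIGMA = 1.0   # Gaussian smoothing applied to both modalities


@dataclass
class NormStats:
    """Per-modality standardisation constants (training split only)."""

    rgb_mean: np.ndarray   # (3,)
    rgb_std: np.ndarray    # (3,)
    depth_mean: float
    depth_std: float

    def apply(self, rgb: np.ndarray, depth: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        """(H,W,3) in [0,255] and (H,W) in mm -> normalised (3,H,W),(1,H,W)."""
        r = (rgb / 255.0 - self.rgb_mean) / self.rgb_std
        d = (depth - self.depth_mean) / self.depth_std
        return r.transpose(2, 0, 1), d[None]

    def to_json(self) -> str:
        return json.dumps({"rgb_mean": self.rgb_mean.tolist(),
                           "rgb_std": self.rgb_std.tolist(),
                           "depth_mean": self.depth_mean,
                           "depth_std": self.depth_std})

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        d = json.loads(s)
        return cls(rgb_mean=np.array(d["rgb_mean"]), rgb_std=np.array(d["rgb_std"]),
                   depth_mean=d["depth_mean"], depth_std=d["depth_std"])


def _resize_pair(rgb: np.ndarray, depth: np.ndarray, size: int):
    kw = dict(order=1, mode="edge", preserve_range=True,
              anti_aliasing=rgb.shape[0] > size)
    rgb = _sk_resize(rgb, (size, size, 3), **kw)
    depth = _sk_resize(depth, (size, size), **kw)
    return rgb, depth


class InMemoryDataset:
    """All pairs of one split, smoothed and held in memory.

    Raw (preprocessed, full-resolution) pairs are kept for augmentation;
    resize-only network inputs are cached for deterministic evaluation.
    """

    def __init__(self, manifest: DatasetManifest, split: str,
                 input_size: int, preprocess_sigma: float = PREPROCESS_SIGMA):
        rows = manifest.rows(split)
        if len(rows) == 0:
            raise ValueError(f"split {split!r} is empty")
        self.input_size = input_size
        sub = DatasetManifest(frame=rows, root=manifest.root)
        self.pairs: list[RGBDPair] = []
        for i in range(len(rows)):
            pair = load_pair(sub, i)
            self.pairs.append(
                preprocess_pair(pair, gaussian_sigma=preprocess_sigma,
                                color_norm=False))
        self.weights = np.array([p.weight for p in self.pairs])
        self.ids = [p.sample_id for p in self.pairs]
        self._plain_cache: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self):
        return len(self.pairs)

    def plain_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Resize-only inputs: rgb (N,S,S,3) in [0,255], depth (N,S,S) mm."""
        if self._plain_cache is None:
            rgbs, depths = [], []
            for p in self.pairs:
                r, d = _resize_pair(p.rgb, p.depth, self.input_size)
                rgbs.append(r)
                depths.append(d)
            self._plain_cache = (np.stack(rgbs), np.stack(depths))
        return self._plain_cache

    def compute_norm(self) -> NormStats:
        rgbs, depths = self.plain_arrays()
        scaled = rgbs / 255.0
        return NormStats(rgb_mean=scaled.mean(axis=(0, 1, 2)),
                         rgb_std=np.maximum(scaled.std(axis=(0, 1, 2)), 1e-6),
                         depth_mean=float(depths.mean()),
                         depth_std=float(max(depths.std(), 1e-6)))

    def eval_tensors(self, norm: NormStats) -> tuple[np.ndarray, np.ndarray]:
        rgbs, depths = self.plain_arrays()
        r = np.stack([norm.apply(rgbs[i], depths[i])[0] for i in range(len(self))])
        d = np.stack([norm.apply(rgbs[i], depths[i])[1] for i in range(len(self))])
        return r, d

    def augmented_sample(self, i: int, cfg: AugmentConfig, norm: NormStats,
                         rng: np.random.Generator):
        pair = augment_pair(self.pairs[i], cfg, rng)
        return norm.apply(pair.rgb, pair.depth)


def _augment_config(mode: str, input_size: int) -> AugmentConfig | None:
    if mode == "none":
        return None
    if mode == "flips":
        return AugmentConfig(out_size=input_size, rotate_max_deg=0.0,
                             crop_scale=(1.0, 1.0), crop_ratio=(1.0, 1.0),
                             jitter_brightness=0.0, jitter_contrast=0.0,
                             jitter_saturation=0.0, blur_prob=0.0)
    return AugmentConfig(out_size=input_size)


@dataclass
class TrainResult:
    model: nn.Module
    model_config: ModelConfig
    train_config: TrainConfig
    norm: NormStats
    log: pd.DataFrame
    modality: str = "rgbd"
    topology: str = "multiscale"
    checkpoint_path: Path | None = None


def _forward_batches(model: nn.Module, rgb: np.ndarray, depth: np.ndarray,
                     batch_size: int) -> np.ndarray:
    preds = []
    with nn.no_grad():
        for lo in range(0, len(rgb), batch_size):
            out = model(Tensor(rgb[lo:lo + batch_size]),
                        Tensor(depth[lo:lo + batch_size]))
            preds.append(out.data.copy())
    return np.concatenate(preds)


def train(manifest: DatasetManifest, model_config: ModelConfig,
          train_config: TrainConfig, out_dir: str | Path | None = None,
          modality: str = "rgbd", topology: str = "multiscale",
          val_split: str = "test", progress: bool = False) -> TrainResult:
    """Fit a model on the manifest's train split; log per-epoch metrics."""
    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32)
    try:
        ss = np.random.SeedSequence(train_config.seed)
        init_ss, shuffle_ss, aug_ss = ss.spawn(3)
        nn.seed_init(int(init_ss.generate_state(1)[0] % (2 ** 31)))
        shuffle_rng = np.random.default_rng(shuffle_ss)
        aug_rng = np.random.default_rng(aug_ss)

        train_set = InMemoryDataset(manifest, "train", train_config.input_size)
        norm = train_set.compute_norm()
        has_val = val_split in set(manifest.frame["split"])
        val_set = (InMemoryDataset(manifest, val_split, train_config.input_size)
                   if has_val else None)

        model = build_model(model_config, modality=modality, topology=topology)
        opt = nn.AdamW(model.parameters(), lr=train_config.lr,
                       weight_decay=train_config.weight_decay)
        loss_fn = make_loss(train_config.loss)
        aug_cfg = _augment_config(train_config.augment, train_config.input_size)

        y = train_set.weights
        y_mu, y_sd = (float(y.mean()), float(max(y.std(), 1e-6))) \
            if train_config.normalize_targets else (0.0, 1.0)
        plain_r, plain_d = (None, None)
        if aug_cfg is None:
            plain_r, plain_d = train_set.eval_tensors(norm)

        n = len(train_set)
        bs = train_config.batch_size
        records = []
        best_mae, best_state = np.inf, None
        for epoch in range(train_config.epochs):
            t0 = time.time()
            order = shuffle_rng.permutation(n)
            model.train()
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                if aug_cfg is None:
                    rb, db = plain_r[idx], plain_d[idx]
                else:
                    samples = [train_set.augmented_sample(i, aug_cfg, norm, aug_rng)
                               for i in idx]
                    rb = np.stack([s[0] for s in samples])
                    db = np.stack([s[1] for s in samples])
                target = (y[idx] - y_mu) / y_sd
                pred = model(Tensor(rb), Tensor(db))
                loss = loss_fn(pred, target)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {lo // bs}")
                model.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            row = {"epoch": epoch, "train_loss": epoch_loss / n_batches,
                   "seconds": round(time.time() - t0, 2)}
            if val_set is not None and (epoch + 1) % train_config.eval_every == 0:
                model.eval()
                vr, vd = val_set.eval_tensors(norm)
                preds = _forward_batches(model, vr, vd, bs) * y_sd + y_mu
                rep = compute_report(val_set.weights, preds)
                row.update(val_mae=rep.mae, val_rmse=rep.rmse, val_r2=rep.r2)
                if train_config.keep_best and rep.mae < best_mae:
                    best_mae, best_state = rep.mae, model.state_dict()
            records.append(row)
            if progress:
                print(f"epoch {epoch}: " + "  ".join(
                    f"{k}={v:.4f}" for k, v in row.items()
                    if isinstance(v, float)))

        if best_state is not None:
            model.load_state_dict(best_state)
        model.eval()
        log = pd.DataFrame.from_records(records)
        result = TrainResult(model=model, model_config=model_config,
                             train_config=train_config, norm=norm, log=log,
                             modality=modality, topology=topology)
        result.target_shift = (y_mu, y_sd)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            log.to_csv(out_dir / "training_log.csv", index=False)
            model_config.to_yaml(out_dir / "model_config.yaml")
            train_config.to_yaml(out_dir / "train_config.yaml")
            result.checkpoint_path = save_checkpoint(
                out_dir / "checkpoint.npz", result)
        return result
    finally:
        set_default_dtype(prev_dtype)


# ---------------------------------------------------------------- checkpoint
def save_checkpoint(path: str | Path, result: TrainResult) -> Path:
    """Single-file archive: parameters, both configs, norm stats, seed."""
    path = Path(path)
    meta = {
        "model_config": json.dumps(dataclasses.asdict(result.model_config)),
        "train_config": json.dumps(dataclasses.asdict(result.train_config)),
        "norm": result.norm.to_json(),
        "modality": result.modality,
        "topology": result.topology,
        "target_shift": json.dumps(getattr(result, "target_shift", (0.0, 1.0))),
        "version": __version__,
    }
    state = {f"param/{k}": v for k, v in result.model.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **state)
    return path


def _tupleize(d: dict, keys) -> dict:
    for k in keys:
        if d.get(k) is not None:
            d[k] = tuple(d[k])
    return d


def load_checkpoint(path: str | Path) -> TrainResult:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    mc = ModelConfig(**_tupleize(json.loads(meta["model_config"]),
                                 ("stage_channels", "stage_strides", "cfs_stages",
                                  "ff_channels", "rfb_dilations")))
    tc = TrainConfig(**json.loads(meta["train_config"]))
    nn.seed_init(0)
    model = build_model(mc, modality=meta["modality"], topology=meta["topology"])
    model.load_state_dict(state)
    model.eval()
    result = TrainResult(model=model, model_config=mc, train_config=tc,
                         norm=NormStats.from_json(meta["norm"]),
                         log=pd.DataFrame(), modality=meta["modality"],
                         topology=meta["topology"], checkpoint_path=Path(path))
    result.target_shift = tuple(json.loads(meta["target_shift"]))
    return result


# ---------------------------------------------------------------- evaluation
def evaluate(source: TrainResult | str | Path, manifest: DatasetManifest,
             split: str = "test", out_csv: str | Path | None = None
             ) -> tuple[MetricsReport, pd.DataFrame]:
    """Deterministic resize-only evaluation of a trained model on a split."""
    result = source if isinstance(source, TrainResult) else load_checkpoint(source)
    dataset = InMemoryDataset(manifest, split, result.train_config.input_size)
    r, d = dataset.eval_tensors(result.norm)
    y_mu, y_sd = getattr(result, "target_shift", (0.0, 1.0))
    result.model.eval()
    preds = _forward_batches(result.model, r, d,
                             result.train_config.batch_size) * y_sd + y_mu
    report = compute_report(dataset.weights, preds)
    frame = pd.DataFrame({"sample_id": dataset.ids,
                          "weight_kg_true": dataset.weights,
                          "weight_kg_pred": preds})
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return report, frame


# ------------------------------------------------------------------ ablation
_ABLATION_AXES = {"cfs_count", "fusion_scheme", "modality", "topology"}


def _variant_args(axis: str, value, model_config: ModelConfig):
    """Map one ablation setting to (model_config, modality, topology)."""
    if axis == "cfs_count":
        k = int(value)
        if not 0 <= k <= 6:
            raise ValueError("cfs_count must be in 0..6")
        return model_config.replace(cfs_stages=tuple(range(1, k + 1))), "rgbd", "multiscale"
    if axis == "fusion_scheme":
        return model_config.replace(fusion_scheme=str(value)), "rgbd", "multiscale"
    if axis == "modality":
        if value not in ("rgb", "depth", "rgbd"):
            raise ValueError(f"unknown modality {value!r}")
        return model_config, str(value), "multiscale"
    if axis == "topology":
        if value not in ("early", "late", "multiscale"):
            raise ValueError(f"unknown topology {value!r}")
        return model_config, "rgbd", str(value)
    raise ValueError(f"unknown ablation axis {axis!r}; one of {_ABLATION_AXES}")


def run_ablation(axis: str, values, manifest: DatasetManifest,
                 model_config: ModelConfig, train_config: TrainConfig,
                 seeds=(0, 1, 2, 3, 4), out_dir: str | Path | None = None,
                 progress: bool = False) -> pd.DataFrame:
    """Train/evaluate every (value, seed) cell under an identical budget.

    Returns the per-run table; a mean +/- sd summary per variant is attached
    as ``frame.attrs['summary']`` and written alongside when `out_dir` is
    given.
    """
    rows = []
    for value in values:
        mc, modality, topology = _variant_args(axis, value, model_config)
        for seed in seeds:
            tc = train_config.replace(seed=int(seed))
            result = train(manifest, mc, tc, modality=modality,
                           topology=topology, progress=False)
            report, _ = evaluate(result, manifest, split="test")
            rows.append({"variant": f"{axis}={value}", "seed": int(seed),
                         "mae": report.mae, "rmse": report.rmse,
                         "r2": report.r2, "n": report.n})
            if progress:
                print(f"{axis}={value} seed={seed}: {report}")
    frame = pd.DataFrame.from_records(rows)
    summary = (frame.groupby("variant")[["mae", "rmse", "r2"]]
               .agg(["mean", "std", "median"]))
    frame.attrs["summary"] = summary
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / f"ablation_{axis}.csv", index=False)
        summary.to_csv(out_dir / f"ablation_{axis}_summary.csv")
    return frame


def architecture_hash(model: nn.Module) -> str:
    """Fingerprint of the computation graph structure (names + shapes)."""
    lines = [f"{type(model).__name__}"]
    lines += [f"{name}:{tuple(p.shape)}" for name, p in model.named_parameters()]
    return hashlib.sha256("\n".join(lines).encode()).hexdigest()


# ------------------------------------------------------------------ gradcam
def gradcam(source: TrainResult | str | Path, pair: RGBDPair,
            target_layer: str) -> np.ndarray:
    """Gradient-weighted activation map of the predicted weight.

    Returns a heatmap in [0, 1] at the network input size.  `target_layer`
    names a module as listed by ``model.named_modules()``.
    """
    result = source if isinstance(source, TrainResult) else load_checkpoint(source)
    model = result.model
    layers = dict(model.named_modules())
    if target_layer not in layers:
        candidates = [k for k in layers if k][:20]
        raise ValueError(f"unknown layer {target_layer!r}; e.g. {candidates}")
    layer = layers[target_layer]

    size = result.train_config.input_size
    pre = preprocess_pair(pair, gaussian_sigma=PREPROCESS_SIGMA, color_norm=False)
    rgb, depth = _resize_pair(np.asarray(pre.rgb, float),
                              np.asarray(pre.depth, float), size)
    r, d = result.norm.apply(rgb, depth)

    captured: dict[str, Tensor] = {}
    orig_forward = layer.forward

    def capture(*args, **kwargs):
        out = orig_forward(*args, **kwargs)
        if isinstance(out, Tensor):
            out.retain_grad()
            captured["act"] = out
        return out

    object.__setattr__(layer, "forward", capture)
    try:
        model.eval()
        pred = model(Tensor(r[None]), Tensor(d[None]))
        pred.backward(np.ones_like(pred.data))
    finally:
        object.__delattr__(layer, "forward")
    act = captured.get("act")
    if act is None or act.grad is None:
        raise ValueError(f"layer {target_layer!r} produced no tensor output")

    weights = act.grad.mean(axis=(2, 3), keepdims=True)       # (1,C,1,1)
    cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return _sk_resize(cam, (size, size), order=1, mode="edge",
                      preserve_range=True)


def render_gradcam_overlay(rgb: np.ndarray, heat: np.ndarray,
                           path: str | Path) -> Path:
    """Save an overlay of the heatmap on the (resized) colour image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = _sk_resize(np.asarray(rgb, float) / 255.0, heat.shape + (3,),
                      order=1, mode="edge", preserve_range=True)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(base)
    ax.imshow(heat, cmap="jet", alpha=0.45, vmin=0.0, vmax=1.0)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return Path(path)
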