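"""Non-contact body-weight estimation from paired top-view RGB and depth
images, via a two-stream bidirectional cross-modal fusion network, plus a
synthetic RGB-D scene generator for end-to-end experimentation.

Typical entry points::

    from rgbdweight import generate_dataset, split_manifest, train, evaluate
    from rgbdweight import ModelConfig, TrainConfig
"""

__version__ = "0.1.0"

from .config import ModelConfig, TrainConfig
from .datagen import (AugmentConfig, DatasetManifest, RGBDPair, SceneParams,
                      augment_pair, generate_dataset, load_pair,
                      preprocess_pair, render_scene, split_manifest)
from .metrics import MetricsReport, compute_report, mae, r2, rmse

__all__ = [
    "__version__",
    "ModelConfig", "TrainConfig",
    "AugmentConfig", "DatasetManifest", "RGBDPair", "SceneParams",
    "augment_pair", "generate_dataset", "load_pair", "preprocess_pair",
    "render_scene", "split_manifest",
    "MetricsReport", "compute_report", "mae", "r2", "rmse",
    "WeightNet", "build_model",
    "train", "evaluate", "run_ablation", "gradcam",
]


def __getattr__(name):
    # model/pipeline pull in the NN core and matplotlib; import lazily
    if name in ("train", "evaluate", "run_ablation", "gradcam"):
        from . import pipeline
        return getattr(pipeline, name)
    if name in ("WeightNet", "build_model"):
        from . import model
        return getattr(model, name)
    raise AttributeError(f"module 'rgbdweight' has no attribute {name!r}")
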