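import numpy as np
import pytest

from rgbdweight.config import ModelConfig
from rgbdweight.datagen import SceneParams, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def noisy_pair():
    """One rendered scene with realistic sensor noise."""
    params = SceneParams(semi_axis_x=140.0, semi_axis_y=115.0, semi_axis_z=90.0,
                         center_xy=(20.0, -15.0), density=8.0e-7,
                         noise_sigma_depth=5.0, noise_sigma_rgb=4.0,
                         rng_seed=77, resolution=128)
    return render_scene(params)


@pytest.fixture(scope="session")
def clean_pair():
    """A noise-free scene (exact silhouettes, exact height field)."""
    params = SceneParams(semi_axis_x=150.0, semi_axis_y=120.0, semi_axis_z=80.0,
                         density=1.0e-6, rng_seed=3, resolution=128)
    return render_scene(params)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
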