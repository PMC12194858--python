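import numpy as np
import pytest

from woundmetry import SceneSpec, render_scene


def random_masks(n, seed, max_size=16):
    """Random small binary masks of varied size and density."""
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n):
        h = int(rng.integers(3, max_size + 1))
        w = int(rng.integers(3, max_size + 1))
        p = rng.uniform(0.2, 0.8)
        masks.append((rng.random((h, w)) < p).astype(np.uint8))
    return masks


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene reused across read-only tests."""
    return render_scene(SceneSpec())


@pytest.fixture(scope="session")
def noiseless_scene():
    return render_scene(SceneSpec(noise_sd=0.0))
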