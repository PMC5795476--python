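import numpy as np
import pytest

from lampseg.synthetic import SceneSpec, default_suite, generate_scene


@pytest.fixture(scope="session")
def default_lit_scene():
    """The default 128x128 lit scene, seed 0 — the integration fixture."""
    return generate_scene(SceneSpec())


@pytest.fixture(scope="session")
def default_unlit_scene():
    import dataclasses

    return generate_scene(dataclasses.replace(SceneSpec(), lit=False))


@pytest.fixture(scope="session")
def suite_seed0():
    """The default synthetic suite: 20 lit scenes + 20 unlit controls, seed 0."""
    return default_suite(20, 0)


def naive_contrast_quantized(values: np.ndarray) -> np.ndarray:
    """O(N^2) oracle for the global contrast sum, on the 8-bit quantization."""
    q = np.rint(np.clip(values, 0, 1) * 255.0).astype(np.int64).ravel()
    out = np.empty(q.size, dtype=np.int64)
    for i, v in enumerate(q):
        out[i] = np.abs(v - q).sum()
    return (out / 255.0).reshape(values.shape)
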