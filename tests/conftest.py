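import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_boxes(rng, n, lo=0.0, hi=64.0, min_size=0.5):
    """Random valid corner-form boxes inside [lo, hi]^2."""
    x1 = rng.uniform(lo, hi - min_size, n)
    y1 = rng.uniform(lo, hi - min_size, n)
    x2 = x1 + rng.uniform(min_size, hi - x1)
    y2 = y1 + rng.uniform(min_size, hi - y1)
    return np.stack([x1, y1, x2, y2], axis=1)


@pytest.fixture()
def tiny_dataset(tmp_path):
    """A 12-image easy synthetic dataset in YOLO layout."""
    from leafdet.synth import generate_dataset

    out = tmp_path / "data"
    generate_dataset("easy", 12, out, seed=7)
    return out
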