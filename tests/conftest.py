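import numpy as np
import pytest

from rped import GrayImage


def rped_bruteforce(values: np.ndarray, thr_value: int, alpha: int) -> np.ndarray:
    """Independent oracle: exhaustive evaluation of the two-neighbor edge
    conditions over every in-bounds (center, neighbor) pair, ignoring
    scan order and clusters entirely."""
    vals = np.asarray(values, dtype=np.int64)
    h, w = vals.shape
    active = np.zeros((h, w), dtype=bool)
    if alpha < w:
        c, n = vals[:, : w - alpha], vals[:, alpha:]
        active[:, : w - alpha] |= c > thr_value + n
        active[:, alpha:] |= thr_value + c < n
    if alpha < h:
        c, n = vals[: h - alpha, :], vals[alpha:, :]
        active[: h - alpha, :] |= c > thr_value + n
        active[alpha:, :] |= thr_value + c < n
    return active


@pytest.fixture
def oracle():
    return rped_bruteforce


@pytest.fixture
def step4x4():
    """The worked-example input: 4x4, every row (10, 10, 200, 200)."""
    return GrayImage(np.tile(np.array([10, 10, 200, 200]), (4, 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
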