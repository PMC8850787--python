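import os

# single-threaded BLAS: the workloads here are many small matmuls, where
# thread-pool handoff costs far exceed any parallel speedup
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from badacount.targets import DotAnnotationSet

# reproducible property tests: same example sequence on every run
_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_dot_64():
    return DotAnnotationSet("one", [(32.0, 32.0)], (64, 64))


def brute_force_density(points, H, W, sigma):
    """Independent per-pixel/per-dot evaluation of the density-map definition.

    Each dot contributes exp(-d²/2σ²)/(2πσ²) at every pixel centre within a
    square support window of half-width ceil(4σ); kernels truncate (no
    renormalisation) at image borders.
    """
    out = np.zeros((H, W))
    r = int(np.ceil(4.0 * sigma))
    for x, y in np.asarray(points, dtype=float).reshape(-1, 2):
        for py in range(H):
            for px in range(W):
                if abs(px - x) <= r and abs(py - y) <= r:
                    d2 = (px - x) ** 2 + (py - y) ** 2
                    out[py, px] += np.exp(-d2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    return out


def brute_force_block_sums(values, h, w):
    H, W = values.shape
    out = np.zeros((H // h, W // w))
    for i in range(H // h):
        for j in range(W // w):
            out[i, j] = values[i * h : (i + 1) * h, j * w : (j + 1) * w].sum()
    return out


def brute_force_mask(values, t_c):
    H, W = values.shape
    out = np.zeros((H, W), dtype=np.uint8)
    for i in range(H):
        for j in range(W):
            out[i, j] = 1 if values[i, j] >= t_c else 0
    return out
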