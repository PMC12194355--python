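import numpy as np
import pytest

from scintidenoise.dataio import DosePair, NormalizedImage
from scintidenoise.model import ModelConfig, init_parameters
from scintidenoise.phantom import (PhantomSpec, acquire_counts,
                                   generate_activity_map, thin_counts)

# small configuration exercising every block type (2 stages) cheaply
TINY_CONFIG = ModelConfig(encoder_widths=(4, 8), gn_groups=2,
                          attention_reduction=2, init_seed=7)


@pytest.fixture
def tiny_config():
    return TINY_CONFIG


@pytest.fixture
def tiny_params():
    return init_parameters(TINY_CONFIG)


def make_synthetic_pairs(n_pairs: int, size: int = 16, fraction: float = 0.3,
                         seed: int = 0) -> list[DosePair]:
    """In-memory dose pairs from the phantom simulator (no disk I/O)."""
    pairs = []
    for i in range(n_pairs):
        spec = PhantomSpec(region="pelvis" if i % 2 == 0 else "thorax",
                           image_size=(size, size), subject_seed=seed + i)
        amap = generate_activity_map(spec)
        full = acquire_counts(amap, 1.0, seed=seed + 1000 + i)
        low = thin_counts(full, fraction, seed=seed + 2000 + i)
        peak = max(int(full.counts.max()), 1)
        pairs.append(DosePair(
            low=NormalizedImage(low.counts / peak, dose_fraction=fraction),
            full=NormalizedImage(full.counts / peak, dose_fraction=1.0),
            subject_id=f"s{i:03d}", region=spec.region, view="anterior"))
    return pairs


@pytest.fixture
def pair_factory():
    return make_synthetic_pairs


# --------------------------------------------------------------------------
# independent brute-force convolution oracles (pure python loops)

def conv2d_bruteforce(x: np.ndarray, w: np.ndarray, b=None, stride: int = 1,
                      padding: int = 0, groups: int = 1) -> np.ndarray:
    n, c, h, wdt = x.shape
    c_out, c_g, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    y = np.zeros((n, c_out, ho, wo))
    og = c_out // groups
    for ni in range(n):
        for oi in range(c_out):
            g = oi // og
            for r in range(ho):
                for s_ in range(wo):
                    acc = 0.0
                    for ci in range(c_g):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (xp[ni, g * c_g + ci,
                                           r * stride + i, s_ * stride + j]
                                        * w[oi, ci, i, j])
                    y[ni, oi, r, s_] = acc
    if b is not None:
        y += b.reshape(1, -1, 1, 1)
    return y


def group_norm_bruteforce(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                          groups: int, eps: float = 1e-5) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.empty_like(x)
    cg = c // groups
    for ni in range(n):
        for g in range(groups):
            block = x[ni, g * cg:(g + 1) * cg]
            mu, var = block.mean(), block.var()
            out[ni, g * cg:(g + 1) * cg] = (block - mu) / np.sqrt(var + eps)
    return out * gamma.reshape(1, c, 1, 1) + beta.reshape(1, c, 1, 1)
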