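"""Shared helpers: seeded RNG derivation and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(seed: int, *keys: object) -> int:
    """Derive a stable child seed (< 2^31) from a base seed and string keys.

    Uses CRC32 of the key path so that every pipeline stage gets an
    independent, reproducible stream regardless of call order.
    """
    h = int(seed) % _MOD
    for key in keys:
        h = (h * 1000003 + zlib.crc32(str(key).encode())) % _MOD
    return h


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *keys))


def wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value for beta/se."""
    from scipy import stats

    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    return 2.0 * stats.norm.sf(z)
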