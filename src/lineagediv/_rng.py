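"""Deterministic seed splitting.

Every stochastic stage derives its generator from one user seed plus a
stable stage key, so stages are independently reproducible and reordering
one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "split_seed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode("utf-8")) & 0x7FFFFFFF


def split_seed(seed: int, *keys: int | str) -> list[int]:
    """Entropy list for a named substream: ``[seed, crc32(key), ...]``."""
    return [int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)]


def spawn_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A NumPy generator for the substream named by ``keys``."""
    return np.random.default_rng(np.random.SeedSequence(split_seed(seed, *keys)))
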