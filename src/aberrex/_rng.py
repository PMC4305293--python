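"""Seed bookkeeping.

Every randomized stage draws from a ``numpy.random.Generator`` produced
here, so a single master seed reproduces the whole pipeline.
"""
from __future__ import annotations

import zlib

import numpy as np

_MAX_INT_SEED = 2**31 - 1


def rng_from(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn(seed: int, *key: int | str) -> np.random.Generator:
    """Derive an independent stream from ``seed`` and a stage key."""
    digest = [seed] + [
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(digest))


def int_seed(rng: np.random.Generator) -> int:
    """A small integer seed (for libraries wanting ``random_state``)."""
    return int(rng.integers(0, _MAX_INT_SEED))
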