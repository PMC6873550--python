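"""Deterministic child-seed derivation.

Every source of randomness in the package flows from one integer seed per
call.  When a routine needs several independent streams (one per epoch, one
per purpose), child seeds are derived by stable arithmetic on
``(seed, tag)`` so that runs are reproducible across platforms and Python
processes (no reliance on ``hash()``).
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(seed: int, *tags: object) -> int:
    """Derive a reproducible child seed below 2**31 from a parent seed and tags."""
    key = ("|".join(str(t) for t in (seed, *tags))).encode("utf-8")
    return zlib.crc32(key) % _MOD


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    """A fresh ``numpy.random.Generator`` for the given seed and purpose tags."""
    return np.random.default_rng(child_seed(seed, *tags))
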