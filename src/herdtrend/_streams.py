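"""Named random-stream hierarchy.

All stochastic operations in the package draw from child generators derived
from a single integer seed via :class:`numpy.random.SeedSequence`, keyed by a
module/operation name.  Two runs with the same seed are bit-identical, and
each named stream is independent of the others, so individual simulation
stages are reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, *names: str) -> np.random.Generator:
    """Return the generator for the stream addressed by ``names`` under ``seed``.

    The name path is hashed (crc32) into the spawn key so that streams are
    stable across releases regardless of call order.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))
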