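"""Deterministic random-stream spawning.

Every generator in the package is a pure function of (parameters, seed).
Named substreams let stages and subjects be re-simulated in isolation
without consuming draws from each other's streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    return zlib.crc32(str(key).encode())


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    Keys may be ints or strings (stage names, subject indices).  The same
    (seed, keys) tuple always yields an identical stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
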