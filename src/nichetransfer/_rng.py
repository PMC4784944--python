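"""Deterministic RNG streams.

Every stochastic operation draws from a stream derived from
(root seed, operation name, entity id), so adding a species or an
operation never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def stream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for stream (seed, *keys).

    Keys may be strings (op names) or integers (entity ids); strings are
    hashed with CRC32, which is stable across processes and platforms.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
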