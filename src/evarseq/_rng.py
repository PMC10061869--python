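"""Deterministic random-stream derivation.

Every stochastic stage derives its generator from a single user-facing
integer seed plus a tuple of string/int keys naming the stage, so that
stages are individually reproducible and mutually independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seedseq", "derive_rng"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, int):
        return key & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seedseq(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """SeedSequence for stream (seed, *keys); same inputs, same stream."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])


def derive_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator for the stream named by ``keys``, rooted at ``seed``."""
    return np.random.default_rng(derive_seedseq(seed, *keys))
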