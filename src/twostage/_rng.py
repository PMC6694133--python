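"""Seed handling.

A single user-facing integer seed fans out to per-component child streams
through :class:`numpy.random.SeedSequence`.  Components are addressed by a
string key so that adding a new consumer never shifts the streams of
existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, key: str) -> int:
    """Derive a deterministic child seed (< 2**31) for component `key`."""
    tag = zlib.crc32(key.encode("utf-8"))
    state = np.random.SeedSequence([int(seed), tag]).generate_state(1, dtype=np.uint32)
    return int(state[0] % (2**31))


def rng_for(seed: int, key: str) -> np.random.Generator:
    """A `numpy` Generator seeded from (`seed`, `key`)."""
    return np.random.default_rng(child_seed(seed, key))
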