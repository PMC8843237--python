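"""Seed plumbing: every source of randomness flows from one master seed.

Named substreams are derived with :class:`numpy.random.SeedSequence` so that
e.g. weight initialisation and trial noise are independent yet both fully
determined by the master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "generator"]


def substream(seed: int, name: str, index: int = 0) -> np.random.SeedSequence:
    """A named, indexed child seed-sequence of the master ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))


def generator(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """A Generator drawn from the named substream of the master ``seed``."""
    return np.random.default_rng(substream(seed, name, index))
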