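"""Deterministic seed derivation.

Every stochastic stage derives its generator from one master integer seed
plus a tuple of string/int tags (stage name, replicate index, ...).  Tags
are hashed with CRC32 into the ``spawn_key`` of a :class:`numpy.random.SeedSequence`,
so stages are statistically independent and bit-reproducible, and no stage
ever touches global numpy state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "rng_for", "int_seed"]


def seed_sequence(master: int, *tags) -> np.random.SeedSequence:
    """SeedSequence for a stage identified by ``tags`` under ``master``."""
    key = tuple(zlib.crc32(str(t).encode("utf8")) for t in tags)
    return np.random.SeedSequence(entropy=int(master) & 0x7FFFFFFF, spawn_key=key)


def rng_for(master: int, *tags) -> np.random.Generator:
    """Independent Generator for a stage."""
    return np.random.default_rng(seed_sequence(master, *tags))


def int_seed(master: int, *tags) -> int:
    """A 31-bit integer seed (for libraries that take ``random_state`` ints)."""
    return int(seed_sequence(master, *tags).generate_state(1)[0] >> 1)
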