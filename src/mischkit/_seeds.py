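"""Deterministic seed derivation.

A single master seed is fanned out into named child streams so that each
pipeline stage (and each iteration within a stage) gets an independent,
reproducible random stream, and adding iterations never reshuffles earlier
ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(master: int | None, name: str) -> np.random.SeedSequence:
    """Spawn a named child stream off ``master``.

    The child key is a CRC32 of the name, so derivation is stable across
    runs and python processes (no use of the salted builtin ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    if master is None:
        return np.random.SeedSequence()
    return np.random.SeedSequence(entropy=int(master), spawn_key=(key,))


def child_rng(master: int | None, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed_sequence(master, name))


def child_int(master: int | None, name: str) -> int:
    """A 31-bit integer seed for libraries that take plain ints (sklearn)."""
    state = child_seed_sequence(master, name).generate_state(1)[0]
    return int(state % (2**31))
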