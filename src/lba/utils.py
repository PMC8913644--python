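"""Seed bookkeeping.

Every stochastic stage draws from its own named substream of one global
integer seed, so any stage can be re-run in isolation and still reproduce
the numbers of the full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "substream"]

_SEED_MOD = 2**31


def derive_seed(seed: int, name: str) -> int:
    """Deterministically derive a child seed for a named substream.

    The child is an integer below 2**31, so it can itself be passed to any
    API that expects a plain seed.
    """
    ss = np.random.SeedSequence([int(seed) % _SEED_MOD, zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator for the named substream of ``seed``."""
    return np.random.default_rng(derive_seed(seed, name))
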