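"""Deterministic random-stream derivation.

Every stochastic component (fold shuffling, negative sampling, parameter
initialisation, dropout, ...) draws from its own substream derived from one
global seed, so components are reproducible in isolation and end-to-end runs
are reproducible as a whole.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The label is hashed (CRC-32) into the spawn key of a ``SeedSequence`` so
    distinct labels give statistically independent streams while the same
    (seed, label) pair always gives the same stream.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def spawn(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Split ``rng`` into ``n`` independent child generators."""
    return list(rng.spawn(n))
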