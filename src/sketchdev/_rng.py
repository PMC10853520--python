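"""Seed fan-out for independent, reproducible random streams.

A single user-facing seed is expanded into per-component streams by
hashing a string label with CRC-32 and feeding ``(seed, crc32(label))``
to :class:`numpy.random.SeedSequence`.  Streams derived from different
labels are statistically independent; the same (seed, label) pair always
yields the same stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, label)."""
    h = zlib.crc32(label.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed), h]).generate_state(1)[0] % (2**31))


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator seeded from (seed, label)."""
    h = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))
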