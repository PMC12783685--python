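"""Keyed child random streams.

Every stochastic step in the pipeline draws from a child generator keyed by
(seed, purpose, level ids...).  Keys are hashed with CRC32 into extra entropy
words of a :class:`numpy.random.SeedSequence`, so adding e.g. one more compound
to a simulated plate never shifts the draws of unrelated levels, and the same
(seed, key) pair yields bit-identical streams on every platform (PCG64).
"""

from __future__ import annotations

from zlib import crc32

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, *keys) -> np.random.SeedSequence:
    """SeedSequence for the child stream identified by ``keys``."""
    words = [int(seed) & 0x7FFFFFFF]
    words.extend(crc32(repr(k).encode("utf-8")) for k in keys)
    return np.random.SeedSequence(words)


def child_rng(seed: int, *keys) -> np.random.Generator:
    """A PCG64 generator for the child stream identified by ``keys``."""
    return np.random.default_rng(child_seed(seed, *keys))
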