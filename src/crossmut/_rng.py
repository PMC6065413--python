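"""Deterministic random-stream management.

Every stochastic routine in the package takes either an integer seed or a
:class:`numpy.random.Generator`.  Per-unit streams (one permutation stream per
gene and feature, one null stream per gene and tissue, ...) are derived from a
master seed through :class:`numpy.random.SeedSequence` with a stable key, so
results do not depend on iteration order or on which subset of genes is run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_generator", "substream", "stable_key"]


def stable_key(label: str) -> int:
    """Map a string label to a stable 32-bit integer (CRC32)."""
    return zlib.crc32(label.encode("utf-8"))


def as_generator(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream(master_seed: int, *labels) -> np.random.Generator:
    """Independent generator keyed by ``(master_seed, *labels)``.

    Labels may be ints or strings; strings are hashed with CRC32.  The same
    key always yields the same stream, regardless of call order.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF]
    for lab in labels:
        entropy.append(stable_key(lab) if isinstance(lab, str) else int(lab) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))
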