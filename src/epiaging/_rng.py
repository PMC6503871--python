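"""Seed-substream management.

Every stochastic stage of the pipeline draws from its own named substream of
a single master seed, so that re-running any stage in isolation reproduces
the full-pipeline output bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stage label."""
    h = zlib.crc32(label.encode("utf-8"))
    return int(np.random.SeedSequence((int(master_seed), h)).generate_state(1)[0] % (2**31))


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    h = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), h)))
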