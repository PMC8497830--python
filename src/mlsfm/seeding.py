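"""Deterministic seed substreams.

A single pipeline seed is expanded into independent, named substreams so each
stage (phantom, acquisition noise, ...) draws from its own generator and
module-level results do not depend on pipeline stage order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream_rng", "as_rng"]


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for the substream ``name`` of the global ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    if seed_or_rng is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    return np.random.default_rng(int(seed_or_rng))
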