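"""Named child random streams derived from a single pipeline seed.

Every stochastic stage pulls its own generator via :func:`child_rng`, so a
stage can be re-run in isolation and still produce the bytes it produced
inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, name: str) -> list[int]:
    """Deterministic per-stream entropy for ``(seed, name)``."""
    return [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` unique to ``(seed, name)``."""
    return np.random.default_rng(np.random.SeedSequence(child_seed(seed, name)))
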