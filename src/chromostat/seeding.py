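"""Deterministic seed fan-out.

One global seed must drive every stochastic component (electrode noise,
vesicle sampling, digestion draws, assay noise) without correlations between
them. Each component asks for a child seed by name; the mapping is stable
across runs and platforms and stays below 2**31 so it can be handed to any
consumer that expects a small non-negative int.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-component seed from a global seed and a label."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, name))
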