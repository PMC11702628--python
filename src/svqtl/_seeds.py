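"""Named substreams expanded from one top-level seed.

Every randomized step in the package draws from ``substream(seed, name)``
so that an entire run is reproducible from a single integer while modules
stay order-independent of each other: the stream for ``"perm:geneX"`` does
not move when another module consumes randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-name random generator derived from ``seed``."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
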