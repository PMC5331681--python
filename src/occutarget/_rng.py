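"""Reproducible, parallel-safe random streams.

Every stochastic operation in the package derives its generator from one
integer seed plus the operation name (and optionally an iteration index), so
two operations never share a stream and adding iterations never perturbs
earlier ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Independent Generator for (seed, operation name, iteration index)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, int(index)])
    )
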