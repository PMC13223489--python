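"""Seed bookkeeping.

Every random draw in the package is traceable to (root seed, stage tag,
index).  Tags are short ASCII strings hashed into a 32-bit stream key so a
re-run of any single stage from saved upstream artifacts reproduces its
output exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(root_seed: int, tag: str, index: int = 0) -> int:
    """A deterministic 31-bit child seed for (root_seed, tag, index)."""
    key = f"{int(root_seed)}/{tag}/{int(index)}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def rng_for(root_seed: int, tag: str, index: int = 0) -> np.random.Generator:
    """Generator keyed to (root_seed, tag, index)."""
    return np.random.default_rng(derive_seed(root_seed, tag, index))
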