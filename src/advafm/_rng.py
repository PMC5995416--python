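"""Seed derivation for reproducible, stage-independent random streams."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "substream"]


def derive_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit sub-seed from a master seed and a stage name.

    Hash-based so that stages draw from independent streams and any stage can
    be re-run in isolation from the master seed alone.
    """
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    """A NumPy generator for the named substream of a master seed."""
    return np.random.default_rng(derive_seed(seed, name))
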