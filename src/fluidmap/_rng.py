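"""Deterministic RNG substreams keyed by string labels.

Randomized steps (censored draws, predictive mean matching) derive one
substream per (feature, run day) or per feature from a master seed via a
stable hash of the labels, so reordering features or samples never changes
the draws attached to a given cell.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _stable_hash(*keys: str) -> int:
    h = hashlib.sha256("\x1f".join(keys).encode("utf-8")).digest()
    return int.from_bytes(h[:4], "big")


def substream(master_seed: int, *keys: str) -> np.random.Generator:
    """Generator for the substream identified by ``keys`` under ``master_seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), _stable_hash(*keys)])
    )
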