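"""Deterministic seed derivation.

A single master seed spawns all per-component seeds through
``numpy.random.SeedSequence`` with an explicit spawn key, so every
sub-result (geometry, dataset, optimizer starts, ...) is independently
reproducible: ``child_seed(master, *path)`` depends only on the master seed
and the integer path.
"""

from __future__ import annotations

import numpy as np


def child_seed(master: int, *path: int) -> int:
    """Derive a reproducible 31-bit child seed from a master seed and path."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(path))
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master, spawn_key=tuple(path))
    )
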