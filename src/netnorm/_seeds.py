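"""Deterministic seed derivation.

Every stochastic operation in the package takes an integer seed; nested
stages derive child seeds from it through :func:`derive` so that a single
master seed pins the whole experiment.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31 - 1


def derive(seed: int, *tags: int) -> int:
    """Derive a child seed < 2**31 from ``seed`` and a tuple of integer tags.

    Stable across processes and platforms (uses numpy's SeedSequence
    hashing, not Python's randomized ``hash``).
    """
    ss = np.random.SeedSequence(entropy=int(seed) % _MOD, spawn_key=tuple(int(t) for t in tags))
    return int(ss.generate_state(1)[0]) % _MOD


def rng_from(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(derive(seed, *tags))
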