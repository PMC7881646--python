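"""Deterministic random-stream management.

One root seed spawns independent child streams (one per permutation
replicate, one per pipeline stage), so results are bit-reproducible and
invariant to execution order.
"""

from __future__ import annotations

import numpy as np


def root_sequence(seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(int(seed))


def spawn_generators(seed: int | np.random.SeedSequence, k: int) -> list[np.random.Generator]:
    """k independent generators derived from one root seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else root_sequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(k)]


def generator(seed: int | np.random.SeedSequence) -> np.random.Generator:
    ss = seed if isinstance(seed, np.random.SeedSequence) else root_sequence(seed)
    return np.random.Generator(np.random.PCG64(ss))


def permutation_block(seed: int | np.random.SeedSequence, K: int, n: int) -> np.ndarray:
    """K permutations of range(n), one per independent substream, as a (K, n) array."""
    gens = spawn_generators(seed, K)
    out = np.empty((K, n), dtype=np.intp)
    for i, g in enumerate(gens):
        out[i] = g.permutation(n)
    return out
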