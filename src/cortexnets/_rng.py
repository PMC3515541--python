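"""Seed management.

Every stochastic stage receives its own child seed derived from a master
seed through :class:`numpy.random.SeedSequence`, so stages are individually
reproducible and two runs with the same master seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

# Fixed stage keys: spawn_key offsets are stable across runs and versions.
STAGE_KEYS = {
    "cohort": 0,
    "null_graphs": 1,
    "perm_global": 2,
    "perm_nodal": 3,
    "nbs": 4,
    "modularity": 5,
    "clinical": 6,
}


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic child SeedSequence for a named pipeline stage."""
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    return np.random.SeedSequence(master_seed, spawn_key=(STAGE_KEYS[stage],))


def rng_from(seed) -> np.random.Generator:
    """Generator from an int seed, SeedSequence, or existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
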