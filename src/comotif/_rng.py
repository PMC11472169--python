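"""Deterministic fan-out of one user-facing seed into per-stage seeds.

Every stochastic stage (each factorization run, carrier sampling, shuffling,
permutation tests) draws its own integer seed from the global seed through a
``numpy.random.SeedSequence`` keyed on a stage identifier, so stages are
reproducible independently of execution order.
"""

from __future__ import annotations

import numpy as np

# fixed stage identifiers for the spawn key
STAGE_NMF = 1
STAGE_SHUFFLE = 2
STAGE_PERMTEST = 3
STAGE_SYNTH = 4


def stage_seed(base_seed: int, stage: int, *indices: int) -> int:
    """A deterministic 31-bit seed for (base_seed, stage, indices)."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(stage, *indices))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stage_rng(base_seed: int, stage: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(stage_seed(base_seed, stage, *indices))
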