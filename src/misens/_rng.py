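"""Seed handling.

Every stochastic operation in misens accepts ``seed`` as an int, a
``numpy.random.SeedSequence``, an already-constructed ``Generator`` or
``None``, and converts it with :func:`as_generator`. Simulation studies
derive independent per-replicate streams with :func:`replicate_seed` so any
single replicate can be regenerated without running the ones before it.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_generator(seed) -> np.random.Generator:
    """Coerce ``seed`` to a ``numpy.random.Generator`` (PCG64)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replicate_seed(master_seed: int, replicate_id: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream.

    Replicate ``i`` of a study with master seed ``s`` always uses
    ``SeedSequence(s, spawn_key=(i,))``, independent of execution order or
    how many other replicates run.
    """
    return np.random.SeedSequence(int(master_seed), spawn_key=(int(replicate_id),))
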