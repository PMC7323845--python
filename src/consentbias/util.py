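"""Seed bookkeeping shared by every stochastic stage.

Child seeds are a counter-based mix of (master_seed, key...) fed through
``numpy.random.SeedSequence``, so independent pipeline stages and independent
runs within a stage draw from non-overlapping streams while remaining fully
reproducible from the single master seed.
"""

from __future__ import annotations

import numpy as np

# stage tags; stage commands and the end-to-end pipeline must agree on these
STAGE_SIMULATE = 0
STAGE_IMPUTE = 1
STAGE_BOOTSTRAP = 2
STAGE_PSM = 3
STAGE_CROSSVAL = 4


def child_seed_sequence(master_seed: int, *keys: int) -> np.random.SeedSequence:
    """SeedSequence for (master_seed, key_1, ..., key_n)."""
    return np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in keys))


def child_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Generator seeded deterministically from (master_seed, keys)."""
    return np.random.default_rng(child_seed_sequence(master_seed, *keys))


def child_seed_int(master_seed: int, *keys: int) -> int:
    """A 31-bit integer identifying the child stream (for manifests/logs)."""
    return int(child_seed_sequence(master_seed, *keys).generate_state(1, np.uint32)[0] % (2**31))


def as_rng(rng: int | np.random.Generator) -> np.random.Generator:
    """Coerce an integer seed or Generator to a Generator.

    Anything else (in particular None, i.e. an unseeded source) is refused:
    every stochastic step must be traceable to an explicit seed.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    raise ReproducibilityError(
        "random source must be an integer seed or a numpy Generator, got "
        f"{type(rng).__name__}; unseeded randomness is not reproducible"
    )


class ReproducibilityError(ValueError):
    """An operation was asked to run without an explicit seed."""
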