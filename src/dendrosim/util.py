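"""Random-state plumbing shared across modules.

All randomness flows from one root seed.  Child streams are derived with
``numpy.random.SeedSequence.spawn``, so a dataset built from a given seed is
bit-identical regardless of how many other streams were derived before it.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from ``seed``."""
    if isinstance(seed, np.random.Generator):
        return seed.spawn(n)
    if isinstance(seed, np.random.SeedSequence):
        seqs = seed.spawn(n)
    else:
        seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def spawn_seedseqs(seed, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` child seed sequences (for manifests / replay)."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)
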