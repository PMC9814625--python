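"""Deterministic seed derivation: one master seed, many independent streams."""

from __future__ import annotations

import numpy as np

# fixed stage tags so streams never collide across pipeline stages
TAG_UNDERSAMPLE = 1
TAG_SPLIT = 2
TAG_FOREST = 3
TAG_SAMPLER = 4
TAG_COHORT = 5


def derive_seed(master_seed: int, *tags: int) -> int:
    """A reproducible 31-bit seed derived from (master_seed, tags)."""
    ss = np.random.SeedSequence([int(master_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
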