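"""Seed plumbing: accept ints, None, or SeedSequence everywhere."""

from __future__ import annotations

import numpy as np


def seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
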