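"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int, None, or an existing SeedSequence interchangeably.

    Lets one pipeline seed fan out into independent per-stage substreams
    while every stage also remains callable with a plain integer.
    """
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
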