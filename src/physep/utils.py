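"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Normalise an int / None / SeedSequence into a SeedSequence.

    Accepting SeedSequence objects lets the pipeline hand each stage its own
    spawned child stream while the public API still takes plain integers.
    """
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
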