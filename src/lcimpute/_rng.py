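"""Named random substreams derived from a single master seed.

Every stochastic stage (panel, offspring, reads, thinning, trait, ...) draws
from its own substream so that changing one stage's consumption never
perturbs another's, and a run is reproducible from one integer seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """A Generator keyed by the master seed and a tuple of stream names."""
    keys = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))
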