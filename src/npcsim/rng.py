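"""Named, independent random-number streams derived from one master seed.

Every stochastic ingredient of a simulation (lateral forces, axial offsets,
tilt, shift, per-NPC parameter draws, labelling, elongation orientation)
draws from its own stream, keyed by (stream name, NPC index).  Toggling one
variability type therefore never perturbs the draws of another, and reruns
from a recorded master seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

# Fixed stream ids; order is part of the reproducibility contract.
STREAMS = {
    "params": 0,
    "forces": 1,
    "axial": 2,
    "tilt": 3,
    "shift": 4,
    "elongation": 5,
    "labelling": 6,
    "placement": 7,
}


def stream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for stream `name` of NPC `index` under `master_seed`."""
    try:
        sid = STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown rng stream {name!r}; known: {sorted(STREAMS)}") from None
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(sid, int(index)))
    return np.random.default_rng(ss)
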