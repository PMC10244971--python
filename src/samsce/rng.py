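"""Counter-based random streams.

Every stochastic decision in the simulator draws from a stream keyed by
(seed, purpose, cell id, event counter).  Streams are independent of each
other and of iteration order, so trajectories are reproducible and a draw
consumed for one purpose never shifts the randomness seen by another —
which is what makes the 2D variant bit-identical to a P3D run whose
out-of-plane probabilities are all zero.
"""

from __future__ import annotations

import numpy as np

# purpose codes
POLARIZATION = 1
DIVISION_PLANE = 2
CYTOPLASM_JITTER = 3
REPLICATE = 4
INIT = 5


def stream(seed: int, *keys: int) -> np.random.Generator:
    """Return an independent Generator keyed by ``seed`` and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *[int(k) for k in keys]]))


def replicate_seed(base_seed: int, arm_index: int, replicate: int) -> int:
    """Derive a per-replicate integer seed < 2**31 from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), REPLICATE, int(arm_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
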