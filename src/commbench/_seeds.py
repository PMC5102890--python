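"""Deterministic per-instance seed derivation.

One master seed drives the whole study.  Every instance/run gets its own
31-bit child seed via a counter scheme on numpy's SeedSequence:

    child = SeedSequence(master, spawn_key=(stream, condition, replicate, run))
             .generate_state(1)[0] mod 2**31

Stream codes keep the generator families statistically independent even when
condition/replicate indices collide.
"""

from __future__ import annotations

import numpy as np

STREAM_CORR = 1
STREAM_LFR = 2
STREAM_DETECT = 3
STREAM_STABILITY = 4


def derive_seed(master_seed: int, *keys: int) -> int:
    """31-bit child seed for the given (stream, condition, replicate, ...) path."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))
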