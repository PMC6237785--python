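"""Derived random streams.

Every stochastic operation draws from a stream derived from one master seed
and a fixed per-operation key, so modules can be re-run in isolation and a
whole pipeline is reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np

# fixed stream keys; append only, never renumber
STREAMS = {
    "genome": 1,
    "nicks": 2,
    "rloops": 3,
    "nickase": 4,
    "rdna": 5,
    "signal": 6,
    "labeling": 7,
    "combing": 8,
    "shuffle": 9,
    "resample": 10,
    "plan": 11,
    "bootstrap": 12,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Generator for the named stream derived from ``seed``."""
    if stream not in STREAMS:
        raise KeyError(f"unknown stream {stream!r}; known: {sorted(STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(STREAMS[stream],)))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either a Generator or an integer seed."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
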