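"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from nicksim.fragmentation import Molecule


def brute_split(length: int, cuts) -> list[int]:
    """Independent splitter: fragment sizes of [0, length) cut at ``cuts``."""
    inner = sorted({int(c) for c in cuts if 0 < int(c) < length})
    edges = [0] + inner + [length]
    return [b - a for a, b in zip(edges[:-1], edges[1:])]


def brute_s1_sizes(length, top, bottom) -> list[int]:
    return brute_split(length, set(top) | set(bottom))


def brute_denature_sizes(length, top, bottom) -> list[int]:
    return brute_split(length, top) + brute_split(length, bottom)


def brute_apposed_cuts(top, bottom, window) -> set[int]:
    return {
        (t + b) // 2 for t in top for b in bottom if abs(t - b) <= window
    }


def median(xs) -> float:
    return float(np.median(np.asarray(list(xs), dtype=float)))


@pytest.fixture
def simple_molecule() -> Molecule:
    """1 kb duplex with one nick per strand (top 300, bottom 700)."""
    return Molecule(1000, np.array([300]), np.array([700]))
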