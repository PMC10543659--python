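"""Shared fixtures and independent reference implementations.

The naive coders below deliberately avoid the package's vectorized paths:
transitions are counted by an explicit loop and codes are computed center by
center with Python arithmetic, so they can serve as oracles for the
production implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from lbpradiomics.neighborhoods import GroupedNeighborhood


def naive_riu2(bits) -> int:
    """Reference riu2 mapping: explicit circular transition count."""
    bits = [int(b) for b in bits]
    p = len(bits)
    transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
    return sum(bits) if transitions <= 2 else p + 1


def naive_encode(image: np.ndarray, grouping: GroupedNeighborhood, group_index: int) -> np.ndarray:
    """Reference per-pixel double-loop coder for one group."""
    img = np.asarray(image, dtype=float)
    m = grouping.valid_margin
    h, w = img.shape
    offsets = grouping.groups[group_index - 1]
    out = np.empty((h - 2 * m, w - 2 * m), dtype=int)
    for i in range(m, h - m):
        for j in range(m, w - m):
            c = img[i, j]
            bits = [1 if img[i + dr, j + dc] >= c else 0 for dr, dc in offsets]
            out[i - m, j - m] = naive_riu2(bits)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image(rng):
    return rng.integers(0, 256, size=(20, 20)).astype(float)
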