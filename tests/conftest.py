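"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive run and pair enumeration from first
principles (python loops over explicit coordinates) so they share no code with
the vectorized implementations they check.
"""

from __future__ import annotations

from itertools import groupby

import numpy as np
import pytest

from mucotex.images import GreyImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_grey(rng: np.random.Generator, shape=(8, 8), bit_depth=2) -> GreyImage:
    """Random test image with 2**bit_depth levels."""
    return GreyImage(rng.integers(0, 2**bit_depth, size=shape), bit_depth=bit_depth)


def _oracle_lines(pixels: np.ndarray, direction: int) -> list[list[int]]:
    """Scan lines as explicit coordinate walks (independent of the package)."""
    h, w = pixels.shape
    lines = []
    if direction == 0:
        for r in range(h):
            lines.append([int(pixels[r, c]) for c in range(w)])
    elif direction == 90:
        for c in range(w):
            lines.append([int(pixels[r, c]) for r in range(h)])
    elif direction == 45:
        # anti-diagonals: constant r + c
        for s in range(h + w - 1):
            lines.append([int(pixels[r, s - r])
                          for r in range(h) if 0 <= s - r < w])
    elif direction == 135:
        # main diagonals: constant r - c
        for s in range(-(w - 1), h):
            lines.append([int(pixels[r, r - s])
                          for r in range(h) if 0 <= r - s < w])
    else:
        raise ValueError(direction)
    return lines


def oracle_runs(pixels: np.ndarray, direction: int) -> dict[tuple[int, int], int]:
    """Maximal-run counts {(level, length): count} by direct enumeration."""
    counts: dict[tuple[int, int], int] = {}
    for line in _oracle_lines(pixels, direction):
        for level, grp in groupby(line):
            key = (level, len(list(grp)))
            counts[key] = counts.get(key, 0) + 1
    return counts


ORACLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_pairs(pixels: np.ndarray, distance: int, angle: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pixel-pair enumeration."""
    h, w = pixels.shape
    dr, dc = (o * distance for o in ORACLE_OFFSETS[angle])
    n = int(pixels.max()) + 1
    counts = np.zeros((16, 16), dtype=np.int64)  # generous fixed size
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = int(pixels[r, c]), int(pixels[r2, c2])
                counts[i, j] += 1
                counts[j, i] += 1
    return counts
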