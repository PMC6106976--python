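"""Seeded region growing with a gray-level homogeneity criterion.

A pixel joins the region when the absolute difference between its gray
value and the running mean of the region is strictly less than the
tolerance W.  On the binary preprocessed image this is trivially robust:
any W in (0, 1] and any seed inside a white component recover exactly that
4-connected component.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import BinaryMask, Image2D

__all__ = ["SeedSet", "region_grow", "fill_holes"]

_NEIGHBORS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class SeedSet:
    """Non-empty list of (row, col) seed pixels inside the image bounds."""

    seeds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.seeds) == 0:
            raise ValueError("at least one seed is required")
        object.__setattr__(
            self, "seeds", tuple((int(r), int(c)) for r, c in self.seeds)
        )

    def validate_within(self, shape: tuple[int, int]) -> None:
        for r, c in self.seeds:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"seed ({r}, {c}) outside image of shape {shape}")


def region_grow(
    image: Image2D,
    seeds: SeedSet | Sequence[tuple[int, int]],
    W: float,
) -> BinaryMask:
    """Grow one region per seed; the result is their union.

    Growth is breadth-first over 4-neighbours (FIFO queue); the region
    mean is updated incrementally after every accepted pixel, and the
    acceptance criterion is strict: |value - mean| < W.
    """
    if W <= 0:
        raise ValueError("W must be > 0")
    if not isinstance(seeds, SeedSet):
        seeds = SeedSet(tuple(seeds))
    seeds.validate_within(image.shape)

    px = image.pixels
    rows, cols = px.shape
    out = np.zeros((rows, cols), dtype=np.uint8)
    for seed in seeds.seeds:
        visited = np.zeros((rows, cols), dtype=bool)
        region = np.zeros((rows, cols), dtype=bool)
        r0, c0 = seed
        region[r0, c0] = True
        visited[r0, c0] = True
        total = float(px[r0, c0])
        count = 1
        queue: deque[tuple[int, int]] = deque([seed])
        while queue:
            r, c = queue.popleft()
            for dr, dc in _NEIGHBORS_4:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or visited[rr, cc]:
                    continue
                visited[rr, cc] = True
                if abs(px[rr, cc] - total / count) < W:
                    region[rr, cc] = True
                    total += float(px[rr, cc])
                    count += 1
                    queue.append((rr, cc))
        out |= region
    return BinaryMask(out, image.spacing)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background components not connected to the image border.

    Background connectivity is 4-neighbour; foreground is unchanged.
    """
    filled = ndimage.binary_fill_holes(
        mask.astype_bool(), structure=ndimage.generate_binary_structure(2, 1)
    )
    return BinaryMask(filled.astype(np.uint8), mask.spacing)
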