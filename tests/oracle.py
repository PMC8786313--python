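"""Independent brute-force oracles used to cross-check the pipelines.

Deliberately naive pure-Python implementations (no scikit-image), so the
tested code path and the oracle share nothing.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBOURS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBOURS_8 = NEIGHBOURS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Component sizes of a 2-D boolean mask by breadth-first flood fill."""
    nbrs = NEIGHBOURS_8 if connectivity == 8 else NEIGHBOURS_4
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    ny, nx = mask.shape
    sizes = []
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        size = 0
        queue = deque([(sy, sx)])
        seen[sy, sx] = True
        while queue:
            y, x = queue.popleft()
            size += 1
            for dy, dx in nbrs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not seen[yy, xx]:
                    seen[yy, xx] = True
                    queue.append((yy, xx))
        sizes.append(size)
    return sizes


def count_components(
    mask: np.ndarray, min_size: int = 5, max_size: int = 1000, connectivity: int = 8
) -> int:
    """Number of size-passing components, the detection-stage oracle."""
    return sum(
        1 for s in flood_fill_components(mask, connectivity) if min_size <= s <= max_size
    )


def circle_pixels_brute(center: tuple[float, float], radius: float, extent: int) -> int:
    """Count pixels whose center lies within the circle, by enumeration."""
    cy, cx = center
    return sum(
        1
        for y in range(extent)
        for x in range(extent)
        if (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
    )
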