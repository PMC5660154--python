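"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: exhaustive
search instead of fixed-point iteration, queue-based flood fill instead of
scipy labeling, direct formulas instead of library statistics.
"""

from collections import deque

import numpy as np


def isodata_fixed_points(values: np.ndarray) -> list[int]:
    """All integer thresholds t in 1..255 satisfying the ISODATA fixed-point
    condition |t - (mean(v < t) + mean(v >= t)) / 2| <= 0.5 (8-bit data)."""
    values = np.asarray(values).ravel()
    out = []
    for t in range(1, 256):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        m = 0.5 * (lo.mean() + hi.mean())
        if abs(t - m) <= 0.5:
            out.append(t)
    return out


def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Number of connected components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    seen = np.zeros(mask.shape, dtype=bool)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < mask.shape[0]
                    and 0 <= n[1] < mask.shape[1]
                    and 0 <= n[2] < mask.shape[2]
                    and mask[n]
                    and not seen[n]
                ):
                    seen[n] = True
                    queue.append(n)
    return count


def discrete_dog_center_value(sigma_small: float, sigma_large: float) -> float:
    """Central coefficient of the separable discrete 3-D DoG kernel
    (sampled Gaussian, radius int(4 sigma + 0.5), normalized per axis)."""

    def center_coeff(sigma: float) -> float:
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        return w[radius]

    return center_coeff(sigma_small) ** 3 - center_coeff(sigma_large) ** 3
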