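"""Independent brute-force region merger used as a segmentation oracle.

Re-implements greedy lowest-cost-first region merging with none of the
production code's machinery: regions are plain pixel-index sets, every
adjacent pair's cost is recomputed from raw pixel values at every step,
and the global minimum is found by linear scan.  O(n² · merges) — only
usable on tiny instances, which is the point.
"""

from __future__ import annotations

import numpy as np


def _sd(values: np.ndarray) -> float:
    return float(np.std(values))


def _cost(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
    merged = np.concatenate([vals_a, vals_b])
    return (
        len(merged) * _sd(merged) - len(vals_a) * _sd(vals_a) - len(vals_b) * _sd(vals_b)
    )


def _adjacent(region_a: set, region_b: set) -> bool:
    for r, c in region_a:
        if ((r + 1, c) in region_b or (r - 1, c) in region_b
                or (r, c + 1) in region_b or (r, c - 1) in region_b):
            return True
    return False


def brute_force_segment(
    img: np.ndarray, scale: float, dn_scale: float = 255.0
) -> tuple[list[frozenset], list[float]]:
    """Greedy merge by full recomputation; 4-connectivity.

    Returns the final partition (list of frozensets of (row, col)) and
    the accepted merge-cost history.
    """
    dn = np.asarray(img, dtype=float) * dn_scale
    rows, cols = dn.shape
    regions: list[set] = [{(r, c)} for r in range(rows) for c in range(cols)]
    threshold = scale * scale
    history: list[float] = []

    def values(region: set) -> np.ndarray:
        return np.array([dn[r, c] for r, c in region])

    while len(regions) > 1:
        best = None
        best_cost = None
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if not _adjacent(regions[i], regions[j]):
                    continue
                c = _cost(values(regions[i]), values(regions[j]))
                if best_cost is None or c < best_cost:
                    best_cost = c
                    best = (i, j)
        if best is None or best_cost > threshold:
            break
        i, j = best
        history.append(best_cost)
        regions[i] = regions[i] | regions[j]
        del regions[j]
    return [frozenset(r) for r in regions], history
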