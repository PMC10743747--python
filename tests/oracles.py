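"""Independent brute-force oracles used to check the implementation.

These deliberately avoid scipy's labelling and the package's dynamic
programming: flood fill by explicit BFS, nearest-pixel assignment by
exhaustive pairwise distances, and sequence selection by full enumeration.
"""

from collections import deque
from itertools import product

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """All connected components of a boolean mask, as sets of (row, col)."""
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        comp = set()
        q = deque([(int(r0), int(c0))])
        seen[r0, c0] = True
        while q:
            r, c = q.popleft()
            comp.add((r, c))
            for dr, dc in steps:
                nr, nc = r + dr, c + dc
                if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1] \
                        and mask[nr, nc] and not seen[nr, nc]:
                    seen[nr, nc] = True
                    q.append((nr, nc))
        comps.append(comp)
    return comps


def nearest_component_assignment(el_pixels, components):
    """For each EL pixel, the index of the component holding its nearest
    pixel (exact integer squared distance; ties -> lowest component index).

    ``components`` must already be ordered the way the implementation
    orders sub-clusters (size descending), so index ties favour the larger.
    """
    out = []
    for (r, c) in el_pixels:
        best = None
        for idx, comp in enumerate(components):
            d2 = min((r - cr) ** 2 + (c - cc) ** 2 for cr, cc in comp)
            if best is None or d2 < best[0]:
                best = (d2, idx)
        out.append(best[1])
    return out


def enumerate_best_sequence(candidates_per_slice):
    """Exhaustive minimum of summed consecutive centroid distances.

    ``candidates_per_slice``: list of lists of clusters (empty slices
    already removed). Returns the index tuple minimising
    (total_distance, -total_size, indices) — the same ordering the DP uses.
    """
    best = None
    for indices in product(*(range(len(c)) for c in candidates_per_slice)):
        chosen = [cands[i] for cands, i in zip(candidates_per_slice, indices)]
        dist = 0.0
        for a, b in zip(chosen, chosen[1:]):
            dist += float(np.hypot(a.centroid[0] - b.centroid[0],
                                   a.centroid[1] - b.centroid[1]))
        key = (dist, -sum(c.size for c in chosen), indices)
        if best is None or key < best:
            best = key
    return best
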