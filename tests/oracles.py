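"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: plateaus are found by
explicit flood fill and neighbour inspection, and point matching is
checked against optimal bipartite matching from scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
NEIGHBOURS_4 = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def brute_force_regional_maxima(
    values: np.ndarray, roi: np.ndarray, connectivity: int = 8, min_area: int = 1
) -> set[frozenset[tuple[int, int]]]:
    """All regional-maximum plateaus inside ``roi`` by explicit search.

    Flood-fills every equal-valued plateau restricted to the ROI and
    keeps it iff every ROI neighbour of the plateau is strictly lower.
    A plateau equal to the whole ROI is dropped as degenerate, as are
    plateaus below ``min_area``.
    """
    nbrs = NEIGHBOURS_8 if connectivity == 8 else NEIGHBOURS_4
    h, w = values.shape
    seen = np.zeros_like(roi, dtype=bool)
    roi_area = int(roi.sum())
    result: set[frozenset[tuple[int, int]]] = set()
    for r0 in range(h):
        for c0 in range(w):
            if not roi[r0, c0] or seen[r0, c0]:
                continue
            v = values[r0, c0]
            plateau = [(r0, c0)]
            seen[r0, c0] = True
            stack = [(r0, c0)]
            is_max = True
            while stack:
                r, c = stack.pop()
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not roi[rr, cc]:
                        continue
                    if values[rr, cc] == v:
                        if not seen[rr, cc]:
                            seen[rr, cc] = True
                            plateau.append((rr, cc))
                            stack.append((rr, cc))
                    elif values[rr, cc] > v:
                        is_max = False
            if is_max and len(plateau) >= min_area and len(plateau) != roi_area:
                result.add(frozenset(plateau))
    return result


def optimal_matching_tp(detections: np.ndarray, truths: np.ndarray, radius: float) -> int:
    """Maximum number of one-to-one detection/truth pairs within radius."""
    if len(detections) == 0 or len(truths) == 0:
        return 0
    diff = detections[:, None, :] - truths[None, :, :]
    adj = (np.sqrt((diff**2).sum(-1)) <= radius).astype(int)
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int((match >= 0).sum())
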