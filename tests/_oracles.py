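"""Independent oracles shared across test modules.

These deliberately avoid the package's algorithms: least-cost distances come
from exhaustive enumeration of simple paths (depth-first, with a sound
cost bound so the search stays exact while finite).
"""

import math

import numpy as np


def brute_force_least_cost(cost: np.ndarray, sources: np.ndarray, connectivity: int = 8):
    rows, cols = cost.shape
    if connectivity == 4:
        moves = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0)]
    else:
        d = math.sqrt(2.0)
        moves = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
                 (-1, -1, d), (-1, 1, d), (1, -1, d), (1, 1, d)]
    best = np.full((rows, cols), np.inf)
    for r in range(rows):
        for c in range(cols):
            if sources[r, c]:
                best[r, c] = 0.0

    def dfs(r, c, acc, visited):
        for dr, dc, step in moves:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols) or (nr, nc) in visited:
                continue
            na = acc + 0.5 * (cost[r, c] + cost[nr, nc]) * step
            if na < best[nr, nc]:
                best[nr, nc] = na
                dfs(nr, nc, na, visited | {(nr, nc)})

    for r in range(rows):
        for c in range(cols):
            if sources[r, c]:
                dfs(r, c, 0.0, {(r, c)})
    return best
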