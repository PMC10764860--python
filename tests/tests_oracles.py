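"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_average_linkage(X):
    """O(n^3) agglomeration: recompute every pairwise average linkage at
    every step; lowest-(min id, max id) tie-break."""
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = np.mean([np.linalg.norm(X[p] - X[q])
                             for p in clusters[a] for q in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, next_id))
        next_id += 1
    return merges
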