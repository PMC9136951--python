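"""Independent brute-force average-linkage oracle shared by tests."""

import numpy as np

SAME_FRAME = 1.0e6


def brute_force_average_linkage(positions, frame_ids, cutoff):
    """Naive agglomeration: repeatedly merge the pair of clusters with the
    smallest average inter-cluster distance (same-frame pairs counted at an
    arbitrarily high distance) until that minimum exceeds the cutoff."""
    positions = np.asarray(positions, float)
    clusters = [[i] for i in range(len(positions))]

    def avg_dist(ca, cb):
        total = 0.0
        for i in ca:
            for j in cb:
                if frame_ids[i] == frame_ids[j]:
                    total += SAME_FRAME
                else:
                    total += float(np.linalg.norm(positions[i] - positions[j]))
        return total / (len(ca) * len(cb))

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = avg_dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        if best[0] > cutoff:
            break
        _, x, y = best
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return {frozenset(c) for c in clusters}
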