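"""Independent reference implementations used as test oracles."""

import math

from shapely.geometry import MultiPoint, Point


def locoh_bruteforce(pts, k, fraction):
    """Fixed-k LoCoH by explicit neighbour sort and greedy union by area."""
    pts = [tuple(p) for p in pts]
    n = len(pts)
    hulls = []
    for i in range(n):
        by_dist = sorted(range(n), key=lambda j: (math.dist(pts[i], pts[j]), j))
        hulls.append(MultiPoint([pts[j] for j in by_dist[:k]]).convex_hull)
    union = None
    for i in sorted(range(n), key=lambda i: (hulls[i].area, i)):
        union = hulls[i] if union is None else union.union(hulls[i])
        covered = sum(union.covers(Point(p)) for p in pts)
        if covered >= fraction * n:
            break
    return union
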