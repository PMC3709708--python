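"""Independent reference implementations used as oracles by the tests and
by scripts/acceptance.py.  These are deliberately naive (plain loops, plain
math) and share no code with the package internals they check."""

import math

import numpy as np


def naive_hbond(n, h, o, max_distance=0.25, min_angle=135.0):
    """Plain-math hydrogen-bond criterion (strict inequalities)."""
    d = math.dist(h, o)
    v1 = np.asarray(n) - np.asarray(h)
    v2 = np.asarray(o) - np.asarray(h)
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return d < max_distance and ang > min_angle


def daura_reference(matrix, cutoff):
    """O(n^3) neighbor-count clustering, recomputing neighborhoods from
    scratch on the surviving set at every iteration."""
    n = matrix.shape[0]
    remaining = set(range(n))
    assignments = np.zeros(n, dtype=int)
    centers = []
    cid = 0
    while remaining:
        cid += 1
        best_center, best_members = None, None
        for i in sorted(remaining):
            members = {
                j for j in remaining if j != i and matrix[i, j] < cutoff
            }
            members.add(i)
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        for j in best_members:
            assignments[j] = cid
        centers.append(best_center)
        remaining -= best_members
    sizes = np.bincount(assignments)[1:]
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(len(order) + 1, dtype=int)
    relabel[order + 1] = np.arange(1, len(order) + 1)
    relabel[0] = 0
    return relabel[assignments], np.asarray(centers)[order], sizes[order] / n


def loop_minima(F):
    """Exhaustive 8-neighbor strict-minimum check on a grid with NaN
    marking unsampled bins; returns sorted (i, j) index pairs."""
    nx, ny = F.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            if np.isnan(F[i, j]):
                continue
            neigh = [
                F[a, b]
                for a in range(max(0, i - 1), min(nx, i + 2))
                for b in range(max(0, j - 1), min(ny, j + 2))
                if (a, b) != (i, j) and not np.isnan(F[a, b])
            ]
            if all(F[i, j] < v for v in neigh):
                out.append((i, j))
    return sorted(out)
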