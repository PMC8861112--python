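"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function re-implements, from scratch and without touching the package's
code paths, the operation it is used to check.
"""

import itertools
import math

import numpy as np
from scipy import stats


def exact_rank_sum_p(x, y, alternative):
    """Enumerate every C(n+m, n) assignment of the pooled ranks to the
    y-group to obtain the exact permutation p-value."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_y = len(y)
    obs = ranks[len(x):].sum()
    total = count_ge = count_le = 0
    for comb in itertools.combinations(range(len(pooled)), n_y):
        s = ranks[list(comb)].sum()
        total += 1
        if s >= obs - 1e-9:
            count_ge += 1
        if s <= obs + 1e-9:
            count_le += 1
    if alternative == "greater":
        return count_ge / total
    return min(1.0, 2.0 * min(count_ge, count_le) / total)


def daura_brute_force(coords, cutoff):
    """Greedy RMSD-neighbor clustering with explicit lists and its own SVD
    superposition, recomputing neighbor counts from scratch each round."""

    def pair_rmsd(i, j):
        a, b = coords[i], coords[j]
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        h = bc.T @ ac
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        moved = bc @ rot
        return float(np.sqrt(np.mean(np.sum((moved - ac) ** 2, axis=1))))

    n = coords.shape[0]
    pool = list(range(n))
    clusters = []
    while pool:
        best_center, best_members = None, None
        for c in pool:
            members = [f for f in pool if pair_rmsd(c, f) <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        clusters.append((best_center, best_members))
        for f in best_members:
            pool.remove(f)
    order = sorted(range(len(clusters)),
                   key=lambda k: (-len(clusters[k][1]), clusters[k][0]))
    assignments = np.empty(n, dtype=int)
    for rank, k in enumerate(order):
        for f in clusters[k][1]:
            assignments[f] = rank
    pops = np.array([len(clusters[k][1]) / n for k in order])
    centers = np.array([clusters[k][0] for k in order])
    return assignments, pops, centers


def hbond_brute_force(d, h, a, d_cut=0.35, a_cut=30.0):
    """Plain-scalar geometric hydrogen-bond check."""
    dist = math.sqrt(sum((a[k] - d[k]) ** 2 for k in range(3)))
    u = [h[k] - d[k] for k in range(3)]
    v = [a[k] - d[k] for k in range(3)]
    dot = sum(u[k] * v[k] for k in range(3))
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))
    return dist <= d_cut and ang <= a_cut
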