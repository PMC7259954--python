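"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle deliberately avoids the code path it checks: exact rational
arithmetic for the Fisher test, a refined SO(3) rotation grid for
superposition RMSD, exhaustive partition search for Ward, power iteration
for the stationary distribution.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np
from scipy.spatial.transform import Rotation


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, in exact rational arithmetic (probability-mass rule)."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        bb, cc, dd = r1 - k, c1 - k, r2 - (c1 - k)
        if min(k, bb, cc, dd) < 0:
            return Fraction(0)
        return Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1),
            factorial(n) * factorial(k) * factorial(bb) * factorial(cc) * factorial(dd))

    p_obs = prob(a)
    total = sum(p for k in range(0, min(r1, c1) + 1)
                if (p := prob(k)) <= p_obs)
    return float(total)


def rmsd_rotation_grid(mobile, reference, coarse_deg=10.0, refinements=3):
    """Minimum RMSD over rigid transforms by a refined Euler-angle grid search."""
    a = np.asarray(mobile, float)
    b = np.asarray(reference, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def evaluate(angles):
        R = Rotation.from_euler("zyz", angles).as_matrix()  # (m, 3, 3)
        rotated = np.einsum("mij,nj->mni", R, a)
        return np.sqrt(((rotated - b) ** 2).sum(axis=(1, 2)) / len(a))

    centers = np.array([[0.0, 0.0, 0.0]])
    step = coarse_deg
    grid1 = np.arange(0.0, 360.0, coarse_deg)
    grid2 = np.arange(0.0, 180.0 + coarse_deg, coarse_deg)
    angles = np.array(np.meshgrid(grid1, grid2, grid1)).reshape(3, -1).T
    best = None
    for _ in range(refinements + 1):
        all_angles = (centers[:, None, :] + angles[None, :, :]).reshape(-1, 3) \
            if best is not None else angles
        rmsds = evaluate(all_angles)
        i = int(np.argmin(rmsds))
        best = float(rmsds[i])
        centers = all_angles[i][None, :]
        step /= 10.0
        offs = np.linspace(-step * 10, step * 10, 21)
        angles = np.array(np.meshgrid(offs, offs, offs)).reshape(3, -1).T
    return best


def ward_two_partition(points):
    """Best 2-partition of 1-D/any-D points by exhaustive within-cluster
    sum-of-squares minimization."""
    X = np.asarray(points, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    best, best_labels = np.inf, None
    for r in range(1, n // 2 + 1):
        for idx in combinations(range(n), r):
            mask = np.zeros(n, bool)
            mask[list(idx)] = True
            sse = (((X[mask] - X[mask].mean(0)) ** 2).sum()
                   + ((X[~mask] - X[~mask].mean(0)) ** 2).sum())
            if sse < best:
                best = sse
                best_labels = mask.copy()
    return best_labels


def stationary_power_iteration(T, n_iter=1000):
    """Stationary distribution as a row of T^n for large n."""
    P = np.linalg.matrix_power(np.asarray(T, float), n_iter)
    return P[0]


def knn_brute_force(labeled, labels, query, k):
    """Majority label of the k nearest points by full distance sort; ties go
    to the tied label with the nearest member."""
    labeled = np.asarray(labeled, float)
    d = np.linalg.norm(labeled - np.asarray(query, float), axis=1)
    order = np.argsort(d, kind="stable")[:k]
    neigh = [labels[i] for i in order]
    counts = {}
    for lab in neigh:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for lab in neigh:
        if lab in tied:
            return lab


def mfpt_monte_carlo(T, source, target, n_chains, seed, max_steps=100000):
    """Mean first-passage steps by direct chain simulation (all chains
    advanced in parallel)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(np.asarray(T, float), axis=1)
    cum[:, -1] = 1.0
    state = np.full(n_chains, source)
    steps = np.zeros(n_chains, dtype=np.int64)
    active = state != target
    for _ in range(max_steps):
        if not active.any():
            return steps.mean()
        u = rng.random(active.sum())
        state[active] = (cum[state[active]] > u[:, None]).argmax(axis=1)
        steps[active] += 1
        active = state != target
    raise RuntimeError("chains did not all reach the target")
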