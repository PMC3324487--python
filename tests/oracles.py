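"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: transitive
closure over all feature pairs for matching, the literal step-up rule
for BH, all-pairs counting for the AUC, full enumeration for rank-test
and rank-correlation p-values.
"""

from itertools import combinations, permutations

import numpy as np


def transitive_closure_clusters(mass, time, mass_tol_fn, time_tol_fn):
    """Union-find over all pairs considered identical (pairwise windows
    evaluated conservatively at the smaller tolerance of the pair)."""
    n = len(mass)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        mtol = min(
            mass_tol_fn(mass[i]) * mass[i], mass_tol_fn(mass[j]) * mass[j]
        ) * 1e-6
        ttol = min(time_tol_fn(time[i]), time_tol_fn(time[j]))
        if abs(mass[i] - mass[j]) <= mtol and abs(time[i] - time[j]) <= ttol:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    labels = [find(i) for i in range(n)]
    remap = {}
    return [remap.setdefault(l, len(remap)) for l in labels]


def clusters_window_consistent(
    labels, mass, time, sample, mass_tol_fn, time_tol_fn, margin=1.0
):
    """True when the oracle partition is unambiguous.

    Intra-cluster pairs must sit within both windows at the *smaller*
    tolerance, clusters must not repeat a sample, and cross-cluster
    pairs must sit outside at least one window at the *larger* tolerance
    times ``margin``.
    """
    n = len(mass)
    for i, j in combinations(range(n), 2):
        lo_m = min(mass_tol_fn(mass[i]) * mass[i], mass_tol_fn(mass[j]) * mass[j]) * 1e-6
        hi_m = max(mass_tol_fn(mass[i]) * mass[i], mass_tol_fn(mass[j]) * mass[j]) * 1e-6
        lo_t = min(time_tol_fn(time[i]), time_tol_fn(time[j]))
        hi_t = max(time_tol_fn(time[i]), time_tol_fn(time[j]))
        dm, dt = abs(mass[i] - mass[j]), abs(time[i] - time[j])
        if labels[i] == labels[j]:
            if sample[i] == sample[j]:
                return False
            if dm > lo_m or dt > lo_t:
                return False
        else:
            if dm <= hi_m * margin and dt <= hi_t * margin:
                return False
    return True


def bh_stepup(pvalues):
    """Literal BH step-up: find largest k with p_(k) <= k/m * q and
    report adjusted values by the textbook recursion."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        adj[i] = val
        prev = val
    return adj


def auc_all_pairs(case, control):
    wins = 0.0
    for c in case:
        for k in control:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case) * len(control))


def ranksum_exact_p(case, control):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(list(case) + list(control))
    n1 = len(case)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # tie-free inputs only
    w_obs = sum(ranks[v] for v in case)
    mean_w = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def spearman_exact_p(x, y):
    """Two-sided Spearman p by enumerating all rank permutations."""
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d2_obs = float(((rx - ry) ** 2).sum())
    rho_obs = 1 - 6 * d2_obs / (n * (n**2 - 1))
    count = 0
    total = 0
    base = np.arange(n)
    for perm in permutations(range(n)):
        total += 1
        d2 = float(((np.array(perm) - base) ** 2).sum())
        rho = 1 - 6 * d2 / (n * (n**2 - 1))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total
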