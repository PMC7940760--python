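"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the code paths they check: clustering by explicit
neighbour counting / breadth-first reachability, and superposition by a
dense rotation-grid search with local refinement.
"""

import numpy as np


def brute_force_gromos(rmsd_matrix, cutoff):
    """Neighbour-count clustering restated with explicit set bookkeeping."""
    n = rmsd_matrix.shape[0]
    neigh = rmsd_matrix <= cutoff
    np.fill_diagonal(neigh, True)
    labels = np.full(n, -1)
    cid = 0
    alive = set(range(n))
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            count = len([j for j in alive if neigh[i, j]])
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(alive) if neigh[best, j]]
        for j in members:
            labels[j] = cid
            alive.remove(j)
        cid += 1
    return labels


def brute_force_dbscan(points, eps, min_samples):
    """Density reachability by explicit BFS over core points."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            cur = queue.pop()
            if not core[cur]:
                continue
            for j in np.nonzero(neigh[cur])[0]:
                if labels[j] == -1:
                    labels[j] = cid
                    if core[j]:
                        queue.append(j)
        cid += 1
    return labels


def same_partition(a, b):
    """True when two labelings induce the same partition (noise matched)."""
    mapping = {}
    for x, y in zip(a, b):
        if x == -1 or y == -1:
            if x != y:
                return False
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return True


def grid_search_rmsd(mobile, reference, n=30):
    """Minimum RMSD over an Euler-angle grid plus simplex refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)

    def rmsd_at(euler):
        rot = Rotation.from_euler("zyz", euler).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1)))

    best, best_euler = np.inf, None
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    half = np.linspace(0, np.pi, n // 2)
    for alpha in angles:
        for beta in half:
            for gamma in angles:
                r = rmsd_at([alpha, beta, gamma])
                if r < best:
                    best, best_euler = r, [alpha, beta, gamma]
    res = minimize(rmsd_at, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    return min(best, res.fun)
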