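"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately takes a different computational route from the
code it checks: rotation search by sampling + local refinement instead of
the SVD closed form; exhaustive enumeration of monotone alignments instead
of dynamic programming; a full-matrix rescan at every agglomeration step
instead of incremental distance updates.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_under_rotation(P: np.ndarray, Q: np.ndarray, R: np.ndarray) -> float:
    """RMSD of Q onto P under rotation R with the optimal translation
    (which is always the centroid match)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    diff = Qc @ R.T - Pc
    return float(np.sqrt((diff * diff).sum() / len(P)))


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray, seed: int = 0, n_samples: int = 600) -> float:
    """Minimum superposition RMSD by quaternion sampling + local search.

    Samples proper rotations uniformly, keeps the best few, and refines
    each with Nelder-Mead on the rotation-vector parameterization.
    Independent of the Kabsch closed form.
    """
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_samples, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    scores = []
    for q in quats:
        R = Rotation.from_quat(q).as_matrix()
        scores.append(rmsd_under_rotation(P, Q, R))
    order = np.argsort(scores)

    def objective(rotvec):
        return rmsd_under_rotation(P, Q, Rotation.from_rotvec(rotvec).as_matrix())

    best = np.inf
    for k in order[:5]:
        x0 = Rotation.from_quat(quats[k]).as_rotvec()
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def enumerate_monotone_alignments(n1: int, n2: int):
    """All monotone (i, j) pair sets between ranges of sizes n1 and n2,
    including the empty alignment."""
    for k in range(0, min(n1, n2) + 1):
        for rows in itertools.combinations(range(n1), k):
            for cols in itertools.combinations(range(n2), k):
                yield tuple(zip(rows, cols))


def gap_openings(pairs, n1: int, n2: int) -> int:
    """Number of maximal unmatched runs across both sequences (each run is
    one gap opening under open-cost/free-extension scoring)."""
    count = 0
    for n, axis in ((n1, 0), (n2, 1)):
        matched = {p[axis] for p in pairs}
        in_run = False
        for idx in range(n):
            if idx not in matched:
                if not in_run:
                    count += 1
                    in_run = True
            else:
                in_run = False
    return count


def best_alignment_score_exhaustive(S: np.ndarray, gap_open: float) -> float:
    """Maximum of (sum of matched scores + gap_open per opening) over every
    monotone alignment, by direct enumeration."""
    n1, n2 = S.shape
    best = -np.inf
    for pairs in enumerate_monotone_alignments(n1, n2):
        score = sum(S[i, j] for i, j in pairs) + gap_open * gap_openings(pairs, n1, n2)
        best = max(best, score)
    return best


def upgma_rescan(D: np.ndarray):
    """UPGMA by rescanning the original matrix at every step.

    Clusters are node-index -> leaf-set; the inter-cluster distance is
    recomputed each step as the mean of all original leaf-leaf distances
    (which equals the weighted-average update rule). Returns the merge
    sequence [(left_index, right_index, new_index, height), ...].
    """
    n = D.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_index = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            members_a, members_b = clusters[a], clusters[b]
            d = np.mean([D[i, j] for i in members_a for j in members_b])
            key = (d, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        d, a, b = best
        merges.append((a, b, next_index, d / 2.0))
        clusters[next_index] = clusters.pop(a) | clusters.pop(b)
        next_index += 1
    return merges
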