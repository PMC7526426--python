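"""Rigid-body superposition and TM-score machinery.

Both alignment stages rest on three primitives: the Kabsch closed-form
least-squares superposition, the length-dependent TM-score distance scale
d0, and a fragment-seeded search for the superposition that maximizes the
TM-score of a fixed residue correspondence.

The TM-score of an alignment with residue-pair distances ``d_i`` under a
normalization length ``L`` is

    TM = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2)

with ``d0(L) = max(1.24 * (L - 15)^(1/3) - 1.8, 0.5)`` angstroms. Unlike the
RMSD-minimizing superposition, the TM-score-maximizing one has no closed
form; it is found by seeding superpositions on contiguous alignment
fragments and iteratively re-superposing on the close pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "TMScoreParams",
    "kabsch_superpose",
    "d0_from_length",
    "tm_score",
    "tm_score_optimal",
]


class GeometryError(ValueError):
    """Raised for ill-posed superposition or scoring requests."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant must be +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class TMScoreParams:
    """Normalization length and distance scale of the TM-score."""

    L_norm: int
    d0: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.L_norm < 1:
            raise GeometryError("L_norm must be >= 1")
        if self.d0 <= 0.0:
            object.__setattr__(self, "d0", d0_from_length(self.L_norm))

    @staticmethod
    def from_length(L_norm: int) -> "TMScoreParams":
        return TMScoreParams(L_norm=int(L_norm))


def d0_from_length(L_norm: int) -> float:
    """TM-score distance scale: max(1.24*(L-15)^(1/3) - 1.8, 0.5) angstrom.

    For short chains the cube-root term goes negative and the 0.5 A floor
    engages; the floor keeps the score well defined down to L = 1.
    """
    if L_norm < 1:
        raise GeometryError("L_norm must be >= 1")
    return max(1.24 * np.cbrt(L_norm - 15.0) - 1.8, 0.5)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``Q`` onto ``P`` (Kabsch, via SVD).

    Returns the proper rotation + translation minimizing the RMSD of the
    transformed ``Q`` from ``P``. Reflections are excluded by flipping the
    sign of the smallest singular direction when the raw solution is
    improper. Collinear (rank-deficient) point sets still yield a minimizing
    transform; the result is flagged ``degenerate``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("underdetermined superposition: need at least 3 points")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise GeometryError("coordinates must be finite")

    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (Q - Qc).T @ (P - Pc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Pc - R @ Qc

    transform = RigidTransform(rotation=R, translation=t)
    diff = transform.apply(Q) - P
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    # rank < 2 of the cross-covariance means the rotation about the
    # degenerate axis is arbitrary (though still minimizing)
    degenerate = bool(S[1] <= 1e-9 * max(S[0], 1.0))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_points=n, degenerate=degenerate)


def tm_score(distances, params: TMScoreParams) -> float:
    """TM-score of a set of aligned-pair distances under ``params``."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise GeometryError("need at least one pair distance")
    if (d < 0).any():
        raise GeometryError("distances must be non-negative")
    return float(np.sum(1.0 / (1.0 + (d / params.d0) ** 2)) / params.L_norm)


def _pair_distances(P: np.ndarray, Q: np.ndarray, transform: RigidTransform) -> np.ndarray:
    diff = transform.apply(Q) - P
    return np.sqrt((diff * diff).sum(axis=1))


def tm_score_optimal(
    coords1: np.ndarray,
    coords2: np.ndarray,
    pairs,
    L_norm: int,
) -> tuple[float, RigidTransform]:
    """Maximize the TM-score of a fixed correspondence over superpositions.

    ``pairs`` is a sequence of (i, j) index pairs into ``coords1`` /
    ``coords2``. The search seeds superpositions on contiguous runs of the
    mapped pairs at fragment lengths {m, m/2, m/4} (m = number of mapped
    pairs, minimum fragment length 4), sliding each fragment at half-length
    steps. Each seed is refined by re-superposing on the subset of mapped
    pairs closer than max(d0, 4.5 A) until the subset stabilizes (at most 20
    iterations). The best TM-score seen, over all mapped pairs and
    normalized by ``L_norm``, is returned with its transform.
    """
    pairs = np.asarray(list(pairs), dtype=int)
    if pairs.size == 0:
        raise GeometryError("empty mapping: nothing to superpose")
    params = TMScoreParams.from_length(L_norm)
    P = np.asarray(coords1, dtype=float)[pairs[:, 0]]
    Q = np.asarray(coords2, dtype=float)[pairs[:, 1]]
    m = P.shape[0]
    if m < 3:
        # too few pairs for a well-posed superposition on a sub-fragment;
        # fall back to padding with the full set (requires >= 3 pairs overall)
        raise GeometryError("need at least 3 mapped pairs")

    cutoff = max(params.d0, 4.5)
    frag_lengths = sorted({m, max(m // 2, 4), max(m // 4, 4)}, reverse=True)
    frag_lengths = [f for f in frag_lengths if f <= m]

    best_score = -1.0
    best_transform: RigidTransform | None = None

    for flen in frag_lengths:
        step = max(flen // 2, 1)
        starts = list(range(0, m - flen + 1, step))
        if starts[-1] != m - flen:
            starts.append(m - flen)
        for s in starts:
            if flen < 3:
                continue
            transform = kabsch_superpose(P[s : s + flen], Q[s : s + flen]).transform
            prev_subset = None
            for _ in range(20):
                d = _pair_distances(P, Q, transform)
                score = tm_score(d, params)
                if score > best_score:
                    best_score = score
                    best_transform = transform
                subset = d < cutoff
                if subset.sum() < 3:
                    break
                if prev_subset is not None and np.array_equal(subset, prev_subset):
                    break
                prev_subset = subset
                transform = kabsch_superpose(P[subset], Q[subset]).transform
            # score the final transform of the refinement too
            d = _pair_distances(P, Q, transform)
            score = tm_score(d, params)
            if score > best_score:
                best_score = score
                best_transform = transform

    assert best_transform is not None
    return best_score, best_transform
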