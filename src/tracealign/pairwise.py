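"""TM-align-style pairwise structure alignment on CA traces.

The aligner follows the classic recipe: generate a small set of seed
correspondences (gapless threading, secondary-structure alignment, and a
hybrid of the two), then refine each seed by alternating TM-score-optimal
superposition with Needleman-Wunsch dynamic programming on a
distance-derived score matrix, and keep the candidate with the highest
TM-score normalized by the shorter chain. Both chain-length normalizations
are reported, along with the aligned-core RMSD and sequence identity.

Gap penalties (open -0.6, extension 0) follow the published TM-align
convention. Secondary structure is assigned from CA-only geometry with
pinned distance windows so the labels are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dp import gotoh_align
from .geometry import (
    GeometryError,
    RigidTransform,
    d0_from_length,
    kabsch_superpose,
    tm_score,
    TMScoreParams,
    tm_score_optimal,
)
from .structure_io import ProteinStructure

__all__ = [
    "AlignmentMapping",
    "PairwiseAlignment",
    "assign_secondary_structure",
    "nwdp",
    "seed_alignments",
    "refine_alignment",
    "align_pair",
]

GAP_OPEN = -0.6

# CA-geometry secondary-structure windows (angstrom): center +/- half-width
_HELIX_D2 = (5.45, 0.5)   # |CA(k-2) - CA(k)| and the two shifted copies
_HELIX_D4 = (6.1, 0.65)   # |CA(k-2) - CA(k+2)|
_STRAND_D2 = (6.1, 0.65)
_STRAND_D4 = (11.7, 1.4)


class AlignmentError(ValueError):
    """Ill-posed pairwise alignment request."""


@dataclass(frozen=True)
class AlignmentMapping:
    """Monotone residue correspondence: ordered (i, j) pairs, strictly
    increasing in both indices (sequential, no crossings)."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_i, prev_j = -1, -1
        for i, j in self.pairs:
            if i <= prev_i or j <= prev_j:
                raise AlignmentError(f"mapping not monotone at ({i}, {j})")
            prev_i, prev_j = i, j

    def __len__(self) -> int:
        return len(self.pairs)

    def as_array(self) -> np.ndarray:
        if not self.pairs:
            return np.empty((0, 2), dtype=int)
        return np.asarray(self.pairs, dtype=int)

    def swapped(self) -> "AlignmentMapping":
        return AlignmentMapping(tuple((j, i) for i, j in self.pairs))

    def validate_ranges(self, L1: int, L2: int) -> None:
        for i, j in self.pairs:
            if not (0 <= i < L1 and 0 <= j < L2):
                raise AlignmentError(f"mapping pair ({i}, {j}) out of range ({L1}, {L2})")

    @staticmethod
    def from_array(arr) -> "AlignmentMapping":
        return AlignmentMapping(tuple((int(i), int(j)) for i, j in np.asarray(arr).reshape(-1, 2)))


@dataclass(frozen=True)
class PairwiseAlignment:
    """One pairwise structure alignment result."""

    id1: str
    id2: str
    mapping: AlignmentMapping
    tm_norm1: float  # TM-score normalized by len(structure 1)
    tm_norm2: float  # TM-score normalized by len(structure 2)
    rmsd_aligned: float  # Kabsch RMSD over the mapped pairs, angstrom
    seq_identity: float  # fraction of mapped pairs with equal residue names

    @property
    def aligned_length(self) -> int:
        return len(self.mapping)


def assign_secondary_structure(s: ProteinStructure) -> str:
    """Per-residue H/E/C labels from CA-only distance geometry.

    Residue k is helical when the (k-2,k), (k-1,k+1), (k,k+2) distances sit
    in the helix window and (k-2,k+2) in its 4-residue window; strand when
    (k-2,k), (k,k+2) sit in the strand window and (k-2,k+2) in its
    4-residue window; coil otherwise. The two residues at each terminus are
    always coil.
    """
    L = len(s)
    labels = ["C"] * L
    if L < 5:
        return "".join(labels)
    X = s.coords

    def dist(a: int, b: int) -> float:
        return float(np.linalg.norm(X[a] - X[b]))

    def within(d: float, window: tuple[float, float]) -> bool:
        c, h = window
        return abs(d - c) <= h

    for k in range(2, L - 2):
        d_m2_k = dist(k - 2, k)
        d_m1_p1 = dist(k - 1, k + 1)
        d_k_p2 = dist(k, k + 2)
        d_m2_p2 = dist(k - 2, k + 2)
        if (
            within(d_m2_k, _HELIX_D2)
            and within(d_m1_p1, _HELIX_D2)
            and within(d_k_p2, _HELIX_D2)
            and within(d_m2_p2, _HELIX_D4)
        ):
            labels[k] = "H"
        elif (
            within(d_m2_k, _STRAND_D2)
            and within(d_k_p2, _STRAND_D2)
            and within(d_m2_p2, _STRAND_D4)
        ):
            labels[k] = "E"
    return "".join(labels)


def nwdp(score: np.ndarray, gap_open: float = GAP_OPEN) -> AlignmentMapping:
    """Global alignment over an n1 x n2 score matrix.

    Maximizes (sum of matched scores) + gap_open per gap opening; gap
    extension is free. Traceback ties resolve match > gap-in-second >
    gap-in-first. An empty matrix yields an empty mapping.
    """
    if gap_open > 0:
        raise AlignmentError("gap_open must be <= 0")
    _, pairs = gotoh_align(np.asarray(score, dtype=float), gap_open)
    return AlignmentMapping.from_array(pairs)


def _gapless_mappings(L1: int, L2: int, min_overlap: int = 4):
    """All diagonal-offset ungapped mappings with at least min_overlap pairs.

    Offset o pairs residue (k + o) of structure 1 with residue k of
    structure 2 (negative o shifts the other way).
    """
    for o in range(-(L2 - min_overlap), L1 - min_overlap + 1):
        i0 = max(o, 0)
        j0 = max(-o, 0)
        n = min(L1 - i0, L2 - j0)
        if n >= min_overlap:
            yield o, np.stack(
                [np.arange(i0, i0 + n), np.arange(j0, j0 + n)], axis=1
            )


def _score_mapping_kabsch(s1, s2, pairs: np.ndarray, params: TMScoreParams) -> float:
    """TM-score of a mapping under its plain Kabsch superposition (cheap)."""
    P = s1.coords[pairs[:, 0]]
    Q = s2.coords[pairs[:, 1]]
    if len(P) < 3:
        return -1.0
    sup = kabsch_superpose(P, Q)
    d = np.sqrt(((sup.transform.apply(Q) - P) ** 2).sum(axis=1))
    return tm_score(d, params)


def seed_alignments(s1: ProteinStructure, s2: ProteinStructure) -> list[AlignmentMapping]:
    """Seed correspondences for the iterative refinement.

    (a) best gapless threading: the diagonal offset whose implied ungapped
        mapping has the highest TM-score under its Kabsch superposition;
    (b) secondary-structure alignment: NWDP on a +1/equal-label matrix with
        gap open -1;
    (c) hybrid: NWDP on 0.5 * (label match) + 0.5 * (distance score under
        the gapless seed's superposition).

    Duplicates and empty mappings are dropped; order (a), (b), (c) is kept.
    """
    L1, L2 = len(s1), len(s2)
    if L1 < 5 or L2 < 5:
        raise AlignmentError("structure too short to align (need length >= 5)")
    params = TMScoreParams.from_length(min(L1, L2))

    # (a) gapless threading
    best_offset_pairs = None
    best_sc = -np.inf
    for _, pairs in _gapless_mappings(L1, L2):
        sc = _score_mapping_kabsch(s1, s2, pairs, params)
        if sc > best_sc:
            best_sc = sc
            best_offset_pairs = pairs
    assert best_offset_pairs is not None
    gapless = AlignmentMapping.from_array(best_offset_pairs)

    # (b) secondary-structure alignment
    ss1 = np.frombuffer(assign_secondary_structure(s1).encode(), dtype="S1")
    ss2 = np.frombuffer(assign_secondary_structure(s2).encode(), dtype="S1")
    ss_match = (ss1[:, None] == ss2[None, :]).astype(float)
    ss_map = nwdp(ss_match, gap_open=-1.0)

    # (c) hybrid: label match + distance score under the gapless superposition
    sup = kabsch_superpose(
        s1.coords[best_offset_pairs[:, 0]], s2.coords[best_offset_pairs[:, 1]]
    )
    moved = sup.transform.apply(s2.coords)
    diff = s1.coords[:, None, :] - moved[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    dscore = 1.0 / (1.0 + (dist / params.d0) ** 2)
    hybrid = nwdp(0.5 * ss_match + 0.5 * dscore, gap_open=GAP_OPEN)

    seeds: list[AlignmentMapping] = []
    seen = set()
    for cand in (gapless, ss_map, hybrid):
        if len(cand) == 0:
            continue
        if cand.pairs not in seen:
            seen.add(cand.pairs)
            seeds.append(cand)
    return seeds


def refine_alignment(
    s1: ProteinStructure,
    s2: ProteinStructure,
    seed: AlignmentMapping,
    max_iter: int = 30,
) -> tuple[AlignmentMapping, float, RigidTransform]:
    """Alternate TM-optimal superposition and NWDP until the mapping cycles.

    Each iteration superposes on the current mapping (TM-score search),
    rebuilds the full L1 x L2 score matrix S[i, j] = 1 / (1 + (|x1_i -
    T(x2_j)| / d0)^2) with d0 from the shorter chain, and realigns with gap
    open -0.6. Cycles are detected against the set of all visited mappings
    (the loop can 2-cycle). Returns the visited mapping with the highest
    TM-score normalized by the shorter chain, its score, and its transform.
    """
    if len(seed) == 0:
        raise AlignmentError("empty seed mapping")
    L1, L2 = len(s1), len(s2)
    seed.validate_ranges(L1, L2)
    L_min = min(L1, L2)
    d0 = d0_from_length(L_min)

    visited: dict[tuple, tuple[float, AlignmentMapping, RigidTransform]] = {}
    current = seed
    for _ in range(max_iter):
        fp = current.pairs
        if fp in visited:
            break
        score, transform = tm_score_optimal(s1.coords, s2.coords, current.as_array(), L_min)
        visited[fp] = (score, current, transform)
        moved = transform.apply(s2.coords)
        diff = s1.coords[:, None, :] - moved[None, :, :]
        S = 1.0 / (1.0 + (diff * diff).sum(axis=2) / (d0 * d0))
        nxt = nwdp(S, gap_open=GAP_OPEN)
        if len(nxt) == 0:
            break
        current = nxt

    best_fp = max(visited, key=lambda fp: visited[fp][0])
    score, mapping, transform = visited[best_fp]
    return mapping, score, transform


def align_pair(s1: ProteinStructure, s2: ProteinStructure) -> PairwiseAlignment:
    """Full pairwise alignment: refine every seed, keep the best candidate.

    The winning candidate maximizes the TM-score normalized by the shorter
    chain (ties resolve in seed order). Both normalizations are then scored
    with their own d0, the aligned-core RMSD is the Kabsch RMSD over the
    mapped pairs, and sequence identity is the fraction of mapped pairs
    with identical residue names.
    """
    best: tuple[float, AlignmentMapping] | None = None
    for seed in seed_alignments(s1, s2):
        try:
            mapping, score, _ = refine_alignment(s1, s2, seed)
        except GeometryError:
            continue
        if best is None or score > best[0]:
            best = (score, mapping)
    if best is None:
        raise AlignmentError(f"no viable alignment between {s1.id!r} and {s2.id!r}")
    mapping = best[1]
    arr = mapping.as_array()

    tm1, _ = tm_score_optimal(s1.coords, s2.coords, arr, len(s1))
    tm2, _ = tm_score_optimal(s1.coords, s2.coords, arr, len(s2))
    rmsd = kabsch_superpose(s1.coords[arr[:, 0]], s2.coords[arr[:, 1]]).rmsd
    ident = float(
        np.mean([s1.residue_names[i] == s2.residue_names[j] for i, j in mapping.pairs])
    )
    return PairwiseAlignment(
        id1=s1.id,
        id2=s2.id,
        mapping=mapping,
        tm_norm1=tm1,
        tm_norm2=tm2,
        rmsd_aligned=rmsd,
        seq_identity=ident,
    )
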