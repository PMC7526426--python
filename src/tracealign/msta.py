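"""Stage-2: progressive multiple structure alignment over the guide tree.

Profiles (partial multiple alignments) are merged from the leaves to the
root in post-order. A merge picks the cross-profile structure pair with
the smallest stage-1 distance as its anchor, initializes a rigid transform
from that pair's stored pairwise mapping, then alternates profile-column
NWDP with re-superposition on the matched core until the column mapping
cycles (at most 10 rounds). Leaf-leaf merges adopt the stored stage-1
mapping directly: stage 1 already optimized that pair with the full seed
set, so the two-structure alignment is an exact reduction to the pairwise
aligner.

Nodes at depth <= ``cutoff`` may evaluate their two subtrees concurrently;
a parent never starts before both children finish, and results are
combined in tree order, so the alignment is identical to the fully serial
traversal for every cutoff and worker count. Concurrency here trades wall
time only. The same contract holds for the final per-pair metrics.
"""

from __future__ import annotations

import concurrent.futures
import threading
from dataclasses import dataclass

import numpy as np

from ._dp import gotoh_align
from .engine import PSAResultSet
from .geometry import RigidTransform, d0_from_length, kabsch_superpose, tm_score_optimal
from .pairwise import GAP_OPEN, AlignmentMapping
from .structure_io import ProteinStructure
from .tree import GuideTree, TreeNode

__all__ = [
    "GAP",
    "MultipleAlignment",
    "MSTAMetrics",
    "profile_score_matrix",
    "merge_nodes",
    "progressive_align",
    "core_columns",
    "compute_metrics",
    "superposed_pdb",
]

GAP = -1

MERGE_MAX_ITER = 10


class MSTAError(RuntimeError):
    pass


@dataclass
class MultipleAlignment:
    """Rows = structures, columns = alignment positions.

    ``rows[r, c]`` is the residue index of structure ``structure_ids[r]``
    placed in column ``c``, or :data:`GAP`. ``structure_indices`` maps each
    row back to the global structure list.
    """

    structure_ids: tuple[str, ...]
    structure_indices: tuple[int, ...]
    rows: np.ndarray  # (n_rows, n_columns) int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.structure_ids):
            raise MSTAError("alignment table shape does not match structure ids")

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    @property
    def n_structures(self) -> int:
        return self.rows.shape[0]

    def validate(self, structures: list[ProteinStructure] | None = None) -> None:
        """Check the alignment invariants: row-internal order, completeness,
        no all-gap column."""
        for r in range(self.n_structures):
            entries = self.rows[r][self.rows[r] != GAP]
            if (np.diff(entries) <= 0).any():
                raise MSTAError(f"row {r}: residue order not increasing")
            if structures is not None:
                L = len(structures[self.structure_indices[r]])
                expect = np.arange(L)
                if entries.shape != expect.shape or (entries != expect).any():
                    raise MSTAError(f"row {r}: residues missing or duplicated")
        if self.n_columns and (self.rows == GAP).all(axis=0).any():
            raise MSTAError("all-gap column present")

    def induced_pair_mapping(self, r1: int, r2: int) -> AlignmentMapping:
        """Monotone pairwise mapping read off rows r1 and r2."""
        both = (self.rows[r1] != GAP) & (self.rows[r2] != GAP)
        return AlignmentMapping(
            tuple(zip(self.rows[r1][both].tolist(), self.rows[r2][both].tolist()))
        )


@dataclass(frozen=True)
class MSTAMetrics:
    avg_rmsd: float
    avg_tm: float
    n_columns: int
    n_core_columns: int
    n_structures: int

    def to_dict(self) -> dict:
        return {
            "avg_rmsd": self.avg_rmsd,
            "avg_tm": self.avg_tm,
            "n_columns": self.n_columns,
            "n_core_columns": self.n_core_columns,
            "n_structures": self.n_structures,
        }


@dataclass
class _Profile:
    """A partial alignment plus each member's coordinates in the profile's
    common reference frame (the frame of its first merged structure)."""

    msta: MultipleAlignment
    frame_coords: list[np.ndarray]  # per row, (L, 3) transformed coords
    frame_transforms: list[RigidTransform]  # structure frame -> profile frame


def _leaf_profile(structure: ProteinStructure, index: int) -> _Profile:
    msta = MultipleAlignment(
        structure_ids=(structure.id,),
        structure_indices=(index,),
        rows=np.arange(len(structure))[None, :],
    )
    return _Profile(
        msta=msta,
        frame_coords=[structure.coords.copy()],
        frame_transforms=[RigidTransform.identity()],
    )


def _column_coords(profile: _Profile):
    """Per row: (n_columns, 3) coords with NaN at gaps, plus the gap mask."""
    out = []
    for r in range(profile.msta.n_structures):
        row = profile.msta.rows[r]
        coords = np.full((row.size, 3), np.nan)
        nongap = row != GAP
        coords[nongap] = profile.frame_coords[r][row[nongap]]
        out.append((coords, nongap))
    return out


def profile_score_matrix(
    profA: "_Profile | MultipleAlignment",
    profB: "_Profile | MultipleAlignment",
    structures: list[ProteinStructure],
    transform: RigidTransform,
) -> np.ndarray:
    """Average cross-pair distance score between profile columns.

    Entry (p, q) averages 1 / (1 + (d / d0_pair)^2) over every structure
    pair (a in A non-gap at p, b in B non-gap at q), with d the CA distance
    after mapping B into A's frame via ``transform`` and d0_pair from the
    shorter of the two chains. Columns with no non-gap cross pair score 0.
    """
    pa = profA if isinstance(profA, _Profile) else _profile_from_msta(profA, structures)
    pb = profB if isinstance(profB, _Profile) else _profile_from_msta(profB, structures)
    colsA = pa.msta.n_columns
    colsB = pb.msta.n_columns
    total = np.zeros((colsA, colsB))
    count = np.zeros((colsA, colsB))
    ccA = _column_coords(pa)
    # B coords moved into A's frame once
    ccB = []
    for coords, mask in _column_coords(pb):
        moved = np.full_like(coords, np.nan)
        moved[mask] = transform.apply(coords[mask])
        ccB.append((moved, mask))
    for ra, (XA, mA) in enumerate(ccA):
        La = len(structures[pa.msta.structure_indices[ra]])
        for rb, (XB, mB) in enumerate(ccB):
            Lb = len(structures[pb.msta.structure_indices[rb]])
            d0 = d0_from_length(min(La, Lb))
            diff = XA[:, None, :] - XB[None, :, :]
            d2 = (diff * diff).sum(axis=2)
            score = 1.0 / (1.0 + d2 / (d0 * d0))
            valid = mA[:, None] & mB[None, :]
            total[valid] += score[valid]
            count[valid] += 1.0
    out = np.zeros_like(total)
    nz = count > 0
    out[nz] = total[nz] / count[nz]
    return out


def _profile_from_msta(msta: MultipleAlignment, structures) -> _Profile:
    coords = [structures[idx].coords.copy() for idx in msta.structure_indices]
    transforms = [RigidTransform.identity() for _ in msta.structure_indices]
    return _Profile(msta=msta, frame_coords=coords, frame_transforms=transforms)


def _stage1_distance(res) -> float:
    return 1.0 - 0.5 * (res.tm_norm1 + res.tm_norm2)


def _lookup_pair(psa: PSAResultSet, gi: int, gj: int):
    """Stored pairwise result for global indices (gi, gj); the mapping is
    returned oriented gi -> gj."""
    key = (min(gi, gj), max(gi, gj))
    if key not in psa.results:
        raise MSTAError(f"incomplete stage-1 results: missing pair {key}")
    res = psa.results[key]
    mapping = res.mapping if gi < gj else res.mapping.swapped()
    return res, mapping


def _merge_columns(rowsA: np.ndarray, rowsB: np.ndarray, colmap: np.ndarray) -> np.ndarray:
    """Combine two alignment tables along the matched-column path.

    Unmatched columns are inserted with gaps in the other profile's rows;
    within a gap region, A's columns precede B's. Row-internal residue
    order is preserved because column order within each profile is kept.
    """
    nA, cA = rowsA.shape
    nB, cB = rowsB.shape
    out_cols: list[np.ndarray] = []

    def emit_a(p):
        out_cols.append(np.concatenate([rowsA[:, p], np.full(nB, GAP, dtype=int)]))

    def emit_b(q):
        out_cols.append(np.concatenate([np.full(nA, GAP, dtype=int), rowsB[:, q]]))

    pa = pb = 0
    for p, q in colmap:
        while pa < p:
            emit_a(pa)
            pa += 1
        while pb < q:
            emit_b(pb)
            pb += 1
        out_cols.append(np.concatenate([rowsA[:, p], rowsB[:, q]]))
        pa, pb = p + 1, q + 1
    while pa < cA:
        emit_a(pa)
        pa += 1
    while pb < cB:
        emit_b(pb)
        pb += 1
    return np.stack(out_cols, axis=1)


def _merge_profiles(
    profA: _Profile,
    profB: _Profile,
    structures: list[ProteinStructure],
    psa: PSAResultSet,
) -> _Profile:
    """Merge two profiles; the result lives in A's reference frame."""
    if profA.msta.n_structures == 0 or profB.msta.n_structures == 0:
        raise MSTAError("cannot merge an empty profile")
    overlap = set(profA.msta.structure_indices) & set(profB.msta.structure_indices)
    if overlap:
        raise MSTAError(f"profiles share structures {sorted(overlap)}")

    # anchor: cross-profile pair with the smallest stage-1 distance
    best = None
    for ra, gi in enumerate(profA.msta.structure_indices):
        for rb, gj in enumerate(profB.msta.structure_indices):
            res, mapping = _lookup_pair(psa, gi, gj)
            d = _stage1_distance(res)
            key = (d, gi, gj)  # deterministic tie-break on indices
            if best is None or key < best[0]:
                best = (key, ra, rb, mapping)
    assert best is not None
    _, ra, rb, anchor_map = best
    La = len(structures[profA.msta.structure_indices[ra]])
    Lb = len(structures[profB.msta.structure_indices[rb]])

    arr = anchor_map.as_array()
    _, transform = tm_score_optimal(
        profA.frame_coords[ra], profB.frame_coords[rb], arr, min(La, Lb)
    )

    leaf_leaf = profA.msta.n_structures == 1 and profB.msta.n_structures == 1
    if leaf_leaf:
        # adopt the stage-1 mapping as the column mapping verbatim
        colmap = arr
    else:
        colmap = None
        seen: set[bytes] = set()
        for _ in range(MERGE_MAX_ITER):
            S = profile_score_matrix(profA, profB, structures, transform)
            _, candidate = gotoh_align(S, GAP_OPEN)
            fp = candidate.tobytes()
            colmap = candidate
            if fp in seen or candidate.size == 0:
                break
            seen.add(fp)
            # re-superpose on all residue pairs implied by matched columns
            P_parts, Q_parts = [], []
            for p, q in candidate:
                for r_a in range(profA.msta.n_structures):
                    ia = profA.msta.rows[r_a, p]
                    if ia == GAP:
                        continue
                    xa = profA.frame_coords[r_a][ia]
                    for r_b in range(profB.msta.n_structures):
                        ib = profB.msta.rows[r_b, q]
                        if ib == GAP:
                            continue
                        P_parts.append(xa)
                        Q_parts.append(profB.frame_coords[r_b][ib])
            if len(P_parts) < 3:
                break
            transform = kabsch_superpose(np.array(P_parts), np.array(Q_parts)).transform
        if colmap is None or colmap.size == 0:
            raise MSTAError(
                "no common core found between profiles "
                f"{profA.msta.structure_ids} and {profB.msta.structure_ids}"
            )

    rows = _merge_columns(profA.msta.rows, profB.msta.rows, colmap)
    msta = MultipleAlignment(
        structure_ids=profA.msta.structure_ids + profB.msta.structure_ids,
        structure_indices=profA.msta.structure_indices + profB.msta.structure_indices,
        rows=rows,
    )
    frame_coords = [c.copy() for c in profA.frame_coords]
    frame_transforms = list(profA.frame_transforms)
    for rb2 in range(profB.msta.n_structures):
        frame_coords.append(transform.apply(profB.frame_coords[rb2]))
        frame_transforms.append(transform.compose(profB.frame_transforms[rb2]))
    return _Profile(msta=msta, frame_coords=frame_coords, frame_transforms=frame_transforms)


def merge_nodes(
    profA: MultipleAlignment,
    profB: MultipleAlignment,
    structures: list[ProteinStructure],
    psa: PSAResultSet,
) -> MultipleAlignment:
    """Merge two partial alignments (public surface over profile merging)."""
    pa = _profile_from_msta(profA, structures)
    pb = _profile_from_msta(profB, structures)
    return _merge_profiles(pa, pb, structures, psa).msta


def progressive_align(
    tree: GuideTree,
    structures: list[ProteinStructure],
    psa: PSAResultSet,
    cutoff: int = 0,
    workers: int = 1,
) -> MultipleAlignment:
    """Post-order progressive merge over the guide tree.

    Leaves yield single-row profiles; each internal node merges its
    children. With ``cutoff`` > 0 and ``workers`` > 1, subtrees rooted at
    depth <= cutoff evaluate concurrently (the parent always waits for both
    children); deeper subtrees run serially. The result is identical to
    the fully serial traversal for every (cutoff, workers) setting.
    """
    if tree.n_leaves != len(structures):
        raise MSTAError("tree leaves do not match structure count")
    psa.require_complete()
    if psa.n_structures != len(structures):
        raise MSTAError("stage-1 results do not match structure count")

    parallel = cutoff > 0 and workers > 1
    gate = threading.BoundedSemaphore(max(workers, 1)) if parallel else None

    def evaluate(node: TreeNode, depth: int) -> _Profile:
        if node.is_leaf:
            return _leaf_profile(structures[node.index], node.index)
        if parallel and depth <= cutoff:
            with concurrent.futures.ThreadPoolExecutor(max_workers=2) as pool:
                fa = pool.submit(evaluate, node.left, depth + 1)
                fb = pool.submit(evaluate, node.right, depth + 1)
                pa, pb = fa.result(), fb.result()  # parent waits for both children
        else:
            pa = evaluate(node.left, depth + 1)
            pb = evaluate(node.right, depth + 1)
        if gate is not None:
            with gate:
                return _merge_profiles(pa, pb, structures, psa)
        return _merge_profiles(pa, pb, structures, psa)

    profile = evaluate(tree.root, 0)
    profile.msta.validate(structures)
    return profile.msta


def core_columns(msta: MultipleAlignment) -> list[int]:
    """Columns with no gap in any row (the common structural core)."""
    if msta.n_columns == 0:
        return []
    mask = (msta.rows != GAP).all(axis=0)
    return np.nonzero(mask)[0].tolist()


def _pair_metrics(args):
    (r1, r2), msta, structures, core = args
    idx1 = msta.structure_indices[r1]
    idx2 = msta.structure_indices[r2]
    s1, s2 = structures[idx1], structures[idx2]
    pairs = np.stack([msta.rows[r1][core], msta.rows[r2][core]], axis=1)
    rmsd = kabsch_superpose(s1.coords[pairs[:, 0]], s2.coords[pairs[:, 1]]).rmsd
    tm, _ = tm_score_optimal(s1.coords, s2.coords, pairs, min(len(s1), len(s2)))
    return rmsd, tm

def compute_metrics(
    msta: MultipleAlignment,
    structures: list[ProteinStructure],
    workers: int = 1,
) -> MSTAMetrics:
    """Average pairwise RMSD and TM-score over the alignment's core.

    Every unordered pair of members is superposed on the core-column
    residue pairs (Kabsch) for its RMSD; its TM-score is the optimal score
    of the core correspondence normalized by the shorter chain. Averages
    run over pairs in canonical order, so the values are independent of
    worker count and completion order.
    """
    if msta.n_structures < 2:
        raise MSTAError("metrics need at least 2 structures")
    core = core_columns(msta)
    if len(core) < 3:
        raise MSTAError("core too small for superposition (need >= 3 core columns)")
    pairs = [
        (r1, r2)
        for r1 in range(msta.n_structures)
        for r2 in range(r1 + 1, msta.n_structures)
    ]
    tasks = [((r1, r2), msta, structures, core) for r1, r2 in pairs]
    if workers <= 1:
        outcomes = [_pair_metrics(t) for t in tasks]
    else:
        with concurrent.futures.ThreadPoolExecutor(max_workers=workers) as pool:
            outcomes = list(pool.map(_pair_metrics, tasks))  # canonical order kept
    rmsds = np.array([o[0] for o in outcomes])
    tms = np.array([o[1] for o in outcomes])
    return MSTAMetrics(
        avg_rmsd=float(rmsds.mean()),
        avg_tm=float(tms.mean()),
        n_columns=msta.n_columns,
        n_core_columns=len(core),
        n_structures=msta.n_structures,
    )


def superposed_pdb(msta: MultipleAlignment, structures: list[ProteinStructure]) -> str:
    """All members rigidly superposed into the first member's frame, as a
    multi-model PDB (core-column Kabsch against row 0)."""
    from .structure_io import write_pdb

    core = core_columns(msta)
    if len(core) < 3:
        raise MSTAError("core too small for superposition (need >= 3 core columns)")
    blocks = []
    ref_idx = msta.structure_indices[0]
    ref = structures[ref_idx]
    for r in range(msta.n_structures):
        s = structures[msta.structure_indices[r]]
        if r == 0:
            moved = s.coords
        else:
            pairs = np.stack([msta.rows[0][core], msta.rows[r][core]], axis=1)
            sup = kabsch_superpose(ref.coords[pairs[:, 0]], s.coords[pairs[:, 1]])
            moved = sup.transform.apply(s.coords)
        clone = ProteinStructure(
            id=s.id,
            residue_names=list(s.residue_names),
            residue_numbers=list(s.residue_numbers),
            coords=moved,
        )
        body = write_pdb(clone).replace("END\n", "")
        blocks.append(f"MODEL     {r + 1:>4}\n{body}ENDMDL")
    return "\n".join(blocks) + "\nEND\n"
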