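"""Stage-1 engine: all-to-all / one-to-all pairwise alignment with a
determinism contract.

The workload is the set of unordered structure pairs in lexicographic
order. It is split into ordered, contiguous partitions which may be fused
("coalesced") to a smaller count and executed by worker processes.
Parallelism settings (workers, partitions, coalesce target) affect wall
time only, never values: every pair is aligned exactly once by a pure
function of the two structures, and results are re-sorted into enumeration
order before any serialization. A failing pair aborts the whole run —
a missing pair would silently invalidate the distance matrix downstream.
"""

from __future__ import annotations

import concurrent.futures
import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .pairwise import AlignmentMapping, PairwiseAlignment, align_pair
from .structure_io import ProteinStructure

__all__ = [
    "WorkPartition",
    "PSAResultSet",
    "DistanceMatrix",
    "enumerate_pairs",
    "partition_work",
    "coalesce",
    "run_all_to_all",
    "run_one_to_all",
    "to_distance_matrix",
    "write_results_tsv",
    "read_results_tsv",
    "write_distance_tsv",
]

logger = logging.getLogger(__name__)


class EngineError(RuntimeError):
    pass


class PairAlignmentError(EngineError):
    """A single pair failed; carries the pair identity (fail-fast policy)."""

    def __init__(self, pair: tuple[int, int], cause: Exception):
        super().__init__(f"alignment failed for pair {pair}: {cause}")
        self.pair = pair


@dataclass(frozen=True)
class WorkPartition:
    index: int
    items: tuple[tuple[int, int], ...]


@dataclass
class PSAResultSet:
    """All pairwise results of a run, keyed by unordered pair (i, j), i < j."""

    results: dict[tuple[int, int], PairwiseAlignment]
    n_structures: int

    def require_complete(self) -> None:
        for pair in enumerate_pairs(self.n_structures):
            if pair not in self.results:
                raise EngineError(f"incomplete result set: missing pair {pair}")


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarities in [0, 1]."""

    n: int
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (self.n, self.n):
            raise EngineError(f"distance matrix shape {self.d.shape} != ({self.n}, {self.n})")
        if not np.isfinite(self.d).all():
            raise EngineError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise EngineError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise EngineError("distance matrix diagonal not zero")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise EngineError("distances must lie in [0, 1]")


def enumerate_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered index pairs (i, j), i < j, in lexicographic order.

    The n(n-1)/2 pairs are what remains of the n x n cartesian product
    after dropping self-pairs and one of each duplicate orientation.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def partition_work(items, k: int) -> list[WorkPartition]:
    """Split an ordered item list into min(k, len) contiguous chunks.

    Chunk sizes differ by at most one, larger chunks first; concatenating
    the chunks in index order restores the input.
    """
    if k < 1:
        raise ValueError("partition count must be >= 1")
    items = list(items)
    k_eff = min(k, len(items))
    if k_eff == 0:
        return []
    base, rem = divmod(len(items), k_eff)
    parts = []
    pos = 0
    for idx in range(k_eff):
        size = base + (1 if idx < rem else 0)
        parts.append(WorkPartition(index=idx, items=tuple(items[pos : pos + size])))
        pos += size
    return parts


def coalesce(partitions: list[WorkPartition], m: int) -> list[WorkPartition]:
    """Fuse adjacent partitions down to ``m`` with near-equal item counts.

    Item order is preserved globally. Asking for more partitions than exist
    is a warning no-op (coalescing never expands).
    """
    if m < 1:
        raise ValueError("target partition count must be >= 1")
    if m > len(partitions):
        warnings.warn(
            f"coalesce target {m} exceeds partition count {len(partitions)}; keeping as-is",
            stacklevel=2,
        )
        return list(partitions)
    counts = np.array([len(p.items) for p in partitions])
    total = int(counts.sum())
    cum = np.cumsum(counts)
    # group boundaries at the partitions whose cumulative count first
    # reaches each fraction g/m of the total
    boundaries = []
    prev = 0
    for g in range(1, m):
        target = total * g / m
        b = int(np.searchsorted(cum, target, side="left")) + 1
        b = max(b, prev + 1)
        b = min(b, len(partitions) - (m - g))
        boundaries.append(b)
        prev = b
    edges = [0] + boundaries + [len(partitions)]
    fused = []
    for idx in range(m):
        chunk = partitions[edges[idx] : edges[idx + 1]]
        items = tuple(it for p in chunk for it in p.items)
        fused.append(WorkPartition(index=idx, items=items))
    return fused


def _align_partition(args) -> list[tuple[tuple[int, int], PairwiseAlignment]]:
    items, structures_by_index = args
    out = []
    for pair in items:
        i, j = pair
        try:
            out.append((pair, align_pair(structures_by_index[i], structures_by_index[j])))
        except Exception as exc:  # fail-fast with the pair identity
            raise PairAlignmentError(pair, exc) from exc
    return out


def _execute(partitions: list[WorkPartition], structures, workers: int):
    """Run partitions on ``workers`` processes; order of collection is
    irrelevant because results are keyed by pair and re-sorted later."""
    tasks = []
    for part in partitions:
        needed = {idx for pair in part.items for idx in pair}
        tasks.append((part.items, {idx: structures[idx] for idx in needed}))
    results: list[tuple[tuple[int, int], PairwiseAlignment]] = []
    if workers <= 1 or len(partitions) <= 1:
        for task in tasks:
            results.extend(_align_partition(task))
    else:
        with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
            for chunk in pool.map(_align_partition, tasks):
                results.extend(chunk)
    return results


def run_all_to_all(
    structures: list[ProteinStructure],
    workers: int = 1,
    partitions: int | None = None,
    coalesce_to: int | None = None,
) -> PSAResultSet:
    """Align every unordered pair of ``structures`` exactly once.

    The serialized result set is identical for every (workers, partitions,
    coalesce_to) combination; those knobs trade wall time only.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    n = len(structures)
    pairs = enumerate_pairs(n)
    parts = partition_work(pairs, partitions if partitions is not None else max(workers, 1))
    if coalesce_to is not None and parts:
        parts = coalesce(parts, coalesce_to)

    t0 = time.perf_counter()
    raw = _execute(parts, structures, workers)
    elapsed = time.perf_counter() - t0
    logger.info(
        "all-to-all PSA: %d structures, %d pairs, %d partitions, %d workers, %.3f s total, %.4f s/pair",
        n, len(pairs), len(parts), workers, elapsed, elapsed / max(len(pairs), 1),
    )
    results = dict(sorted(raw, key=lambda kv: kv[0]))
    rs = PSAResultSet(results=results, n_structures=n)
    rs.require_complete()
    return rs


def run_one_to_all(
    query: ProteinStructure,
    db: list[ProteinStructure],
    workers: int = 1,
    partitions: int | None = None,
) -> list[PairwiseAlignment]:
    """Align one query against every database entry, db order preserved."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    items = [(0, 1 + k) for k in range(len(db))]
    parts = partition_work(items, partitions if partitions is not None else max(workers, 1))
    structures = [query] + list(db)
    t0 = time.perf_counter()
    raw = _execute(parts, structures, workers)
    elapsed = time.perf_counter() - t0
    logger.info(
        "one-to-all PSA: %d db entries, %d workers, %.3f s total",
        len(db), workers, elapsed,
    )
    by_pair = dict(raw)
    return [by_pair[(0, 1 + k)] for k in range(len(db))]


def to_distance_matrix(resultset: PSAResultSet) -> DistanceMatrix:
    """Dissimilarity d[i, j] = 1 - (tm_norm1 + tm_norm2) / 2, zero diagonal."""
    n = resultset.n_structures
    resultset.require_complete()
    d = np.zeros((n, n))
    for (i, j), res in resultset.results.items():
        v = 1.0 - 0.5 * (res.tm_norm1 + res.tm_norm2)
        v = min(max(v, 0.0), 1.0)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(n=n, d=d)


_TSV_COLUMNS = [
    "id1", "id2", "aligned_length", "rmsd_aligned",
    "tm_norm1", "tm_norm2", "seq_identity", "mapping",
]


def _mapping_to_str(mapping: AlignmentMapping) -> str:
    return ",".join(f"{i}:{j}" for i, j in mapping.pairs)


def _mapping_from_str(text: str) -> AlignmentMapping:
    if not text:
        return AlignmentMapping(())
    pairs = []
    for token in text.split(","):
        i, j = token.split(":")
        pairs.append((int(i), int(j)))
    return AlignmentMapping(tuple(pairs))


def write_results_tsv(resultset: PSAResultSet) -> str:
    """Serialize a result set as TSV, rows in pair-enumeration order.

    Floats are written with round-trip precision so the serialization is
    lossless and byte-stable.
    """
    lines = ["\t".join(_TSV_COLUMNS)]
    for pair in sorted(resultset.results):
        r = resultset.results[pair]
        lines.append(
            "\t".join([
                r.id1, r.id2, str(r.aligned_length), repr(r.rmsd_aligned),
                repr(r.tm_norm1), repr(r.tm_norm2), repr(r.seq_identity),
                _mapping_to_str(r.mapping),
            ])
        )
    return "\n".join(lines) + "\n"


def read_results_tsv(text: str) -> PSAResultSet:
    """Parse a pairwise-results TSV back into a PSAResultSet.

    Structure indices are recovered from the order of first appearance of
    the ids, which for a file written in enumeration order reproduces the
    original indexing.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != _TSV_COLUMNS:
        raise EngineError("results TSV: missing or malformed header")
    index_of: dict[str, int] = {}
    results: dict[tuple[int, int], PairwiseAlignment] = {}
    for rowno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(_TSV_COLUMNS):
            raise EngineError(f"results TSV: malformed row {rowno}")
        try:
            r = PairwiseAlignment(
                id1=parts[0], id2=parts[1],
                mapping=_mapping_from_str(parts[7]),
                tm_norm1=float(parts[4]), tm_norm2=float(parts[5]),
                rmsd_aligned=float(parts[3]), seq_identity=float(parts[6]),
            )
            if r.aligned_length != int(parts[2]):
                raise ValueError("aligned_length disagrees with mapping")
        except (ValueError, IndexError) as exc:
            raise EngineError(f"results TSV: parse error at row {rowno}: {exc}") from exc
        for sid in (r.id1, r.id2):
            if sid not in index_of:
                index_of[sid] = len(index_of)
        i, j = index_of[r.id1], index_of[r.id2]
        key = (min(i, j), max(i, j))
        if key in results:
            raise EngineError(f"results TSV: duplicate pair at row {rowno}")
        results[key] = r
    return PSAResultSet(results=results, n_structures=len(index_of))


def write_distance_tsv(matrix: DistanceMatrix, ids: list[str]) -> str:
    """Distance matrix as TSV with an id header row and id row labels."""
    if len(ids) != matrix.n:
        raise EngineError("id count does not match matrix size")
    lines = ["\t".join(["id"] + list(ids))]
    for i, sid in enumerate(ids):
        lines.append("\t".join([sid] + [repr(float(v)) for v in matrix.d[i]]))
    return "\n".join(lines) + "\n"
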