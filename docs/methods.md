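# Methods

This note records the models, algorithms, numerical choices, and known
limitations behind `tracealign`, at the level of detail a maintainer or a
careful user needs.

## Problem setting

Given N protein chains represented by their CA traces, the pipeline
produces (1) all N(N−1)/2 pairwise structure alignments and a derived
distance matrix, (2) a UPGMA guide tree, and (3) a progressive multiple
structure alignment (MSTA) with core-based quality metrics. Residue
correspondences are sequential (monotone, no crossings); non-sequential
alignment is out of scope.

## Pairwise alignment

### TM-score

For aligned pair distances d_i under normalization length L:
TM = (1/L) Σ 1/(1 + (d_i/d0(L))²) with
d0(L) = max(1.24·(L−15)^⅓ − 1.8, 0.5) Å. The 0.5 Å floor keeps the score
defined for short chains. The score is in (0, 1]; it is invariant under a
common rigid motion of both structures and anti-monotone in each d_i.

### TM-score-optimal superposition

The superposition maximizing the TM-score of a fixed mapping has no
closed form. We seed Kabsch superpositions on contiguous runs of the
mapped pairs at fragment lengths {m, m/2, m/4} (floor 4, m = mapped
pairs), sliding each fragment at half-length steps, and refine each seed
by re-superposing on the subset of mapped pairs with distance below
max(d0, 4.5 Å) until the subset stabilizes, at most 20 iterations,
tracking the best score seen. The full-length fragment is always among
the seeds, so the result never falls below the single whole-set Kabsch
superposition score. The fragment schedule, inclusion cutoff, and
iteration cap are pinned constants chosen in the spirit of the standard
TM-score search; they are not fitted to any dataset.

### Seeds, refinement, selection

Three seeds: (a) the gapless diagonal threading whose implied mapping
scores best under its own Kabsch superposition (offsets with at least 4
overlapping residues); (b) NWDP over a +1/equal secondary-structure-label
matrix, gap open −1; (c) NWDP over 0.5·(label match) + 0.5·(distance
score under the gapless seed's superposition), gap open −0.6. Refinement
alternates TM-optimal superposition with NWDP (gap open −0.6, free
extension) on S[i,j] = 1/(1 + (‖x1_i − T(x2_j)‖/d0(L_min))²), stopping
when a mapping repeats (a fingerprint set catches 2-cycles, which the
DP/superposition loop does produce) or after 30 iterations, and returns
the *visited* mapping with the best TM-score normalized by the shorter
chain — not necessarily the last one. The final result reports both
normalizations (each scored with its own d0 by a separate optimal-
superposition run), the Kabsch RMSD over the mapped pairs, and sequence
identity over mapped pairs.

Secondary structure is assigned from CA geometry alone with pinned
windows: helix when the (k−2,k), (k−1,k+1), (k,k+2) distances lie in
5.45 ± 0.5 Å and (k−2,k+2) in 6.1 ± 0.65 Å; strand when (k−2,k), (k,k+2)
lie in 6.1 ± 0.65 Å and (k−2,k+2) in 11.7 ± 1.4 Å; coil otherwise, and
always at the two terminal residues on each end. These windows reproduce
ideal helix geometry (verified against the closed-form helix with 2.3 Å
radius, 1.5 Å rise, 100°/residue) and reject extended traces.

### NWDP gap model

Global alignment with an opening cost (−0.6 by convention, −1 for the
secondary-structure seed) and free extension, implemented as a
three-state Gotoh recursion. Traceback ties resolve deterministically:
match > gap-in-second-sequence > gap-in-first-sequence, applied uniformly
to state selection and predecessors. The kernel is numba-compiled with a
pure-Python fallback of identical semantics.

## Stage-1 engine and the determinism contract

Pairs are enumerated lexicographically; `partition_work` makes contiguous
chunks differing by at most one item (larger first); `coalesce` fuses
adjacent partitions toward equal item counts and refuses to expand.
Partitions execute on worker processes; since each pair's result is a
pure function of its two structures, and collected results are re-sorted
into enumeration order before serialization, the serialized output is
identical for every (workers, partitions, coalesce) setting. Failures are
fail-fast with the offending pair named: a silently missing pair would
corrupt the distance matrix. Defaults: partitions = workers = available
cores. The distance is d = 1 − (TM_norm1 + TM_norm2)/2 — symmetric by
construction; the exact TM-to-distance transform is a design choice
isolated behind `to_distance_matrix`.

## Guide tree

Classic UPGMA: merge the cluster pair at minimal average-linkage
distance; new node height = merge distance / 2; distance update
d(A∪B, C) = (|A|·d(A,C) + |B|·d(B,C))/(|A|+|B|). Ties break on the
lexicographically smallest (min index, max index) pair of cluster node
indices — a pinned rule so the merge order is reproducible. Nodes live in
a binary tree with leaves 0..N−1 and internal nodes N..2N−2 assigned in
merge order (leaf-ness is readable from the index); the smaller-index
cluster becomes the left child. The tree is ultrametric; Newick branch
lengths are parent height − child height, hence non-negative. The
best-case speedup of task-parallel post-order traversal on a fully
balanced tree of n nodes is (n−1)/(2h), h = log₂(n+1) − 1 — exposed as a
utility and restricted to n+1 a power of two, where the formula is
defined.

## Progressive merge

Each profile carries its members' coordinates in a common reference frame
(the frame of its first structure). Merging profiles A and B:

1. anchor = the cross-profile structure pair (a, b) with the smallest
   stage-1 distance (ties on structure indices); the initial transform is
   the TM-optimal superposition of the stored stage-1 mapping between
   a's and b's frame coordinates.
2. Column scoring: entry (p, q) is the mean over all non-gap cross pairs
   of 1/(1 + (d/d0_pair)²), d0_pair from the shorter of the two chains;
   gaps contribute nothing, and an empty cross set scores 0.
3. NWDP (gap open −0.6) on the column score matrix; matched columns
   merge, unmatched columns gain gaps in the other profile's rows (within
   a gap region A's columns precede B's). The matched core re-superposes
   B onto A, and steps 2–3 repeat until the column mapping repeats or 10
   iterations.

**Leaf–leaf merges adopt the stage-1 mapping verbatim** instead of
re-iterating: the pairwise stage already optimized that pair with the
full seed set and a larger iteration budget, so re-deriving the mapping
from a single anchor could only degrade it. A corollary is that the
MSTA of exactly two structures *is* the pairwise alignment — mapping and
metrics reduce exactly.

Traversal is post-order; a parent never starts before both children
finish. Nodes at depth ≤ `cutoff` may evaluate their two subtrees
concurrently (bounded thread pool; `cutoff = 0` disables task traversal
entirely), but profiles combine in tree order, so the result
is identical to the serial traversal for every cutoff and worker count.
The default is `cutoff = 0` (serial traversal): most of the tree's work
sits near the root where no parallelism is available, so task-parallel
traversal rarely pays for its overhead, while the pair-level parallelism
of stage 1 and of the metrics step scales well.

If the column NWDP finds no matched columns (structures too divergent to
share a core), the merge raises a "no common core" error rather than
emitting a degenerate alignment; `compute_metrics` likewise requires at
least 3 core columns.

## Metrics

For every unordered member pair: RMSD = Kabsch superposition on the
core-column residue pairs; TM-score = the optimal-superposition score of
those pairs normalized by the shorter chain (consistent with the pairwise
stage, so the 2-structure reduction is exact). Averages run over the
canonical pair order regardless of worker count; parallel and serial
metrics are bit-identical.

## Synthetic data

`make_backbone` draws a self-avoiding walk with exact 3.8 Å CA steps,
pseudo-bond angles uniform in [80°, 150°], and a 3.5 Å non-adjacent
clash floor (per-step resampling, whole-chain restarts). `perturb`
applies a uniform random rotation (normalized Gaussian quaternion), a
uniform translation in [−20, 20] Å per axis, isotropic Gaussian
coordinate noise, then single-residue indels (insertions at the neighbor
midpoint, unmapped to the ancestor). `make_family` derives member
sub-seeds from the family seed through numpy's PCG64 generator, so
families are pure functions of their parameters on any platform.
Residue names are uniform over the 20 standard amino acids so sequence
identity is exercised.

What this emulates — and does not. The generator reproduces the
*geometry* of a structure family: a shared fold with rigid-motion
ambiguity, coordinate noise, and small indels, with exact ground truth.
It does not emulate real protein features: secondary-structure content,
domain motions, compactness, realistic indel length distributions, or
sequence–structure correlation. Passing tests therefore demonstrate
algorithmic correctness (mapping recovery, invariances, determinism),
not benchmark-level alignment accuracy on real folds.

Default test conditions: noisy families use σ = 0.3–0.5 Å (well inside a
fold's conserved-core variation) at lengths 40–80 and sizes 4–12; the
end-to-end recovery check uses n = 8, L = 80, σ = 0.3 Å, no indels. The
determinism check uses a 12-member, L = 50 family — large enough to give
the partitioner real work at 64 partitions, small enough that the full
suite stays interactive.

## Numerical choices and degenerate inputs

- Kabsch via SVD with the determinant sign correction on the smallest
  singular direction; collinear point sets are solved (SVD handles the
  rank deficiency) and flagged. Fewer than 3 points is an error.
- Distances/scores in float64 throughout; TSV serialization uses Python
  `repr` round-trip formatting, making files byte-stable and lossless.
- Mapping fingerprints are the tuples of (i, j) pairs; cycle detection is
  by set membership, not last-value comparison.
- PDB parsing is fixed-column (v3.3): first MODEL, altloc blank/'A',
  first chain unless specified, first CA per residue, ATOM records only
  (HETATM — including MSE — ignored). Consecutive CA distances outside
  (1, 10) Å flag the structure with a warning but do not reject it.
- Chains shorter than 5 residues refuse to align; families that would
  drop below 5 residues refuse to generate.

## Limitations

- Sequential alignments only; circular permutations and non-sequential
  cores are invisible.
- The profile column score and core definition are reasonable standard
  choices, isolated behind `profile_score_matrix` / `core_columns`, but
  other MSTA tools use different conventions; metric values are
  comparable within this package, not across tools.
- No iterative refinement after the progressive pass; alignment quality
  is bounded by the guide tree's merge order.
- UPGMA assumes a roughly constant divergence rate across the family; a
  strongly non-clock-like family can yield a suboptimal merge order.
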