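import numpy as np
import pytest

import tracealign as ta
from tracealign.geometry import RigidTransform, d0_from_length, kabsch_superpose, tm_score_optimal
from tracealign.msta import (
    GAP,
    MSTAError,
    MultipleAlignment,
    _leaf_profile,
    _profile_from_msta,
    compute_metrics,
    core_columns,
    merge_nodes,
    profile_score_matrix,
    progressive_align,
)


def _pipeline(members, cutoff=0, workers=1):
    rs = ta.run_all_to_all(members)
    tree = ta.upgma(ta.to_distance_matrix(rs))
    m = progressive_align(tree, members, rs, cutoff=cutoff, workers=workers)
    return rs, tree, m


class TestProfileScoreMatrix:
    def test_single_structure_diagonal_is_one(self, backbone40):
        pa = _leaf_profile(backbone40, 0)
        pb = _leaf_profile(backbone40, 1)
        S = profile_score_matrix(pa, pb, [backbone40, backbone40], RigidTransform.identity())
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)

    def test_all_gap_column_scores_zero(self, family_rigid):
        members = family_rigid.members[:2]
        rows = np.array([[0, 1, 2, GAP], [GAP, GAP, GAP, 0]])
        prof = MultipleAlignment(
            structure_ids=(members[0].id,), structure_indices=(0,), rows=rows[:1]
        )
        # column 3 of this profile is all-gap for its single row
        pa = _profile_from_msta(prof, members)
        pb = _leaf_profile(members[1], 1)
        S = profile_score_matrix(pa, pb, members, RigidTransform.identity())
        assert (S[3, :] == 0.0).all()

    def test_matches_double_loop_recomputation(self, family_small):
        """Vectorized profile scoring equals a naive per-entry double loop."""
        members = family_small.members[:4]
        rs = ta.run_all_to_all(members)
        tree = ta.upgma(ta.to_distance_matrix(rs))
        # build two 2-member profiles by merging leaf pairs
        from tracealign.msta import _merge_profiles, _leaf_profile as leaf

        pa = _merge_profiles(leaf(members[0], 0), leaf(members[1], 1), members, rs)
        pb = _merge_profiles(leaf(members[2], 2), leaf(members[3], 3), members, rs)
        T = RigidTransform.identity()
        S = profile_score_matrix(pa, pb, members, T)

        for p in range(0, pa.msta.n_columns, 7):
            for q in range(0, pb.msta.n_columns, 7):
                total, count = 0.0, 0
                for ra in range(2):
                    ia = pa.msta.rows[ra, p]
                    if ia == GAP:
                        continue
                    for rb in range(2):
                        ib = pb.msta.rows[rb, q]
                        if ib == GAP:
                            continue
                        La = len(members[pa.msta.structure_indices[ra]])
                        Lb = len(members[pb.msta.structure_indices[rb]])
                        d0 = d0_from_length(min(La, Lb))
                        d2 = ((pa.frame_coords[ra][ia] - pb.frame_coords[rb][ib]) ** 2).sum()
                        total += 1.0 / (1.0 + d2 / d0**2)
                        count += 1
                expected = total / count if count else 0.0
                assert S[p, q] == pytest.approx(expected, rel=1e-12)


class TestMergeNodes:
    def test_merging_identical_copies_is_ungapped(self, family_rigid):
        members = family_rigid.members[:2]
        rs = ta.run_all_to_all(members)
        a = _leaf_profile(members[0], 0).msta
        b = _leaf_profile(members[1], 1).msta
        merged = merge_nodes(a, b, members, rs)
        assert merged.n_columns == len(members[0])
        assert (merged.rows != GAP).all()

    def test_merge_requires_disjoint_structures(self, family_rigid):
        members = family_rigid.members[:2]
        rs = ta.run_all_to_all(members)
        a = _leaf_profile(members[0], 0).msta
        with pytest.raises(MSTAError, match="share"):
            merge_nodes(a, a, members, rs)

    def test_invariants_after_merging_noisy_profiles(self, family_small):
        members = family_small.members
        rs, tree, m = _pipeline(members)
        m.validate(members)  # order, completeness, no all-gap column
        # restriction to any two rows induces a monotone mapping
        for r1 in range(m.n_structures):
            for r2 in range(r1 + 1, m.n_structures):
                m.induced_pair_mapping(r1, r2)  # constructor checks monotone


class TestProgressiveAlign:
    def test_two_structures_reduce_to_pairwise(self, family_small):
        members = family_small.members[:2]
        rs, tree, m = _pipeline(members)
        pair = rs.results[(0, 1)]
        assert m.induced_pair_mapping(0, 1).pairs == pair.mapping.pairs

    def test_identical_structures_align_fully_any_cutoff(self, family_rigid):
        members = family_rigid.members[:3]
        rs = ta.run_all_to_all(members)
        tree = ta.upgma(ta.to_distance_matrix(rs))
        outputs = set()
        for cutoff, workers in [(0, 1), (1, 2), (5, 4)]:
            m = progressive_align(tree, members, rs, cutoff=cutoff, workers=workers)
            assert (m.rows != GAP).all()
            outputs.add(m.rows.tobytes())
        assert len(outputs) == 1

    def test_serial_parallel_identity_on_family(self, family_small):
        members = family_small.members
        rs = ta.run_all_to_all(members)
        tree = ta.upgma(ta.to_distance_matrix(rs))
        serial = progressive_align(tree, members, rs, cutoff=0, workers=1)
        parallel = progressive_align(tree, members, rs, cutoff=3, workers=4)
        assert serial.rows.tobytes() == parallel.rows.tobytes()
        assert serial.structure_ids == parallel.structure_ids

    def test_incomplete_psa_rejected(self, family_small):
        members = family_small.members
        rs = ta.run_all_to_all(members)
        del rs.results[(0, 1)]
        tree_rs = ta.run_all_to_all(members)
        tree = ta.upgma(ta.to_distance_matrix(tree_rs))
        with pytest.raises(Exception, match="missing pair"):
            progressive_align(tree, members, rs)


class TestCoreColumns:
    def test_ungapped_alignment_is_all_core(self, family_rigid):
        members = family_rigid.members[:3]
        _, _, m = _pipeline(members)
        assert core_columns(m) == list(range(m.n_columns))

    def test_gapped_column_excluded(self):
        rows = np.array([[0, 1, 2], [0, GAP, 1]])
        m = MultipleAlignment(("a", "b"), (0, 1), rows)
        assert core_columns(m) == [0, 2]

    def test_count_bounded_by_columns(self, family_small):
        _, _, m = _pipeline(family_small.members)
        assert len(core_columns(m)) <= m.n_columns


class TestMetrics:
    def test_identical_copies_perfect_scores(self, family_rigid):
        members = family_rigid.members
        _, _, m = _pipeline(members)
        metrics = compute_metrics(m, members)
        assert metrics.avg_rmsd <= 1e-6
        assert metrics.avg_tm == pytest.approx(1.0, abs=1e-9)
        assert metrics.n_core_columns == len(members[0])

    def test_two_structure_metrics_equal_pairwise(self, family_small):
        members = family_small.members[:2]
        rs, _, m = _pipeline(members)
        metrics = compute_metrics(m, members)
        pair = rs.results[(0, 1)]
        assert metrics.avg_rmsd == pytest.approx(pair.rmsd_aligned, abs=1e-12)
        expected_tm = max(pair.tm_norm1, pair.tm_norm2)  # shorter-chain normalization
        assert metrics.avg_tm == pytest.approx(expected_tm, abs=1e-12)

    def test_parallel_equals_serial_bitwise(self, family_small):
        members = family_small.members
        _, _, m = _pipeline(members)
        m1 = compute_metrics(m, members, workers=1)
        m4 = compute_metrics(m, members, workers=4)
        assert m1 == m4

    def test_matches_brute_force_recomputation(self, family_small):
        """avg_rmsd / avg_tm equal an independent double loop over pairs."""
        members = family_small.members
        _, _, m = _pipeline(members)
        metrics = compute_metrics(m, members)
        core = core_columns(m)
        rmsds, tms = [], []
        for r1 in range(m.n_structures):
            for r2 in range(r1 + 1, m.n_structures):
                s1 = members[m.structure_indices[r1]]
                s2 = members[m.structure_indices[r2]]
                pairs = np.stack([m.rows[r1][core], m.rows[r2][core]], axis=1)
                rmsds.append(kabsch_superpose(s1.coords[pairs[:, 0]],
                                              s2.coords[pairs[:, 1]]).rmsd)
                tms.append(tm_score_optimal(s1.coords, s2.coords, pairs,
                                            min(len(s1), len(s2)))[0])
        assert metrics.avg_rmsd == pytest.approx(float(np.mean(rmsds)), abs=1e-12)
        assert metrics.avg_tm == pytest.approx(float(np.mean(tms)), abs=1e-12)

    def test_core_too_small_raises(self):
        rows = np.array([[0, 1, GAP], [GAP, 0, 1]])
        m = MultipleAlignment(("a", "b"), (0, 1), rows)
        with pytest.raises(MSTAError, match="core too small"):
            compute_metrics(m, [None, None])
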