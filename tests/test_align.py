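"""Global alignment against an enumeration oracle; progressive MSA contracts."""
import numpy as np
import pytest

import fam111kit as fk
from fam111kit.align import AlignmentError, AlignmentMatrix

from _oracles import brute_force_global_score, score_gapped_pair

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def params():
    return fk.AlignmentParams()


class TestGlobalAlign:
    def test_single_residue(self, params):
        score, ga, gb = fk.global_align("A", "A", params)
        assert score == 4  # BLOSUM62 A-A
        assert (ga, gb) == ("A", "A")

    def test_self_alignment_is_diagonal_sum(self, params):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        mat = params.substitution_matrix
        score, ga, gb = fk.global_align(seq, seq, params)
        assert score == sum(mat[c, c] for c in seq)
        assert ga == gb == seq

    def test_gapped_strings_realize_score(self, params):
        rng = np.random.default_rng(3)
        mat = params.substitution_matrix
        for _ in range(30):
            a = "".join(rng.choice(list(AA), rng.integers(4, 25)))
            b = "".join(rng.choice(list(AA), rng.integers(4, 25)))
            score, ga, gb = fk.global_align(a, b, params)
            assert ga.replace("-", "") == a
            assert gb.replace("-", "") == b
            realized = score_gapped_pair(ga, gb, mat, params.gap_open, params.gap_extend)
            assert realized == pytest.approx(score)

    def test_matches_enumeration_oracle(self, params):
        """Optimal score equals exhaustive enumeration on >= 50 random pairs."""
        rng = np.random.default_rng(11)
        mat = params.substitution_matrix
        cases = []
        for _ in range(46):
            la, lb = rng.integers(3, 7, size=2)
            cases.append((la, lb))
        cases += [(6, 7), (7, 6), (7, 7), (8, 5)]
        for la, lb in cases:
            a = "".join(rng.choice(list(AA), la))
            b = "".join(rng.choice(list(AA), lb))
            expected = brute_force_global_score(
                a, b, mat, params.gap_open, params.gap_extend
            )
            score, _, _ = fk.global_align(a, b, params)
            assert score == pytest.approx(expected), (a, b)

    def test_bad_residue_rejected(self, params):
        with pytest.raises(AlignmentError):
            fk.global_align("MKB-", "MK", params)

    def test_empty_rejected(self, params):
        with pytest.raises(AlignmentError):
            fk.global_align("", "MK", params)


class TestAlignmentParams:
    def test_gap_invariant_enforced(self):
        with pytest.raises(ValueError):
            fk.AlignmentParams(gap_open=-1, gap_extend=-11)
        with pytest.raises(ValueError):
            fk.AlignmentParams(gap_open=-5, gap_extend=0)


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        a = fk.SequenceRecord("a", "a", "", "MKTAYIAKQR")
        b = fk.SequenceRecord("b", "b", "", "MKTAYIAKQR")
        D = fk.distance_matrix([a, b])
        assert D.d[0, 1] == 0.0

    def test_disjoint_alphabet_pair(self):
        a = fk.SequenceRecord("a", "a", "", "AAAAA")
        b = fk.SequenceRecord("b", "b", "", "GGGGG")
        D = fk.distance_matrix([a, b])
        assert D.d[0, 1] == 1.0

    def test_three_sequences_hand_identities(self):
        # gap-free optimal alignments: identities 3/4, 2/4, 3/4
        a = fk.SequenceRecord("a", "a", "", "MKTA")
        b = fk.SequenceRecord("b", "b", "", "MKTW")
        c = fk.SequenceRecord("c", "c", "", "MKWW")
        D = fk.distance_matrix([a, b, c])
        assert D.d[0, 1] == pytest.approx(0.25)
        assert D.d[0, 2] == pytest.approx(0.50)
        assert D.d[1, 2] == pytest.approx(0.25)


class TestProgressiveMSA:
    def test_two_sequences_match_pairwise(self, params):
        a = fk.SequenceRecord("a", "a", "", "MKTAYIAKQRQISFVK")
        b = fk.SequenceRecord("b", "b", "", "MKTAYIKQRQISFV")
        D = fk.distance_matrix([a, b], params)
        guide = fk.build_guide_tree(D)
        msa = fk.progressive_msa([a, b], guide, params)
        pair_score, _, _ = fk.global_align(a.residues, b.residues, params)
        mat = params.substitution_matrix
        realized = score_gapped_pair(
            msa.row("a"), msa.row("b"), mat, params.gap_open, params.gap_extend
        )
        assert realized == pytest.approx(pair_score)

    def test_identical_copies_gap_free(self, params):
        records = [
            fk.SequenceRecord(i, i, "", "MKTAYIAKQRQISFVK") for i in ("a", "b", "c")
        ]
        D = fk.distance_matrix(records, params)
        msa = fk.progressive_msa(records, fk.build_guide_tree(D), params)
        assert msa.n_cols == 16
        assert all("-" not in row for row in msa.rows)

    def test_degap_invariant(self, family17, pipeline17):
        _, records, _, _ = family17
        msa = pipeline17["msa"]
        for r in records:
            assert msa.degapped(r.id) == r.residues

    def test_planted_columns_mostly_aligned(self, family17, pipeline17):
        """>= 90% of planted motif columns are recovered as single columns."""
        spec, records, _, truth = family17
        msa = pipeline17["msa"]
        maps = {rid: msa.column_map(rid) for rid in msa.row_ids}
        aligned = total = 0
        for pos, motif in spec.planted_motifs:
            for k in range(len(motif)):
                cols = {
                    maps[t].pos_to_col[truth.motif_spans[t][motif.name][0] + k]
                    for t in msa.row_ids
                }
                total += 1
                aligned += len(cols) == 1
        assert aligned / total >= 0.90

    def test_relabeling_invariance(self, params):
        rng = np.random.default_rng(5)
        records = [
            fk.SequenceRecord(f"s{i}", f"s{i}", "", "".join(rng.choice(list(AA), 30)))
            for i in range(4)
        ]
        D = fk.distance_matrix(records, params)
        guide = fk.build_guide_tree(D)
        msa1 = fk.progressive_msa(records, guide, params)

        mapping = {f"s{i}": f"t{i}" for i in range(4)}

        def relabel(node):
            if node.is_leaf:
                return fk.TreeNode(label=mapping[node.label], height=node.height)
            return fk.TreeNode(
                children=tuple(relabel(c) for c in node.children), height=node.height
            )

        renamed = [
            fk.SequenceRecord(mapping[r.id], mapping[r.id], "", r.residues)
            for r in records
        ]
        msa2 = fk.progressive_msa(renamed, relabel(guide), params)
        assert [mapping[i] for i in msa1.row_ids] == msa2.row_ids
        assert msa1.rows == msa2.rows

    def test_leaf_mismatch_rejected(self, params):
        a = fk.SequenceRecord("a", "a", "", "MKTA")
        b = fk.SequenceRecord("b", "b", "", "MKTW")
        D = fk.distance_matrix([a, b], params)
        guide = fk.build_guide_tree(D)
        with pytest.raises(AlignmentError, match="leaves"):
            fk.progressive_msa([a], guide, params)


class TestColumnMap:
    def test_gap_free_identity(self):
        msa = AlignmentMatrix(row_ids=["a"], rows=["MKT"])
        cmap = msa.column_map("a")
        assert cmap.position(0) == 1 and cmap.position(2) == 3

    def test_leading_gap(self):
        msa = AlignmentMatrix(row_ids=["a", "b"], rows=["-AB", "CAB"])
        cmap = msa.column_map("a")
        assert cmap.position(1) == 1
        assert cmap.column(1) == 1
        assert 0 not in cmap.col_to_pos

    def test_round_trip_random_rows(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            row = "".join(rng.choice(list(AA + "----"), n))
            if row.replace("-", "") == "":
                continue
            msa = AlignmentMatrix(row_ids=["a"], rows=[row])
            cmap = msa.column_map("a")
            for col, pos in cmap.col_to_pos.items():
                assert cmap.pos_to_col[pos] == col
            assert len(cmap.col_to_pos) == len(row.replace("-", ""))
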