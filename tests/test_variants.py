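"""Variant grammar, bundled-table loading, annotation, blocks, verification."""
import pytest

import fam111kit as fk
from fam111kit.variants import (
    DELETION,
    FRAMESHIFT,
    MISSENSE,
    POSITION_ONLY,
    SYNONYMOUS,
    VariantParseError,
    format_variant,
    load_variant_table,
)


class TestParseVariant:
    def test_missense(self):
        (v,) = fk.parse_variant("R569H")
        assert (v.ref_residue, v.position, v.kind, v.alt_residue) == (
            "R", 569, MISSENSE, "H",
        )

    def test_multi_allelic_two(self):
        records = fk.parse_variant("S541[Y/P]")
        assert [r.alt_residue for r in records] == ["Y", "P"]
        assert all(r.kind == MISSENSE for r in records)

    def test_multi_allelic_three_with_space(self):
        records = fk.parse_variant("G542 [S/V/D]")
        assert len(records) == 3
        assert all(r.position == 542 for r in records)

    def test_mixed_missense_frameshift(self):
        records = fk.parse_variant("V357[I/fs]")
        assert [r.kind for r in records] == [MISSENSE, FRAMESHIFT]

    def test_deletion_frameshift_synonymous_position(self):
        assert fk.parse_variant("S342del")[0].kind == DELETION
        assert fk.parse_variant("L292fs")[0].kind == FRAMESHIFT
        assert fk.parse_variant("K586K")[0].kind == SYNONYMOUS
        assert fk.parse_variant("D439")[0].kind == POSITION_ONLY

    @pytest.mark.parametrize("bad", ["569H", "Rx569H", "R569[]", "R0H", "R569[Y//P]"])
    def test_unparseable_tokens(self, bad):
        with pytest.raises(VariantParseError):
            fk.parse_variant(bad)

    def test_round_trip_all_bundled_tokens(self, reference_variants):
        by_row = {}
        for v in reference_variants:
            by_row.setdefault(v.row_index, []).append(v)
        for rows in by_row.values():
            token = format_variant(rows)
            again = fk.parse_variant(token)
            assert [(r.ref_residue, r.position, r.kind, r.alt_residue) for r in again] == [
                (r.ref_residue, r.position, r.kind, r.alt_residue) for r in rows
            ]


class TestLoadVariantTable:
    def test_bundled_table_34_rows(self, reference_variants):
        assert len({v.row_index for v in reference_variants}) == 34

    def test_region_and_flag_parsing(self, reference_variants):
        first = [v for v in reference_variants if v.row_index == 1][0]
        assert first.region_labels == ("PIP",)
        assert first.clinvar_flag is False
        flagged = [v for v in reference_variants if v.row_index == 2][0]
        assert flagged.clinvar_flag is True
        assert flagged.region_labels == ("UBL2/DBD", "Mutation Block 1", "Motif 1")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert load_variant_table(p) == []


class TestDetectBlocks:
    def test_bundled_labels_mode_two_blocks(self, reference_variants):
        blocks = fk.detect_blocks(reference_variants, method="labels")
        assert len(blocks) == 2
        assert [b.name for b in blocks] == ["Mutation Block 1", "Mutation Block 2"]
        for b in blocks:
            lo, hi = b.span
            assert all(lo <= v.position <= hi for v in b.members)

    def test_labels_partition_labeled_variants(self, reference_variants):
        blocks = fk.detect_blocks(reference_variants, method="labels")
        labeled = [
            v
            for v in reference_variants
            if any(l.lower().startswith("mutation block") for l in v.region_labels)
        ]
        in_blocks = [v for b in blocks for v in b.members]
        assert len(in_blocks) == len(labeled)

    def test_density_single_variant(self):
        (v,) = fk.parse_variant("R569H")
        blocks = fk.detect_blocks([v], method="density", min_count=1)
        assert len(blocks) == 1
        assert blocks[0].span == (569, 569)

    def test_density_on_bundled_table_runs(self, reference_variants):
        blocks = fk.detect_blocks(reference_variants, method="density")
        # recorded, not asserted: default density parameters need not
        # reproduce the two printed blocks
        assert all(b.method == "density" for b in blocks)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            fk.detect_blocks([], method="magic")


class TestAnnotateVariants:
    def test_domain_assignment(self, reference_variants):
        dmap = fk.fam111a_domain_map()
        table = fk.annotate_variants(reference_variants, dmap)
        by_pos = table.drop_duplicates("position").set_index("position")
        assert by_pos.loc[569, "domains"] == "SPD"
        assert by_pos.loc[541, "in_s1_pocket"]
        assert by_pos.loc[541, "triad_distance"] == 0
        assert by_pos.loc[226, "domains"] == "UBL2/DBD"

    def test_position_outside_all_domains(self):
        (v,) = fk.parse_variant("M10I")
        table = fk.annotate_variants([v], fk.fam111a_domain_map())
        row = table.iloc[0]
        assert row["domains"] == ""
        assert not row["in_s1_pocket"]
        assert row["triad_distance"] == 375  # |10 - 385|

    def test_f231_pip_discordance_surfaced(self, reference_variants):
        # the printed PIP label for F231A conflicts with PIP 16-28; the
        # annotation reports the discordance instead of silently correcting
        dmap = fk.fam111a_domain_map()
        table = fk.annotate_variants(reference_variants, dmap)
        row = table[table["position"] == 231].iloc[0]
        assert "PIP" in row["domain_discordance"]

    def test_pure_function(self, reference_variants):
        dmap = fk.fam111a_domain_map()
        t1 = fk.annotate_variants(reference_variants, dmap)
        t2 = fk.annotate_variants(reference_variants, dmap)
        assert t1.equals(t2)

    def test_motif_call_containment(self, reference_variants, reference_sequence):
        calls = []
        for pat in fk.reference_motifs():
            calls.extend(fk.scan_pattern(pat, reference_sequence, max_mismatch=1))
        table = fk.annotate_variants(reference_variants, fk.fam111a_domain_map(), calls)
        row541 = table[table["position"] == 541].iloc[0]
        assert "M6" in row541["motif_calls"]


class TestVerifyAnnotations:
    def test_all_pass_on_reference(self, reference_sequence, reference_variants):
        report = fk.verify_annotations(
            reference_sequence, fk.fam111a_domain_map(), reference_variants
        )
        assert report.all_passed
        assert report.n_checks == report.n_passed

    def test_triad_and_cleavage_letters(self, reference_sequence):
        report = fk.verify_annotations(reference_sequence, fk.fam111a_domain_map())
        frame = report.frame.set_index("check")
        assert frame.loc["catalytic_triad@385", "expected"] == "H"
        assert frame.loc["catalytic_triad@439", "expected"] == "D"
        assert frame.loc["catalytic_triad@541", "expected"] == "S"
        assert frame.loc["cleavage_site@334", "expected"] == "F"
        assert frame.loc["cleavage_site@335", "expected"] == "G"

    def test_corrupted_sequence_fails_locally(self, reference_sequence, reference_variants):
        residues = list(reference_sequence.residues)
        residues[384] = "A" if residues[384] != "A" else "G"  # break H385
        corrupted = fk.SequenceRecord(
            id="corrupt", description="corrupted copy", organism="",
            residues="".join(residues),
        )
        report = fk.verify_annotations(
            corrupted, fk.fam111a_domain_map(), reference_variants
        )
        frame = report.frame
        failed = frame[~frame["passed"]]
        assert not report.all_passed
        assert set(failed["position"]) == {385}
        assert frame[frame["position"] != 385]["passed"].all()
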