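"""Annotation loading: coordinate conversion, species merging, prediction tables."""

import numpy as np
import pytest

from tdmdscan.annotations import (
    AnnotationError,
    TargetPrediction,
    cognate_map,
    load_mirbase_gff,
    load_target_predictions,
    write_mirbase_gff,
    write_target_predictions,
)
from tdmdscan.synthetic import SyntheticConfig, simulate_annotation

from conftest import make_hairpin, make_mature


def _write_toy_annotation(tmp_path, gff_lines, fasta_records):
    gff = tmp_path / "toy.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_lines) + "\n")
    fa = tmp_path / "toy.fa"
    fa.write_text("".join(f">{i}\n{s}\n" for i, s in fasta_records))
    return gff, fa


HAIRPIN_SEQ = "ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGU"


class TestLoadMirbaseGff:
    def test_coordinate_conversion_and_offset(self, tmp_path):
        """1-based inclusive GFF interval 101..200 becomes [100, 200); a mature
        at 111..132 sits at hairpin offset 10 with length 22."""
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t200\t.\t+\t.\tID=hp1",
                "chr1\t.\tmiRNA\t111\t132\t.\t+\t.\tID=m1;Name=mir-1-5p;Derives_from=hp1",
            ],
            [("hp1", HAIRPIN_SEQ)],
        )
        loci, species = load_mirbase_gff(gff, fa)
        assert len(loci) == 1 and len(species) == 1
        assert (loci[0].start, loci[0].end) == (100, 200)
        sp = species[0]
        assert sp.offset_in_hairpin == 10
        assert len(sp.sequence) == 22
        assert sp.sequence == HAIRPIN_SEQ[10:32]

    def test_minus_strand_offset_is_from_hairpin_5prime(self, tmp_path):
        """On the minus strand the mature closest to the genomic end is at the
        5' end of the hairpin sequence."""
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t200\t.\t-\t.\tID=hp1",
                "chr1\t.\tmiRNA\t169\t190\t.\t-\t.\tID=m1;Name=mir-1-5p;Derives_from=hp1",
            ],
            [("hp1", HAIRPIN_SEQ)],
        )
        _loci, species = load_mirbase_gff(gff, fa)
        assert species[0].offset_in_hairpin == 10

    def test_identical_matures_merge_into_one_species(self, tmp_path):
        seq = HAIRPIN_SEQ[:90]
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t190\t.\t+\t.\tID=hp1",
                "chr2\t.\tmiRNA_primary_transcript\t501\t590\t.\t+\t.\tID=hp2",
                "chr1\t.\tmiRNA\t105\t126\t.\t+\t.\tID=m1;Name=mir-9-5p;Derives_from=hp1",
                "chr2\t.\tmiRNA\t505\t526\t.\t+\t.\tID=m2;Name=mir-9-5p;Derives_from=hp2",
            ],
            [("hp1", seq), ("hp2", seq)],
        )
        loci, species = load_mirbase_gff(gff, fa)
        assert len(loci) == 2
        assert len(species) == 1
        assert species[0].parent_locus_ids == ("hp1", "hp2")

    def test_dangling_derives_from_names_the_feature(self, tmp_path):
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t200\t.\t+\t.\tID=hp1",
                "chr1\t.\tmiRNA\t111\t132\t.\t+\t.\tID=m1;Name=mir-1-5p;Derives_from=hpX",
            ],
            [("hp1", HAIRPIN_SEQ)],
        )
        with pytest.raises(AnnotationError, match="hpX"):
            load_mirbase_gff(gff, fa)

    def test_mature_outside_hairpin_is_an_error(self, tmp_path):
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t150\t.\t+\t.\tID=hp1",
                "chr1\t.\tmiRNA\t140\t161\t.\t+\t.\tID=m1;Name=mir-1-5p;Derives_from=hp1",
            ],
            [("hp1", HAIRPIN_SEQ[:50])],
        )
        with pytest.raises(AnnotationError):
            load_mirbase_gff(gff, fa)

    def test_family_confidence_and_missing_entry_warning(self, tmp_path):
        gff, fa = _write_toy_annotation(
            tmp_path,
            [
                "chr1\t.\tmiRNA_primary_transcript\t101\t200\t.\t+\t.\tID=hp1",
                "chr2\t.\tmiRNA_primary_transcript\t101\t200\t.\t+\t.\tID=hp2",
                "chr1\t.\tmiRNA\t111\t132\t.\t+\t.\tID=m1;Name=mir-1-5p;Derives_from=hp1",
                "chr2\t.\tmiRNA\t111\t132\t.\t+\t.\tID=m2;Name=mir-2-5p;Derives_from=hp2",
            ],
            [("hp1", HAIRPIN_SEQ), ("hp2", HAIRPIN_SEQ.replace("A", "G"))],
        )
        fam = tmp_path / "fam.tsv"
        fam.write_text("family_id\tspecies_id\tconfidence\nf1\tmir-1-5p\tBroadly Conserved\n")
        with pytest.warns(UserWarning, match="mir-2-5p"):
            loci, species = load_mirbase_gff(gff, fa, fam)
        by_id = {l.locus_id: l for l in loci}
        assert by_id["hp1"].family_confident is True
        assert by_id["hp2"].family_confident is False
        assert {s.species_id: s.family_id for s in species}["mir-2-5p"] == "NA"


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        cfg = SyntheticConfig(n_loci=30, n_clusters=3, n_clustered=10,
                              include_polycistron=False, include_paralog_trio=False)
        loci, species, _ = simulate_annotation(cfg, 42)
        write_mirbase_gff(loci, species, tmp_path / "a.gff3", tmp_path / "a.fa", tmp_path / "fam.tsv")
        loci2, species2 = load_mirbase_gff(tmp_path / "a.gff3", tmp_path / "a.fa", tmp_path / "fam.tsv")
        orig = {l.locus_id: l for l in loci}
        for l in loci2:
            o = orig[l.locus_id]
            assert (l.chromosome, l.strand, l.start, l.end, l.sequence) == (
                o.chromosome, o.strand, o.start, o.end, o.sequence
            )
        orig_sp = {s.species_id: s for s in species}
        assert set(orig_sp) == {s.species_id for s in species2}
        for s in species2:
            o = orig_sp[s.species_id]
            assert (s.arm, s.offset_in_hairpin, s.sequence, s.annotated_role, s.family_id) == (
                o.arm, o.offset_in_hairpin, o.sequence, o.annotated_role, o.family_id
            )
            assert s.parent_locus_ids == o.parent_locus_ids

    def test_paralog_merge_survives_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_loci=40, n_clusters=4, n_clustered=20,
                              include_polycistron=False, include_paralog_trio=True)
        loci, species, _ = simulate_annotation(cfg, 7)
        shared = [s for s in species if len(s.parent_locus_ids) > 1]
        assert shared and len(shared[0].parent_locus_ids) == 2
        write_mirbase_gff(loci, species, tmp_path / "a.gff3", tmp_path / "a.fa")
        _l2, species2 = load_mirbase_gff(tmp_path / "a.gff3", tmp_path / "a.fa")
        shared2 = [s for s in species2 if len(s.parent_locus_ids) > 1]
        assert {s.species_id for s in shared2} == {s.species_id for s in shared}


class TestTargetPredictions:
    def _rows(self):
        return [
            TargetPrediction("tx1", "famA", True, True, -0.41, 800),
            TargetPrediction("tx2", "famA", True, False, -0.10, 1200),
            TargetPrediction("tx3", "famA", False, False, 0.0, 300),
        ]

    def test_three_row_round_trip(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_target_predictions(self._rows(), path)
        assert load_target_predictions(path) == self._rows()

    def test_conserved_without_site_is_invalid(self):
        with pytest.raises(AnnotationError, match="conserved"):
            TargetPrediction("tx1", "famA", False, True, -0.4, 800)

    def test_duplicate_pair_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "p.tsv"
        rows = self._rows() + [self._rows()[0]]
        write_target_predictions(rows, path)
        with pytest.raises(AnnotationError, match="row 5"):
            load_target_predictions(path)

    def test_non_numeric_score_reports_row(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "transcript_id\tfamily_id\thas_site\tconserved\tcontext_score\tutr_length\n"
            "tx1\tfamA\tTrue\tFalse\toops\t800\n"
        )
        with pytest.raises(AnnotationError, match="row 2"):
            load_target_predictions(path)

    def test_top_decile_of_forty_has_four_members(self):
        preds = [
            TargetPrediction(f"tx{i}", "famA", True, False, -i / 100.0, 500)
            for i in range(1, 41)
        ]
        n_top = max(1, len(preds) // 10)
        assert n_top == 4


def test_cognate_map_pairs_other_arm():
    hp = make_hairpin("hpZ")
    m5 = make_mature(hp, "mir-z-5p", arm="5p", offset=4)
    m3 = make_mature(hp, "mir-z-3p", arm="3p", offset=60, role="passenger")
    cm = cognate_map([m5, m3])
    assert cm["mir-z-5p"] == ("mir-z-3p",)
    assert cm["mir-z-3p"] == ("mir-z-5p",)


def test_every_mature_matches_hairpin_at_offset():
    cfg = SyntheticConfig(n_loci=50, n_clusters=5, n_clustered=24,
                          include_polycistron=False, include_paralog_trio=True)
    loci, species, _ = simulate_annotation(cfg, 3)
    by_id = {l.locus_id: l for l in loci}
    for sp in species:
        for pid in sp.parent_locus_ids:
            hp = by_id[pid]
            assert hp.sequence[sp.offset_in_hairpin : sp.offset_in_hairpin + len(sp.sequence)] == sp.sequence
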