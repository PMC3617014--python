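"""Gene model loading, region classification precedence, tract localization."""

from pathlib import Path

import pytest
from Bio.Seq import Seq

from tritract.annotation import (
    INTERGENIC,
    INTRON,
    UPSTREAM,
    UTR3,
    UTR5,
    EXONIC,
    AnnotationError,
    GeneModel,
    RegionIndex,
    classify_position,
    load_annotation,
    localize_tracts,
)
from tritract.scanner import RepeatTract


def _gff(lines: list[str], tmp_path: Path) -> Path:
    p = tmp_path / "test.gff3"
    p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return p


def _feature(ftype, s, e, strand, attrs, phase="."):
    # s, e are 1-based inclusive as in GFF3
    return f"chr1\ttest\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}"


TWO_VARIANT_GENE = [
    _feature("gene", 1001, 3000, "+", "ID=gA"),
    _feature("mRNA", 1001, 3000, "+", "ID=gA.1;Parent=gA"),
    _feature("exon", 1001, 3000, "+", "ID=gA.1.e1;Parent=gA.1"),
    _feature("CDS", 1101, 1400, "+", "ID=gA.1.c1;Parent=gA.1", "0"),
    _feature("mRNA", 1001, 3000, "+", "ID=gA.2;Parent=gA;protein_id=pA2"),
    _feature("exon", 1001, 3000, "+", "ID=gA.2.e1;Parent=gA.2"),
    _feature("CDS", 1101, 1466, "+", "ID=gA.2.c1;Parent=gA.2", "0"),
]


class TestLoadAnnotation:
    def test_longest_cds_variant_selected(self, tmp_path):
        models = load_annotation(_gff(TWO_VARIANT_GENE, tmp_path), "longest_cds")
        assert len(models) == 1
        assert models[0].cds_length == 366
        assert models[0].protein_id == "pA2"

    def test_first_listed_variant_selected(self, tmp_path):
        models = load_annotation(_gff(TWO_VARIANT_GENE, tmp_path), "first_listed")
        assert models[0].cds_length == 300

    def test_single_variant_kept_under_either_rule(self, tmp_path):
        lines = TWO_VARIANT_GENE[:4]
        for rule in ("longest_cds", "first_listed"):
            models = load_annotation(_gff(lines, tmp_path), rule)
            assert len(models) == 1 and models[0].cds_length == 300

    def test_gene_without_cds_dropped(self, tmp_path):
        lines = [
            _feature("gene", 1, 500, "+", "ID=gN"),
            _feature("mRNA", 1, 500, "+", "ID=gN.1;Parent=gN"),
            _feature("exon", 1, 500, "+", "ID=gN.1.e1;Parent=gN.1"),
        ]
        assert load_annotation(_gff(lines, tmp_path)) == []

    def test_cds_not_multiple_of_three_dropped(self, tmp_path):
        lines = [
            _feature("gene", 1, 500, "+", "ID=gB"),
            _feature("mRNA", 1, 500, "+", "ID=gB.1;Parent=gB"),
            _feature("exon", 1, 500, "+", "ID=gB.1.e1;Parent=gB.1"),
            _feature("CDS", 101, 300, "+", "ID=gB.1.c1;Parent=gB.1", "0"),
        ]
        assert load_annotation(_gff(lines, tmp_path)) == []

    def test_blacklisted_sequences_excluded(self, tmp_path):
        models = load_annotation(
            _gff(TWO_VARIANT_GENE, tmp_path), sequence_blacklist=["chr1"]
        )
        assert models == []

    def test_synthetic_round_trip_translates(self, default_sim_dir):
        sim, paths = default_sim_dir
        models = load_annotation(paths["annotation"])
        assert len(models) == len(sim.genes)
        by_pid = {m.protein_id: m for m in models}
        for g in sim.genes:
            m = by_pid[g.protein_id]
            cds = ""
            for s, e in m.cds_segments:
                piece = sim.genome[s:e]
                if m.strand == "-":
                    piece = str(Seq(piece).reverse_complement())
                cds += piece
            assert str(Seq(cds).translate()).rstrip("*") == g.protein_seq


def _plus_gene():
    # exons [100,200)+[300,400); CDS [150,200)+[300,340); rest UTR
    return GeneModel(
        gene_id="gP", sequence_id="chr1", strand="+",
        exons=[(100, 200), (300, 400)],
        cds_segments=[(150, 200), (300, 340)],
        utr5=[(100, 150)], utr3=[(340, 400)],
        protein_id="pP",
    )


def _minus_gene():
    return GeneModel(
        gene_id="gM", sequence_id="chr1", strand="-",
        exons=[(1000, 1100), (1200, 1300)],
        cds_segments=[(1250, 1300), (1060, 1100)],  # transcription order
        utr5=[(1300, 1300)], utr3=[(1000, 1060)],
        protein_id="pM",
    )


class TestClassifyPosition:
    def test_cds_position_is_exonic(self):
        assert classify_position([_plus_gene()], "chr1", 160) == EXONIC

    def test_utr_and_intron_positions(self):
        g = _plus_gene()
        assert classify_position([g], "chr1", 120) == UTR5
        assert classify_position([g], "chr1", 360) == UTR3
        assert classify_position([g], "chr1", 250) == INTRON

    def test_upstream_window_on_plus_strand(self):
        assert classify_position([_plus_gene()], "chr1", 50, upstream=1000) == UPSTREAM

    def test_upstream_window_on_minus_strand_is_above_gene_end(self):
        g = _minus_gene()
        assert classify_position([g], "chr1", 1400, upstream=1000) == UPSTREAM
        assert classify_position([g], "chr1", 950) == INTERGENIC

    def test_minus_strand_utr5_at_higher_coordinates_than_utr3(self, default_sim):
        for g in default_sim.genes:
            if g.strand == "-" and g.utr5 and g.utr3:
                assert min(s for s, _ in g.utr5) >= max(e for _, e in g.utr3)

    def test_intron_beats_upstream_of_neighbor(self):
        # gene B starts right of gene A; A's intron lies in B's upstream window
        a = _plus_gene()
        b = GeneModel(
            gene_id="gB", sequence_id="chr1", strand="+",
            exons=[(500, 700)], cds_segments=[(530, 680)],
            utr5=[(500, 530)], utr3=[(680, 700)],
        )
        assert classify_position([a, b], "chr1", 250, upstream=1000) == INTRON

    def test_unknown_sequence_raises(self):
        with pytest.raises(AnnotationError):
            classify_position([_plus_gene()], "chrX", 10)


def _tract(start, end, seq_id="chr1"):
    return RepeatTract(
        sequence_id=seq_id, start=start, end=end, period=3, unit="CAG",
        canonical_unit="AGC", copies=(end - start) / 3, score=2 * (end - start),
        matches=end - start, mismatches=0, indels=0, purity=1.0,
    )


class TestLocalizeTracts:
    def test_tract_inside_cds_linked_to_gene(self):
        (t,) = localize_tracts([_tract(155, 185)], [_plus_gene()])
        assert t.region_class == EXONIC
        assert t.gene_id == "gP" and t.protein_id == "pP"

    def test_majority_overlap_wins(self):
        # 60% intron [200,300) / 40% exonic: spans 182..242 -> 18 exonic, 42 intron
        (t,) = localize_tracts([_tract(182, 242)], [_plus_gene()])
        assert t.region_class == INTRON

    def test_no_feature_overlap_is_intergenic(self):
        (t,) = localize_tracts([_tract(5000, 5030)], [_plus_gene()])
        assert t.region_class == INTERGENIC and t.gene_id is None

    def test_classes_partition_tract_counts(self, default_sim):
        from tritract.scanner import scan

        tracts = scan(default_sim.genome, default_sim.config.chrom_name)
        models = [
            GeneModel(
                gene_id=g.gene_id, sequence_id=g.sequence_id, strand=g.strand,
                exons=g.exons, cds_segments=g.cds_segments,
                utr5=g.utr5, utr3=g.utr3, protein_id=g.protein_id,
            )
            for g in default_sim.genes
        ]
        loc = localize_tracts(tracts, models, upstream=1000)
        assert all(t.region_class is not None for t in loc)
        assert len(loc) == len(tracts)

    def test_planted_region_labels_recovered(self, default_sim):
        from tritract.scanner import scan

        sim = default_sim
        tracts = scan(sim.genome, sim.config.chrom_name)
        models = [
            GeneModel(
                gene_id=g.gene_id, sequence_id=g.sequence_id, strand=g.strand,
                exons=g.exons, cds_segments=g.cds_segments,
                utr5=g.utr5, utr3=g.utr3, protein_id=g.protein_id,
            )
            for g in sim.genes
        ]
        index = RegionIndex(models, upstream=sim.config.upstream_window)
        loc = {(t.start, t.end): t for t in localize_tracts(tracts, index)}
        agree = sum(
            loc[(r.start, r.end)].region_class == r.region_class
            for r in sim.truth.tnr_records
            if (r.start, r.end) in loc
        )
        assert agree / len(sim.truth.tnr_records) >= 0.99
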