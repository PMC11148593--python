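"""Coordinate conventions, region parsing, gene overlap, orthology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pilaf.errors import ContractError, RegionParseError, ValidationError
from pilaf.genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    OrthologyMap,
    format_region,
    genes_overlapping,
    merge_intervals,
    orthologs_of,
    parse_region,
    read_bed,
    read_gff3,
    read_orthogroups,
)


class TestParseRegion:
    @pytest.mark.parametrize(
        "text, chrom, start, end",
        [
            # printed 1-based inclusive loci, incl. a thousands separator
            ("Chr01:1523,625-1770814", "Chr01", 1523624, 1770814),
            ("Chr04:4662701-4670717", "Chr04", 4662700, 4670717),
            ("  chr2 : 1,000 - 2,000 ", "Chr2", 999, 2000),
            ("scaffold_3:10-20", "scaffold_3", 9, 20),
        ],
    )
    def test_printed_coordinates_become_half_open(self, text, chrom, start, end):
        iv = parse_region(text)
        assert (iv.chrom, iv.start, iv.end) == (chrom, start, end)

    @pytest.mark.parametrize(
        "text",
        ["Chr1:5-5", "Chr1:10-5", "Chr1:0-5", "Chr1:a-b", "Chr1", "Chr1:-", ""],
    )
    def test_malformed_or_empty_spans_rejected(self, text):
        with pytest.raises(RegionParseError):
            parse_region(text)

    @given(
        chrom=st.integers(1, 12),
        start=st.integers(0, 10**8),
        # single-bp spans print as "X:n-n", which the parser rejects as
        # empty under the 1-based inclusive convention, so the round
        # trip holds for printable spans of >= 2 bp
        length=st.integers(2, 10**6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_format_parse_round_trip(self, chrom, start, length):
        iv = GenomicInterval("", f"Chr{chrom:02d}", start, start + length)
        back = parse_region(format_region(iv))
        assert (back.chrom, back.start, back.end) == (iv.chrom, iv.start, iv.end)


class TestIntervalInvariants:
    def test_invalid_spans_raise(self):
        with pytest.raises(ValidationError):
            GenomicInterval("", "c", 5, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("", "c", -1, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("", "", 0, 5)

    def test_merge_joins_abutting_and_overlapping(self):
        ivs = [
            GenomicInterval("", "c1", 10, 20),
            GenomicInterval("", "c1", 20, 30),
            GenomicInterval("", "c1", 50, 60),
            GenomicInterval("", "c2", 10, 30),
            GenomicInterval("", "c1", 55, 70),
        ]
        merged = [(i.chrom, i.start, i.end) for i in merge_intervals(ivs)]
        assert merged == [("c1", 10, 30), ("c1", 50, 70), ("c2", 10, 30)]


def _annot(spans, genome="G", chrom="c1"):
    genes = [
        GeneModel(f"g{i}", GenomicInterval(genome, chrom, s, e))
        for i, (s, e) in enumerate(spans, 1)
    ]
    return GenomeAnnotation(genome, genes)


class TestGenesOverlapping:
    def test_basic_overlap_and_half_open_touching(self):
        annot = _annot([(150, 160), (300, 400), (200, 210)])
        hits = genes_overlapping([GenomicInterval("G", "c1", 100, 200)], annot)
        # the gene at (200, 210) touches but does not overlap
        assert [g.gene_id for g in hits] == ["g1"]

    def test_empty_interval_list(self):
        assert genes_overlapping([], _annot([(1, 2)])) == []

    def test_genome_mismatch_raises(self):
        with pytest.raises(ContractError):
            genes_overlapping([GenomicInterval("other", "c1", 0, 10)], _annot([(1, 5)]))

    def test_chrom_prefix_insensitive(self):
        annot = _annot([(10, 20)], chrom="chr7")
        hits = genes_overlapping([GenomicInterval("G", "Chr7", 0, 100)], annot)
        assert len(hits) == 1

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        spans = []
        pos = 0
        for _ in range(2000):
            pos += int(rng.integers(1, 50))
            spans.append((pos, pos + int(rng.integers(1, 80))))
        annot = _annot(spans)
        queries = [
            GenomicInterval("G", "c1", s, s + int(rng.integers(1, 500)))
            for s in rng.integers(0, pos, size=50)
        ]
        got = {g.gene_id for g in genes_overlapping(queries, annot)}
        expect = {
            f"g{i}"
            for i, (s, e) in enumerate(spans, 1)
            if any(q.start < e and s < q.end for q in queries)
        }
        assert got == expect

    def test_overlap_symmetry(self):
        rng = np.random.default_rng(3)
        spans = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 5000, 200), rng.integers(1, 100, 200))]
        annot = _annot(spans)
        q = GenomicInterval("G", "c1", 1000, 1400)
        forward = {g.gene_id for g in genes_overlapping([q], annot)}
        # reversed roles: index the query as a "gene", query each gene span
        q_annot = GenomeAnnotation("G", [GeneModel("q", q)])
        backward = {
            f"g{i}"
            for i, (s, e) in enumerate(spans, 1)
            if genes_overlapping([GenomicInterval("G", "c1", s, e)], q_annot)
        }
        assert forward == backward


class TestReadGff3:
    def test_three_genes_with_coordinate_conversion(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 5000\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Note=first\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tsrc\tgene\t301\t400\t.\t-\t.\tID=g2\n"
            "chr1\tsrc\tgene\t1001\t1100\t.\t.\t.\tID=g3\n"
        )
        annot = read_gff3(gff, "G")
        assert len(annot) == 3
        g1 = annot.genes["g1"]
        assert (g1.interval.start, g1.interval.end) == (100, 200)
        assert g1.description == "first"
        assert annot.genes["g2"].strand == "-"
        assert annot.genes["g3"].strand == "?"
        assert annot.chrom_sizes == {"chr1": 5000}

    def test_record_without_id_skipped_with_warning(self, tmp_path):
        gff = tmp_path / "b.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tName=anon\n"
            "chr1\tsrc\tgene\t21\t30\t.\t+\t.\tID=ok\n"
        )
        with pytest.warns(UserWarning, match="no ID"):
            annot = read_gff3(gff, "G")
        assert list(annot.genes) == ["ok"]

    def test_empty_file(self, tmp_path):
        gff = tmp_path / "c.gff3"
        gff.write_text("##gff-version 3\n")
        assert len(read_gff3(gff, "G")) == 0

    def test_gene_past_chromosome_end_rejected(self, tmp_path):
        gff = tmp_path / "d.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 100\n"
            "chr1\tsrc\tgene\t50\t200\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValidationError):
            read_gff3(gff, "G")


class TestReadBed:
    def test_sorting_and_rejection(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("c2\t5\t10\nc1\t100\t200\nc1\t10\t10\nc1\t0\t5\n")
        with pytest.warns(UserWarning, match="invalid span"):
            ivs = read_bed(bed, "G")
        assert [(i.chrom, i.start, i.end) for i in ivs] == [
            ("c1", 0, 5),
            ("c1", 100, 200),
            ("c2", 5, 10),
        ]


class TestOrthology:
    def test_group_lookup_and_misses(self, tmp_path):
        tsv = tmp_path / "og.tsv"
        tsv.write_text(
            "OGI:1\tNB\tg1\nOGI:1\tIR64\tt1\nOGI:1\tIR64\tt1b\nOGI:2\tNB\tg9\n"
        )
        omap = read_orthogroups(tsv)
        assert orthologs_of("g1", omap, "IR64") == {"t1", "t1b"}
        assert orthologs_of("t1", omap, "NB") == {"g1"}
        assert orthologs_of("absent", omap, "IR64") == set()
        # singleton group: no orthologs anywhere else
        assert orthologs_of("g9", omap, "IR64") == set()

    def test_gene_in_two_groups_rejected(self):
        omap = OrthologyMap()
        omap.add("OGI:1", "NB", "g1")
        with pytest.raises(ValidationError):
            omap.add("OGI:2", "NB", "g1")
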