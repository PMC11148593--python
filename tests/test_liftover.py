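"""Interval projection through one-to-one alignments and gene-set
partitioning by orthology."""

import numpy as np
import pytest

from pilaf.errors import ValidationError
from pilaf.genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    OrthologyMap,
)
from pilaf.liftover import (
    SOURCE_TO_TARGET,
    TARGET_TO_SOURCE,
    AlignmentSegment,
    AlignmentSet,
    liftover_gene_sets,
    project_interval,
    read_alignments,
)


def seg(sc, s0, s1, tc, t0, t1, strand="+"):
    return AlignmentSegment(sc, s0, s1, tc, t0, t1, strand)


class TestReadAlignments:
    def test_valid_rows(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\tstrand\n"
            "c1\t0\t100\tt1\t500\t600\t+\n"
            "c1\t200\t300\tt1\t700\t800\t-\n"
        )
        assert len(read_alignments(p)) == 2

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text("c1\t0\t100\tt1\t500\t599\t+\n")
        with pytest.raises(ValidationError, match="preserve length"):
            read_alignments(p)

    def test_target_side_overlap_rejected(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text(
            "c1\t0\t100\tt1\t500\t600\t+\n" "c1\t200\t300\tt1\t550\t650\t+\n"
        )
        with pytest.raises(ValidationError, match="one-to-one"):
            read_alignments(p)

    def test_source_side_overlap_rejected(self):
        with pytest.raises(ValidationError, match="one-to-one"):
            AlignmentSet([seg("c1", 0, 100, "t1", 0, 100),
                          seg("c1", 50, 150, "t2", 0, 100)])


class TestProjectInterval:
    def test_forward_affine(self):
        aln = AlignmentSet([seg("Chr12", 1000, 2000, "chrA", 5000, 6000)])
        out = project_interval(GenomicInterval("", "Chr12", 1500, 1600), aln)
        assert [(i.chrom, i.start, i.end) for i in out] == [("chrA", 5500, 5600)]

    def test_reverse_strand_affine(self):
        aln = AlignmentSet([seg("Chr12", 1000, 2000, "chrA", 5000, 6000, "-")])
        out = project_interval(GenomicInterval("", "Chr12", 1000, 1010), aln)
        assert [(i.chrom, i.start, i.end) for i in out] == [("chrA", 5990, 6000)]

    def test_disjoint_query_empty(self):
        aln = AlignmentSet([seg("c1", 1000, 2000, "t1", 0, 1000)])
        assert project_interval(GenomicInterval("", "c1", 5000, 6000), aln) == []

    def test_unknown_chromosome_warns_empty(self):
        aln = AlignmentSet([seg("c1", 0, 100, "t1", 0, 100)])
        with pytest.warns(UserWarning, match="no alignment coverage"):
            out = project_interval(GenomicInterval("", "c9", 5, 10), aln)
        assert out == []

    def test_query_spanning_segments_on_two_chromosomes(self):
        aln = AlignmentSet(
            [seg("c1", 0, 100, "tA", 500, 600), seg("c1", 150, 250, "tB", 0, 100)]
        )
        out = project_interval(GenomicInterval("", "c1", 50, 200), aln)
        assert [(i.chrom, i.start, i.end) for i in out] == [
            ("tA", 550, 600),
            ("tB", 0, 50),
        ]

    def test_abutting_images_merged(self):
        aln = AlignmentSet(
            [seg("c1", 0, 100, "t1", 0, 100), seg("c1", 100, 200, "t1", 100, 200)]
        )
        out = project_interval(GenomicInterval("", "c1", 50, 150), aln)
        assert [(i.start, i.end) for i in out] == [(50, 150)]

    def test_round_trip_inside_segment_both_strands(self):
        rng = np.random.default_rng(11)
        aln = AlignmentSet(
            [
                seg("c1", 0, 10_000, "t1", 40_000, 50_000, "+"),
                seg("c1", 20_000, 30_000, "t2", 5_000, 15_000, "-"),
            ]
        )
        for _ in range(200):
            s0 = int(rng.integers(0, 2)) * 20_000
            a = s0 + int(rng.integers(0, 9_000))
            b = a + int(rng.integers(1, 1_000))
            iv = GenomicInterval("", "c1", a, b)
            fwd = project_interval(iv, aln, SOURCE_TO_TARGET)
            assert len(fwd) == 1
            back = project_interval(fwd[0], aln, TARGET_TO_SOURCE)
            assert [(i.chrom, i.start, i.end) for i in back] == [("c1", a, b)]

    def test_length_conservation(self):
        aln = AlignmentSet(
            [seg("c1", 100, 200, "t1", 0, 100), seg("c1", 300, 400, "t1", 200, 300)]
        )
        # partially covered query: projected bp < query bp
        iv = GenomicInterval("", "c1", 150, 350)
        out = project_interval(iv, aln)
        assert sum(i.length for i in out) == 100 < iv.length
        # fully covered query: equality
        iv2 = GenomicInterval("", "c1", 110, 190)
        assert sum(i.length for i in project_interval(iv2, aln)) == iv2.length

    def test_monotone_forward_reversing_backward(self):
        fwd = AlignmentSet([seg("c1", 0, 1000, "t1", 0, 1000, "+")])
        rev = AlignmentSet([seg("c1", 0, 1000, "t1", 0, 1000, "-")])
        points = [(10, 20), (500, 510), (990, 1000)]
        f = [project_interval(GenomicInterval("", "c1", a, b), fwd)[0].start
             for a, b in points]
        r = [project_interval(GenomicInterval("", "c1", a, b), rev)[0].start
             for a, b in points]
        assert f == sorted(f)
        assert r == sorted(r, reverse=True)


def _mini_fixture():
    """Hand-built source/target pair exercising all four partition
    categories: src genes g1..g3 in the interval, tgt t1 (ortholog g1),
    t2 (ortholog g9 outside), t3 (no group)."""
    src = GenomeAnnotation(
        "S",
        [
            GeneModel("g1", GenomicInterval("S", "c1", 100, 200)),
            GeneModel("g2", GenomicInterval("S", "c1", 300, 400)),
            GeneModel("g3", GenomicInterval("S", "c1", 500, 600)),
            GeneModel("g9", GenomicInterval("S", "c1", 5000, 5100)),
        ],
    )
    tgt = GenomeAnnotation(
        "T",
        [
            GeneModel("t1", GenomicInterval("T", "x1", 1100, 1200)),
            GeneModel("t2", GenomicInterval("T", "x1", 1300, 1350)),
            GeneModel("t3", GenomicInterval("T", "x1", 1500, 1600)),
        ],
    )
    aln = AlignmentSet([seg("c1", 0, 1000, "x1", 1000, 2000)], "S", "T")
    omap = OrthologyMap()
    omap.add("OGI:1", "S", "g1")
    omap.add("OGI:1", "T", "t1")
    omap.add("OGI:9", "S", "g9")
    omap.add("OGI:9", "T", "t2")
    return src, tgt, aln, omap


class TestLiftoverGeneSets:
    def test_partition_on_mini_fixture(self):
        src, tgt, aln, omap = _mini_fixture()
        comp = liftover_gene_sets(
            [GenomicInterval("S", "c1", 0, 1000)], src, tgt, aln, omap
        )
        assert comp.common == {("g1", "t1")}
        assert comp.ortholog_elsewhere == {"t2"}
        assert comp.no_ortholog == {"t3"}
        assert comp.unique_to_source == {"g2", "g3"}

    def test_no_coverage_all_unique_to_source(self):
        src, tgt, aln, omap = _mini_fixture()
        with pytest.warns(UserWarning):
            comp = liftover_gene_sets(
                [GenomicInterval("S", "c9", 0, 1000)], src, tgt, aln, omap
            )
        assert comp.target_genes == [] and comp.common == set()
        assert comp.unique_to_source == set()  # no src genes on c9 either

    def test_identity_alignment_all_common(self):
        genes = [
            GeneModel(f"g{i}", GenomicInterval("S", "c1", i * 100, i * 100 + 50))
            for i in range(1, 4)
        ]
        src = GenomeAnnotation("S", genes)
        aln = AlignmentSet([seg("c1", 0, 1000, "c1", 0, 1000)], "S", "S")
        omap = OrthologyMap()  # identity pairing needs no groups when ids match
        for g in genes:
            omap.add(f"OGI:{g.gene_id}", "S", g.gene_id)
        comp = liftover_gene_sets(
            [GenomicInterval("S", "c1", 0, 1000)], src, src, aln, omap
        )
        assert comp.common == {("g1", "g1"), ("g2", "g2"), ("g3", "g3")}
        assert not comp.ortholog_elsewhere
        assert not comp.no_ortholog
        assert not comp.unique_to_source

    def test_partition_disjoint_and_exhaustive_random(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            n = int(rng.integers(4, 15))
            src_genes, tgt_genes = [], []
            omap = OrthologyMap()
            for i in range(n):
                s = i * 200 + int(rng.integers(0, 50))
                src_genes.append(
                    GeneModel(f"s{i}", GenomicInterval("S", "c1", s, s + 80))
                )
                t = i * 200 + int(rng.integers(0, 50))
                tgt_genes.append(
                    GeneModel(f"t{i}", GenomicInterval("T", "x1", t, t + 80))
                )
                kind = rng.random()
                if kind < 0.5:
                    omap.add(f"OGI:{i}", "S", f"s{i}")
                    omap.add(f"OGI:{i}", "T", f"t{i}")
                elif kind < 0.75:
                    omap.add(f"OGI:{i}", "T", f"t{i}")  # tgt-only group
            src = GenomeAnnotation("S", src_genes)
            tgt = GenomeAnnotation("T", tgt_genes)
            L = n * 200 + 100
            aln = AlignmentSet([seg("c1", 0, L, "x1", 0, L)], "S", "T")
            a = int(rng.integers(0, L - 300))
            comp = liftover_gene_sets(
                [GenomicInterval("S", "c1", a, a + 300)], src, tgt, aln, omap
            )
            tgt_ids = {t.gene_id for t in comp.target_genes}
            common_t = {t for _, t in comp.common}
            parts = [common_t, comp.ortholog_elsewhere, comp.no_ortholog]
            assert set().union(*parts) == tgt_ids
            assert sum(len(p) for p in parts) == len(tgt_ids)
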