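"""Coordinate lift-over through one-to-one pairwise genome alignments.

GWAS/QTL intervals are usually reported against a single reference
assembly.  Given a precomputed set of ungapped one-to-one local alignment
segments between the reference and another assembly, this module projects
intervals onto the other genome and partitions the gene sets on either
side by orthology.  Alignments are not required to be colinear, so a
single query interval may project onto several chromosomes, which is how
interchromosomal rearrangements surface in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import ContractError, ValidationError
from .genome import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    chrom_key,
    genes_overlapping,
    merge_intervals,
    orthologs_of,
    OrthologyMap,
)

__all__ = [
    "AlignmentSegment",
    "AlignmentSet",
    "PangenomeComparison",
    "read_alignments",
    "project_interval",
    "liftover_gene_sets",
]

SOURCE_TO_TARGET = "source_to_target"
TARGET_TO_SOURCE = "target_to_source"


@dataclass(frozen=True)
class AlignmentSegment:
    """An ungapped, length-preserving mapping between a source span and a
    target span, both half-open.  On the ``-`` strand the map reverses
    orientation: the first source base pairs with the last target base."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"segment strand must be + or -, got {self.strand!r}")
        if not (0 <= self.src_start < self.src_end):
            raise ValidationError(f"invalid source span [{self.src_start},{self.src_end})")
        if not (0 <= self.tgt_start < self.tgt_end):
            raise ValidationError(f"invalid target span [{self.tgt_start},{self.tgt_end})")
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValidationError(
                "ungapped segment must preserve length: "
                f"src {self.src_end - self.src_start} != tgt {self.tgt_end - self.tgt_start}"
            )

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    def map_span(self, start: int, end: int) -> tuple[str, int, int]:
        """Image of source subspan [start, end) (must lie inside the
        segment) under the segment's affine map."""
        if not (self.src_start <= start < end <= self.src_end):
            raise ContractError("subspan not contained in segment")
        if self.strand == "+":
            return (
                self.tgt_chrom,
                self.tgt_start + (start - self.src_start),
                self.tgt_start + (end - self.src_start),
            )
        return (
            self.tgt_chrom,
            self.tgt_end - (end - self.src_start),
            self.tgt_end - (start - self.src_start),
        )

    def inverted(self) -> "AlignmentSegment":
        return AlignmentSegment(
            src_chrom=self.tgt_chrom,
            src_start=self.tgt_start,
            src_end=self.tgt_end,
            tgt_chrom=self.src_chrom,
            tgt_start=self.src_start,
            tgt_end=self.src_end,
            strand=self.strand,
        )


def _check_disjoint(
    segments: list[AlignmentSegment], side: str
) -> None:
    """Verify no two segments overlap on the given side ('src'/'tgt')."""
    keyed = sorted(
        range(len(segments)),
        key=lambda i: (
            getattr(segments[i], f"{side}_chrom"),
            getattr(segments[i], f"{side}_start"),
        ),
    )
    offenders = []
    for a, b in zip(keyed, keyed[1:]):
        sa, sb = segments[a], segments[b]
        if getattr(sa, f"{side}_chrom") == getattr(sb, f"{side}_chrom") and getattr(
            sb, f"{side}_start"
        ) < getattr(sa, f"{side}_end"):
            offenders.append((a, b))
    if offenders:
        raise ValidationError(
            f"alignment is not one-to-one: segments overlap on the {side} side "
            f"(row pairs {offenders})"
        )


class AlignmentSet:
    """A validated one-to-one alignment between two genomes, indexed by
    source interval for fast projection."""

    def __init__(
        self,
        segments: list[AlignmentSegment],
        source_genome: str = "",
        target_genome: str = "",
    ) -> None:
        _check_disjoint(segments, "src")
        _check_disjoint(segments, "tgt")
        self.segments = list(segments)
        self.source_genome = source_genome
        self.target_genome = target_genome
        self._src_trees: dict[str, IntervalTree] = {}
        self._tgt_trees: dict[str, IntervalTree] = {}
        for seg in self.segments:
            self._src_trees.setdefault(chrom_key(seg.src_chrom), IntervalTree()).addi(
                seg.src_start, seg.src_end, seg
            )
            self._tgt_trees.setdefault(chrom_key(seg.tgt_chrom), IntervalTree()).addi(
                seg.tgt_start, seg.tgt_end, seg
            )

    def __len__(self) -> int:
        return len(self.segments)

    def segments_overlapping(
        self, interval: GenomicInterval, direction: str = SOURCE_TO_TARGET
    ) -> list[AlignmentSegment]:
        trees = self._src_trees if direction == SOURCE_TO_TARGET else self._tgt_trees
        tree = trees.get(chrom_key(interval.chrom))
        if tree is None:
            return []
        segs = [h.data for h in tree.overlap(interval.start, interval.end)]
        if direction == TARGET_TO_SOURCE:
            segs = [s.inverted() for s in segs]
        return sorted(segs, key=lambda s: (s.src_chrom, s.src_start))


def read_alignments(
    path, source_genome: str = "", target_genome: str = ""
) -> AlignmentSet:
    """Read an ungapped-segment TSV with columns
    ``src_chrom src_start src_end tgt_chrom tgt_start tgt_end strand``
    (0-based half-open).  A header row repeating those names is optional.
    Length preservation and the one-to-one invariant are enforced."""
    segments: list[AlignmentSegment] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "src_chrom":
                continue
            if len(parts) < 7:
                errors.append(f"line {lineno}: expected 7 columns")
                continue
            try:
                seg = AlignmentSegment(
                    src_chrom=parts[0],
                    src_start=int(parts[1]),
                    src_end=int(parts[2]),
                    tgt_chrom=parts[3],
                    tgt_start=int(parts[4]),
                    tgt_end=int(parts[5]),
                    strand=parts[6],
                )
            except (ValueError, ValidationError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            segments.append(seg)
    if errors:
        raise ValidationError("invalid alignment rows: " + "; ".join(errors))
    return AlignmentSet(segments, source_genome, target_genome)


def project_interval(
    interval: GenomicInterval,
    aln: AlignmentSet,
    direction: str = SOURCE_TO_TARGET,
) -> list[GenomicInterval]:
    """Project an interval through every alignment segment it intersects.

    Each segment contributes the affine image of its intersection with the
    query.  Images abutting on the same chromosome are merged; separate
    images (unaligned gaps, other chromosomes) are reported separately --
    bridging across unaligned sequence would fabricate lifted bases.
    An unknown chromosome yields an empty result with a warning.
    """
    if direction not in {SOURCE_TO_TARGET, TARGET_TO_SOURCE}:
        raise ContractError(f"unknown direction {direction!r}")
    trees = aln._src_trees if direction == SOURCE_TO_TARGET else aln._tgt_trees
    if chrom_key(interval.chrom) not in trees:
        warnings.warn(
            f"chromosome {interval.chrom!r} has no alignment coverage; "
            "empty projection"
        )
        return []
    out_genome = (
        aln.target_genome if direction == SOURCE_TO_TARGET else aln.source_genome
    )
    pieces: list[GenomicInterval] = []
    for seg in aln.segments_overlapping(interval, direction):
        lo = max(interval.start, seg.src_start)
        hi = min(interval.end, seg.src_end)
        if lo >= hi:
            continue
        chrom, t0, t1 = seg.map_span(lo, hi)
        pieces.append(GenomicInterval(out_genome, chrom, t0, t1))
    return merge_intervals(pieces)


@dataclass
class PangenomeComparison:
    """Partition of source/target interval gene sets by orthology.

    The three target-side categories are disjoint and exhaust the genes
    overlapping the lifted intervals:

    - ``common``: (source gene, target gene) ortholog pairs where both
      members lie inside their respective intervals;
    - ``ortholog_elsewhere``: target genes whose source ortholog exists
      but falls outside the input intervals -- candidates a
      reference-only analysis would have missed;
    - ``no_ortholog``: target genes with no ortholog group member in the
      source genome;
    - ``unique_to_source``: source interval genes with no ortholog among
      the target interval genes.
    """

    source_genes: list[GeneModel]
    target_genes: list[GeneModel]
    lifted_intervals: list[GenomicInterval]
    common: set[tuple[str, str]] = field(default_factory=set)
    ortholog_elsewhere: set[str] = field(default_factory=set)
    no_ortholog: set[str] = field(default_factory=set)
    unique_to_source: set[str] = field(default_factory=set)


def liftover_gene_sets(
    src_intervals: list[GenomicInterval],
    src_annot: GenomeAnnotation,
    tgt_annot: GenomeAnnotation,
    aln: AlignmentSet,
    orthology: OrthologyMap,
) -> PangenomeComparison:
    """Lift intervals onto the target genome and compare gene content.

    Mirrors the pangenome view of a GWAS/QTL locus: which target-genome
    genes correspond to reference genes in the locus, which are novel, and
    which reference genes have no counterpart in the lifted regions.
    """
    if aln.source_genome and src_annot.genome and aln.source_genome != src_annot.genome:
        raise ContractError("source annotation does not match alignment source genome")
    if aln.target_genome and tgt_annot.genome and aln.target_genome != tgt_annot.genome:
        raise ContractError("target annotation does not match alignment target genome")

    src_genes = genes_overlapping(src_intervals, src_annot)
    lifted: list[GenomicInterval] = []
    for iv in src_intervals:
        lifted.extend(project_interval(iv, aln, SOURCE_TO_TARGET))
    lifted = merge_intervals(lifted)
    tgt_genes = genes_overlapping(lifted, tgt_annot) if lifted else []

    comp = PangenomeComparison(
        source_genes=src_genes, target_genes=tgt_genes, lifted_intervals=lifted
    )
    src_ids = {g.gene_id for g in src_genes}
    tgt_ids = {g.gene_id for g in tgt_genes}
    src_genome = src_annot.genome
    tgt_genome = tgt_annot.genome

    for tg in tgt_genes:
        src_orths = orthologs_of(tg.gene_id, orthology, src_genome)
        if not src_orths:
            comp.no_ortholog.add(tg.gene_id)
        elif src_orths & src_ids:
            for sg in sorted(src_orths & src_ids):
                comp.common.add((sg, tg.gene_id))
        else:
            comp.ortholog_elsewhere.add(tg.gene_id)
    for sg in src_genes:
        tgt_orths = orthologs_of(sg.gene_id, orthology, tgt_genome)
        if not tgt_orths & tgt_ids:
            comp.unique_to_source.add(sg.gene_id)
    return comp
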