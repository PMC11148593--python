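"""Coordinate conventions, region parsing, gene models, and orthology.

All coordinates held in memory are 0-based half-open (BED arithmetic).
Region strings and GFF3 records use the 1-based fully-closed convention
that wet-lab papers and annotation files print; both are converted at the
parsing boundary and nowhere else.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .errors import ContractError, RegionParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "OrthologyMap",
    "parse_region",
    "format_region",
    "normalize_chrom",
    "chrom_key",
    "merge_intervals",
    "read_gff3",
    "read_bed",
    "read_orthogroups",
    "genes_overlapping",
    "orthologs_of",
]

_REGION_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*([0-9,]+)\s*-\s*([0-9,]+)\s*$")


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name: a leading case-insensitive ``chr``
    prefix is rewritten as ``Chr``; everything else is kept verbatim."""
    name = name.strip()
    if name[:3].lower() == "chr":
        return "Chr" + name[3:]
    return name


def chrom_key(name: str) -> str:
    """Comparison key for chromosome names: lowercase, ``chr`` prefix
    stripped.  ``Chr01``, ``chr01`` and ``01`` all collide; ``Chr01`` and
    ``Chr1`` deliberately do not (zero padding is annotation-specific)."""
    name = name.strip().lower()
    if name.startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open [start, end) span on a named chromosome.

    ``genome`` is a free-form assembly identifier ("" when unknown); two
    intervals are only comparable when their genomes match or either is
    unspecified.
    """

    genome: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            chrom_key(self.chrom) == chrom_key(other.chrom)
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (chrom_key(self.chrom), self.start, self.end)


def parse_region(text: str, genome: str = "") -> GenomicInterval:
    """Parse a printed region string like ``Chr01:1523,625-1770814``.

    Printed coordinates are 1-based fully closed; thousands separators
    (commas) are stripped.  The printed start must be strictly less than
    the printed end -- a ``5-5`` span is rejected as empty.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    chrom = normalize_chrom(m.group(1))
    try:
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
    except ValueError as exc:  # pragma: no cover - regex already numeric
        raise RegionParseError(f"nonnumeric bound in {text!r}") from exc
    if start1 < 1:
        raise RegionParseError(f"start must be >= 1 in {text!r}")
    if start1 >= end1:
        raise RegionParseError(f"empty span in {text!r}: start {start1} >= end {end1}")
    return GenomicInterval(genome=genome, chrom=chrom, start=start1 - 1, end=end1)


def format_region(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_region` on canonical strings
    (1-based fully closed, no thousands separators)."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge any that overlap or abut on the same
    chromosome.  Genome labels must agree (blank mixes with anything)."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and chrom_key(merged[-1].chrom) == chrom_key(iv.chrom)
            and iv.start <= merged[-1].end
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.genome, last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneModel:
    """A gene-level annotation record (children such as mRNA/CDS are not
    modelled; the analyses operate at gene-model granularity)."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "?"
    description: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "?"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeAnnotation:
    """Gene models of one genome, indexed for interval-overlap queries."""

    def __init__(
        self,
        genome: str,
        genes: Iterable[GeneModel],
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.genome = genome
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        sizes_by_key = {chrom_key(c): n for c, n in self.chrom_sizes.items()}
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene id {g.gene_id!r}")
            key = chrom_key(g.interval.chrom)
            size = sizes_by_key.get(key)
            if size is not None and g.interval.end > size:
                raise ValidationError(
                    f"gene {g.gene_id} extends past end of {g.interval.chrom} "
                    f"({g.interval.end} > {size})"
                )
            self.genes[g.gene_id] = g
            self._trees.setdefault(key, IntervalTree()).addi(
                g.interval.start, g.interval.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def query(self, interval: GenomicInterval) -> list[GeneModel]:
        """Genes sharing >= 1 bp with ``interval`` (half-open overlap)."""
        tree = self._trees.get(chrom_key(interval.chrom))
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted(
            (self.genes[h.data] for h in hits),
            key=lambda g: (g.interval.sort_key(), g.gene_id),
        )


def genes_overlapping(
    intervals: Iterable[GenomicInterval], annotation: GenomeAnnotation
) -> list[GeneModel]:
    """All gene models intersecting any input interval, deduplicated and
    sorted by (chromosome, start).  Touching intervals do not overlap."""
    seen: dict[str, GeneModel] = {}
    for iv in intervals:
        if iv.genome and annotation.genome and iv.genome != annotation.genome:
            raise ContractError(
                f"interval genome {iv.genome!r} does not match annotation "
                f"genome {annotation.genome!r}"
            )
        for g in annotation.query(iv):
            seen[g.gene_id] = g
    return sorted(seen.values(), key=lambda g: (g.interval.sort_key(), g.gene_id))


# ---------------------------------------------------------------------------
# File readers


def read_gff3(path, genome_id: str) -> GenomeAnnotation:
    """Read gene records (feature type ``gene``) from a GFF3 file.

    GFF3 is 1-based fully closed; records are converted to half-open
    internally.  Gene records lacking an ``ID`` attribute are skipped with
    a warning.  ``##sequence-region`` pragmas populate chromosome sizes.
    """
    from gffutils.iterators import DataIterator

    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    it = DataIterator(str(path))
    for feat in it:
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID")
        if not ids or not ids[0]:
            warnings.warn(
                f"gene record at {feat.seqid}:{feat.start}-{feat.end} has no ID "
                "attribute; skipped"
            )
            continue
        strand = feat.strand if feat.strand in {"+", "-"} else "?"
        desc = ""
        for key in ("description", "Note", "Name"):
            vals = feat.attributes.get(key)
            if vals:
                desc = vals[0]
                break
        genes.append(
            GeneModel(
                gene_id=ids[0],
                interval=GenomicInterval(
                    genome=genome_id,
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                ),
                strand=strand,
                description=desc,
            )
        )
    for line in getattr(it, "directives", []):
        parts = line.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_sizes[parts[1]] = int(parts[3])
    return GenomeAnnotation(genome_id, genes, chrom_sizes)


def read_bed(path, genome_id: str = "") -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, as BED is defined).

    Rows with ``start >= end`` are rejected with a warning; output is
    sorted by (chromosome, start)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}:{lineno}: fewer than 3 BED columns; skipped")
                continue
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                warnings.warn(f"{path}:{lineno}: nonnumeric coordinates; skipped")
                continue
            if start < 0 or start >= end:
                warnings.warn(
                    f"{path}:{lineno}: invalid span [{start},{end}); skipped"
                )
                continue
            out.append(GenomicInterval(genome_id, chrom, start, end))
    return sorted(out, key=GenomicInterval.sort_key)


# ---------------------------------------------------------------------------
# Orthology


@dataclass
class OrthologyMap:
    """Ortholog groups across genomes (one group id maps to member genes
    of several annotations; a gene belongs to at most one group)."""

    groups: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    by_gene: dict[str, str] = field(default_factory=dict)

    def add(self, group_id: str, genome: str, gene_id: str) -> None:
        prev = self.by_gene.get(gene_id)
        if prev is not None and prev != group_id:
            raise ValidationError(
                f"gene {gene_id!r} assigned to two ortholog groups "
                f"({prev!r}, {group_id!r})"
            )
        self.groups.setdefault(group_id, set()).add((genome, gene_id))
        self.by_gene[gene_id] = group_id

    def group_of(self, gene_id: str) -> str | None:
        return self.by_gene.get(gene_id)


def read_orthogroups(path) -> OrthologyMap:
    """Read a TSV of ``group_id<TAB>genome<TAB>gene_id`` rows."""
    omap = OrthologyMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}:{lineno}: expected 3 columns; skipped")
                continue
            omap.add(parts[0], parts[1], parts[2])
    return omap


def orthologs_of(gene_id: str, orthology: OrthologyMap, target_genome: str) -> set[str]:
    """Members of ``gene_id``'s ortholog group that belong to
    ``target_genome``.  Unmapped genes yield the empty set ("no known
    orthologs").  When a gene is queried against its own genome it is a
    member of its own group, which makes an identity lift-over report
    every gene as common with itself."""
    group_id = orthology.group_of(gene_id)
    if group_id is None:
        return set()
    return {
        g for (genome, g) in orthology.groups[group_id] if genome == target_genome
    }
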