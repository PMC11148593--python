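"""Literature-mined entity annotations: indexing and retrieval.

The input is the tabular output of an upstream named-entity-recognition
pipeline run over PubMed abstracts: one row per recognized entity with
its abstract (PubMed id), surface text, entity type, and -- for gene
entities -- a normalized gene accession.  This module builds in-memory
indexes for two queries: which genes co-occur (same abstract) with a
trait/chemical/species mention, and which abstracts mention a gene.

Matching is case-insensitive substring matching on surface text; gene to
query linkage is same-abstract co-occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ContractError

__all__ = [
    "ENTITY_TYPES",
    "EntityAnnotation",
    "AnnotationIndex",
    "read_annotations",
    "write_annotations",
    "genes_for_query",
    "literature_for_genes",
]

ENTITY_TYPES = {"gene", "species", "chemical", "disease/phenotype"}

_TYPE_ALIASES = {
    "phenotype": "disease/phenotype",
    "disease": "disease/phenotype",
}


def canonical_etype(etype: str) -> str:
    etype = etype.strip().lower()
    etype = _TYPE_ALIASES.get(etype, etype)
    if etype not in ENTITY_TYPES:
        raise ContractError(f"unknown entity type {etype!r}")
    return etype


@dataclass(frozen=True)
class EntityAnnotation:
    pmid: str
    surface: str
    etype: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ContractError("annotation pmid must be nonempty")
        if self.etype not in ENTITY_TYPES:
            raise ContractError(f"unknown entity type {self.etype!r}")


@dataclass
class AnnotationIndex:
    """Indexes kept mutually consistent with the underlying table."""

    annotations: list[EntityAnnotation] = field(default_factory=list)
    by_pmid: dict[str, list[EntityAnnotation]] = field(default_factory=dict)
    by_entity: dict[str, list[EntityAnnotation]] = field(default_factory=dict)
    by_gene: dict[str, set[str]] = field(default_factory=dict)

    def add(self, ann: EntityAnnotation) -> None:
        self.annotations.append(ann)
        self.by_pmid.setdefault(ann.pmid, []).append(ann)
        self.by_entity.setdefault(ann.surface.lower(), []).append(ann)
        if ann.etype == "gene" and ann.gene_id:
            self.by_gene.setdefault(ann.gene_id, set()).add(ann.pmid)

    def __len__(self) -> int:
        return len(self.annotations)


def read_annotations(path) -> AnnotationIndex:
    """Read a TSV of ``pmid<TAB>surface<TAB>etype<TAB>gene_id`` rows;
    rows with an unknown entity type are rejected with a warning."""
    index = AnnotationIndex()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}:{lineno}: expected >= 3 columns; skipped")
                continue
            pmid, surface, etype = parts[0], parts[1], parts[2]
            gene_id = parts[3] if len(parts) > 3 else ""
            try:
                etype = canonical_etype(etype)
            except ContractError:
                warnings.warn(f"{path}:{lineno}: unknown entity type {etype!r}; rejected")
                continue
            index.add(EntityAnnotation(pmid, surface, etype, gene_id))
    return index


def write_annotations(index: AnnotationIndex, path) -> None:
    """Serialize back to the same TSV format (round-trip exact)."""
    with open(path, "w") as fh:
        for ann in index.annotations:
            fh.write(f"{ann.pmid}\t{ann.surface}\t{ann.etype}\t{ann.gene_id}\n")


def genes_for_query(
    index: AnnotationIndex,
    query: str,
    etypes: Iterable[str] | None = None,
) -> set[str]:
    """Gene accessions co-occurring (same abstract) with entity surfaces
    matching ``query``.

    The query is matched case-insensitively as a substring of surfaces
    whose type is in ``etypes`` (all four types when unspecified); the
    genes returned come from gene-type annotations in the matched
    abstracts."""
    wanted = (
        set(ENTITY_TYPES)
        if etypes is None
        else {canonical_etype(t) for t in etypes}
    )
    needle = query.strip().lower()
    if not needle:
        return set()
    pmids: set[str] = set()
    for surface_lc, anns in index.by_entity.items():
        if needle in surface_lc:
            pmids.update(a.pmid for a in anns if a.etype in wanted)
    genes: set[str] = set()
    for pmid in pmids:
        for ann in index.by_pmid.get(pmid, []):
            if ann.etype == "gene" and ann.gene_id:
                genes.add(ann.gene_id)
    return genes


def literature_for_genes(
    index: AnnotationIndex, genes: Iterable[str]
) -> dict[str, set[str]]:
    """PubMed ids per gene; unindexed genes map to empty sets."""
    return {g: set(index.by_gene.get(g, set())) for g in genes}
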