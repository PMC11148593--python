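"""Per-gene prioritization summary.

Collapses the individual analyses into one table with a row per
candidate gene: how many pathways contain it, how many distinct enriched
terms/pathways annotate the modules it belongs to, how many articles
mention it, which modules it sits in, and whether it survived lift-over
into each target genome.  Multi-column stable sorting lets the caller
rank genes by whichever criteria they trust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .community import Module
from .enrichment import EnrichmentResult
from .errors import ContractError

__all__ = ["GeneSummaryRow", "build_summary", "sort_summary", "summary_frame"]

SORTABLE_COLUMNS = {
    "gene_id",
    "n_pathways",
    "n_module_terms",
    "n_articles",
    "n_modules",
}


@dataclass(frozen=True)
class GeneSummaryRow:
    gene_id: str
    n_pathways: int
    n_module_terms: int
    n_articles: int
    module_ids: tuple[int, ...]
    in_lifted_target: Mapping[str, bool] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)


def build_summary(
    genes: Iterable[str],
    modules: Sequence[Module],
    module_enrichment: Sequence[EnrichmentResult],
    ora_results: Mapping[int, Sequence[EnrichmentResult]],
    pathway_membership: Mapping[str, Iterable[str]],
    literature: Mapping[str, Iterable[str]],
    lifted_presence: Mapping[str, Iterable[str]] | None = None,
) -> list[GeneSummaryRow]:
    """One row per candidate gene.

    ``ora_results`` maps a module id to the term/pathway enrichment
    results computed for that module; a gene belonging to several modules
    counts each enriched term once (deduplicated by term id).
    ``pathway_membership`` maps pathway id -> gene set;
    ``literature`` maps gene -> article ids; ``lifted_presence`` maps
    target genome -> genes with an ortholog in the lifted intervals.
    """
    genes = list(dict.fromkeys(genes))
    module_by_id = {m.module_id: m for m in modules}
    unknown = set(ora_results) - set(module_by_id)
    if unknown:
        raise ContractError(
            f"ora_results reference unknown module ids: {sorted(unknown)}"
        )
    enr_by_id = {int(r.unit_id): r for r in module_enrichment}
    unknown = set(enr_by_id) - set(module_by_id)
    if unknown:
        raise ContractError(
            f"module enrichment references unknown module ids: {sorted(unknown)}"
        )

    rows: list[GeneSummaryRow] = []
    lifted_presence = lifted_presence or {}
    lifted_sets = {g: set(v) for g, v in lifted_presence.items()}
    for gene in genes:
        mods = sorted(
            m.module_id for m in modules if gene in m.genes
        )
        terms: set[str] = set()
        for mid in mods:
            for res in ora_results.get(mid, ()):  # only enriched terms count
                if res.enriched:
                    terms.add(res.unit_id)
        n_pathways = sum(
            1 for _, members in pathway_membership.items() if gene in set(members)
        )
        n_articles = len(set(literature.get(gene, ())))
        rows.append(
            GeneSummaryRow(
                gene_id=gene,
                n_pathways=n_pathways,
                n_module_terms=len(terms),
                n_articles=n_articles,
                module_ids=tuple(mods),
                in_lifted_target={
                    genome: gene in members for genome, members in lifted_sets.items()
                },
            )
        )
    return rows


def sort_summary(
    rows: Sequence[GeneSummaryRow],
    keys: Sequence[tuple[str, str]],
) -> list[GeneSummaryRow]:
    """Stable lexicographic sort over (column, direction) pairs, where
    direction is ``asc`` or ``desc``.  An empty key list preserves input
    order; an unknown column raises."""
    out = list(rows)
    for column, direction in reversed(list(keys)):
        if column not in SORTABLE_COLUMNS:
            raise ContractError(f"unknown sort column {column!r}")
        if direction not in {"asc", "desc"}:
            raise ContractError(f"sort direction must be asc/desc, got {direction!r}")
        out.sort(key=lambda r: getattr(r, column), reverse=(direction == "desc"))
    return out


def summary_frame(rows: Sequence[GeneSummaryRow]) -> pd.DataFrame:
    """Tabular form for TSV/JSON export."""
    targets = sorted({g for r in rows for g in r.in_lifted_target})
    records = []
    for r in rows:
        rec = {
            "gene_id": r.gene_id,
            "n_pathways": r.n_pathways,
            "n_module_terms": r.n_module_terms,
            "n_articles": r.n_articles,
            "n_modules": r.n_modules,
            "module_ids": ",".join(str(m) for m in r.module_ids),
        }
        for t in targets:
            rec[f"in_{t}"] = bool(r.in_lifted_target.get(t, False))
        records.append(rec)
    return pd.DataFrame.from_records(records)
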