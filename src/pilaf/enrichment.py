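"""Module-enrichment testing and overrepresentation analysis (ORA).

Both analyses reduce to the same machinery: a 2x2 contingency table whose
columns split a background gene universe into implicated (query) versus
not, and whose rows split it into unit membership (a coexpression module,
an ontology term, a pathway) versus not.  Significance is the one-tailed
Fisher exact test (upper hypergeometric tail), and false-discovery rate
is controlled by Benjamini-Hochberg across the units of one analysis
family.  A unit is called enriched when its adjusted P falls below 0.05.

For module enrichment the background is the union of genes across all
detected modules; implicated genes outside that union are dropped before
tabulation (adding them would break the 2x2 marginals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import Module
from .errors import ContractError

__all__ = [
    "ContingencyTable",
    "AnnotationSet",
    "EnrichmentResult",
    "fisher_exact_greater",
    "bh_adjust",
    "enrich_modules",
    "ora",
    "read_gene_sets",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

NAMESPACES = {"gene_ontology", "trait_ontology", "plant_ontology", "pathway"}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one tested unit.

    a: implicated and in unit        b: not implicated, in unit
    c: implicated, not in unit       d: not implicated, not in unit
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set mapping for one namespace (an ontology or a
    pathway database)."""

    namespace: str
    terms: Mapping[str, tuple[str, frozenset]]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ContractError(
                f"namespace {self.namespace!r} not one of {sorted(NAMESPACES)}"
            )
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ContractError(f"term {term_id!r} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    enriched: bool
    description: str = ""


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-tailed (greater) Fisher exact P: P(X >= a) for
    X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b).

    Evaluated through the survival function of the hypergeometric
    distribution, which works in log space and is exact to double
    precision for the table sizes used here.
    """
    N = table.n
    K = table.a + table.c
    n = table.a + table.b
    if table.a == 0:
        return 1.0
    p = float(stats.hypergeom.sf(table.a - 1, N, K, n))
    return min(1.0, max(0.0, p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ContractError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _test_family(
    units: list[tuple[str, str, ContingencyTable]], alpha: float
) -> list[EnrichmentResult]:
    raws = [fisher_exact_greater(t) for _, _, t in units]
    adjs = bh_adjust(raws)
    return [
        EnrichmentResult(
            unit_id=uid,
            table=t,
            p_raw=praw,
            p_adj=padj,
            enriched=bool(padj < alpha),
            description=desc,
        )
        for (uid, desc, t), praw, padj in zip(units, raws, adjs)
    ]


def enrich_modules(
    modules: Sequence[Module],
    implicated: Iterable[str],
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """Test every detected module for overrepresentation of implicated
    genes.  The background is the union of genes across the detected
    modules; implicated genes outside it are dropped (count logged)."""
    if not modules:
        raise ContractError("no modules to test")
    background: set[str] = set().union(*(m.genes for m in modules))
    implicated = set(implicated)
    dropped = len(implicated - background)
    if dropped:
        logger.info(
            "%d implicated gene(s) outside the module background were dropped",
            dropped,
        )
    impl = implicated & background
    N = len(background)
    units = []
    for m in modules:
        a = len(impl & m.genes)
        b = len(m.genes) - a
        c = len(impl) - a
        d = N - a - b - c
        units.append((str(m.module_id), "", ContingencyTable(a, b, c, d)))
    return _test_family(units, alpha)


def ora(
    query: Iterable[str],
    annotations: AnnotationSet,
    background: Iterable[str],
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """Overrepresentation analysis of ``query`` against one namespace.

    Terms sharing no gene with the query are excluded from testing (and
    from the BH family).  Term gene sets are clipped to the background
    before tabulation."""
    query = set(query)
    background = set(background)
    offenders = query - background
    if offenders:
        raise ContractError(
            f"query genes outside the background: {sorted(offenders)[:10]}"
        )
    N = len(background)
    units = []
    for term_id in sorted(annotations.terms):
        desc, genes = annotations.terms[term_id]
        tg = genes & background
        a = len(query & tg)
        if a == 0:
            continue
        b = len(tg) - a
        c = len(query) - a
        d = N - a - b - c
        units.append((term_id, desc, ContingencyTable(a, b, c, d)))
    return _test_family(units, alpha)


def read_gene_sets(path, namespace: str) -> AnnotationSet:
    """Read GMT-style gene sets:
    ``term_id<TAB>description<TAB>gene1,gene2,...`` per line."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ContractError(f"{path}:{lineno}: expected 3 columns")
            genes = frozenset(g for g in parts[2].split(",") if g)
            if not genes:
                raise ContractError(f"{path}:{lineno}: empty gene set")
            terms[parts[0]] = (parts[1], genes)
    return AnnotationSet(namespace=namespace, terms=terms)
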