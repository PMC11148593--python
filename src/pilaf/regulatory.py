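"""Transcription-factor binding-site overlap enrichment.

Noncoding trait-associated variants may act by perturbing regulatory
elements, so a natural question is whether the input intervals overlap a
TF's predicted binding sites more often than chance placement would.  The
statistic per TF is site-centric: the number of binding-site intervals
intersecting at least one query interval.  The null distribution comes
from a chromosome-aware shuffle -- each query interval is independently
repositioned uniformly within its own chromosome with its length
preserved -- and significance uses the add-one Monte-Carlo estimator

    p = (1 + #{shuffles with count >= observed}) / (1 + n_perm),

so p can never drop below 1/(n_perm + 1).  TFs with zero observed overlap
are excluded from testing; Benjamini-Hochberg controls FDR across the
tested TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import ALPHA, bh_adjust
from .errors import ContractError
from .genome import GenomicInterval, chrom_key, merge_intervals, read_bed

__all__ = [
    "TFBSCollection",
    "OverlapTestResult",
    "count_overlaps",
    "shuffle_intervals",
    "tfbs_enrichment",
    "load_tfbs_dir",
    "load_tfbs_bed",
    "read_chrom_sizes",
]

PREDICTION_METHODS = {"motif-scan", "motif+conservation", "FunTFBS"}
PREDICTION_SCOPES = {"whole-genome", "promoter"}


@dataclass(frozen=True)
class TFBSCollection:
    """Per-TF binding-site intervals plus the provenance of the
    prediction set (how sites were predicted, and against what scope;
    promoter scope conventionally means -500/+100 bp around the TSS)."""

    sites: Mapping[str, tuple[GenomicInterval, ...]]
    method: str = "motif-scan"
    scope: str = "whole-genome"

    def __post_init__(self) -> None:
        if self.method not in PREDICTION_METHODS:
            raise ContractError(f"unknown prediction method {self.method!r}")
        if self.scope not in PREDICTION_SCOPES:
            raise ContractError(f"unknown prediction scope {self.scope!r}")

    def tfs(self) -> list[str]:
        return sorted(self.sites)


@dataclass(frozen=True)
class OverlapTestResult:
    tf: str
    observed: int
    null_ge: int
    n_perm: int
    p_raw: float
    p_adj: float
    enriched: bool


def count_overlaps(
    query: Sequence[GenomicInterval], sites: Sequence[GenomicInterval]
) -> int:
    """Number of site intervals sharing >= 1 bp with at least one query
    interval (half-open convention; each site counted once)."""
    if not query or not sites:
        return 0
    merged = merge_intervals(query)
    q_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for key in {chrom_key(iv.chrom) for iv in merged}:
        ivs = [iv for iv in merged if chrom_key(iv.chrom) == key]
        q_by_chrom[key] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    total = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in sites:
        by_chrom.setdefault(chrom_key(s.chrom), []).append(s)
    for key, chrom_sites in by_chrom.items():
        if key not in q_by_chrom:
            continue
        qs, qe = q_by_chrom[key]
        s_start = np.array([s.start for s in chrom_sites])
        s_end = np.array([s.end for s in chrom_sites])
        # merged query intervals are disjoint and sorted: a site overlaps
        # one iff the first query ending after the site's start begins
        # before the site's end
        idx = np.searchsorted(qe, s_start, side="right")
        valid = idx < len(qs)
        hit = valid & (qs[np.minimum(idx, len(qs) - 1)] < s_end)
        total += int(hit.sum())
    return total


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


def shuffle_intervals(
    query: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator | int,
) -> list[GenomicInterval]:
    """Reposition each interval uniformly within its own chromosome,
    preserving length.  No cross-chromosome moves; deterministic given
    the generator state / seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sizes_by_key = {chrom_key(c): n for c, n in chrom_sizes.items()}
    out = []
    for iv in query:
        size = sizes_by_key.get(chrom_key(iv.chrom))
        if size is None:
            raise ContractError(f"no size known for chromosome {iv.chrom!r}")
        if iv.length > size:
            raise ContractError(
                f"interval length {iv.length} exceeds chromosome "
                f"{iv.chrom!r} length {size}"
            )
        start = int(rng.integers(0, size - iv.length + 1))
        out.append(GenomicInterval(iv.genome, iv.chrom, start, start + iv.length))
    return out


def tfbs_enrichment(
    query: Sequence[GenomicInterval],
    collection: TFBSCollection,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = ALPHA,
) -> list[OverlapTestResult]:
    """Permutation test of binding-site overlap for every TF.

    One pool of ``n_perm`` shuffled query replicates is shared across
    TFs, which keeps the procedure O(n_perm) in shuffles and makes the
    whole run deterministic given (inputs, n_perm, seed)."""
    if n_perm < 1:
        raise ContractError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed))
    )
    tested: list[tuple[str, int]] = []
    for tf in collection.tfs():
        obs = count_overlaps(query, collection.sites[tf])
        if obs > 0:
            tested.append((tf, obs))
    if not tested:
        return []
    null_ge = {tf: 0 for tf, _ in tested}
    for _ in range(n_perm):
        shuffled = shuffle_intervals(query, chrom_sizes, rng)
        for tf, obs in tested:
            if count_overlaps(shuffled, collection.sites[tf]) >= obs:
                null_ge[tf] += 1
    raws = [(1 + null_ge[tf]) / (1 + n_perm) for tf, _ in tested]
    adjs = bh_adjust(raws)
    results = [
        OverlapTestResult(
            tf=tf,
            observed=obs,
            null_ge=null_ge[tf],
            n_perm=n_perm,
            p_raw=praw,
            p_adj=padj,
            enriched=bool(padj < alpha),
        )
        for (tf, obs), praw, padj in zip(tested, raws, adjs)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.tf))


def load_tfbs_dir(
    directory,
    genome_id: str = "",
    method: str = "motif-scan",
    scope: str = "whole-genome",
) -> TFBSCollection:
    """Load per-TF BED files from a directory; the TF name is the file
    stem (``ERF.bed`` -> ``ERF``)."""
    directory = Path(directory)
    sites: dict[str, tuple[GenomicInterval, ...]] = {}
    for bed in sorted(directory.glob("*.bed")):
        ivs = read_bed(bed, genome_id)
        if ivs:
            sites[bed.stem] = tuple(ivs)
    return TFBSCollection(sites=sites, method=method, scope=scope)


def load_tfbs_bed(
    path,
    genome_id: str = "",
    method: str = "motif-scan",
    scope: str = "whole-genome",
) -> TFBSCollection:
    """Load a single BED file whose 4th column names the TF."""
    per_tf: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ContractError(f"{path}:{lineno}: need 4 columns (chrom, start, end, tf)")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                continue
            per_tf.setdefault(parts[3], []).append(
                GenomicInterval(genome_id, parts[0], start, end)
            )
    sites = {
        tf: tuple(sorted(ivs, key=GenomicInterval.sort_key))
        for tf, ivs in per_tf.items()
    }
    return TFBSCollection(sites=sites, method=method, scope=scope)
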