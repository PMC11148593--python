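"""Synthetic fixture bundles for end-to-end testing.

Generates a pair of toy genomes with a one-to-one alignment, gene
annotations, ortholog groups, a weighted coexpression network with one
planted dense module, ontology/pathway gene sets in which the planted
module is enriched for a designated term, per-TF binding-site BED files
with one TF concentrated in the query region, and a literature-mined
annotation table -- every format the analysis readers consume, plus a
manifest recording the planted ground truth so tests are self-checking.

The layout is deliberately schematic rather than biologically realistic:
genes sit on a regular grid inside alignment segments, which makes the
expected lift-over partition exactly computable at construction time.
The planted signals (module, enriched term, enriched TF, query/trait
co-occurrence) are the only structure; everything else is uniform noise
from a seeded generator, so a bundle is byte-reproducible from its spec.

Construction outline (defaults):

- Each source chromosome is tiled with 40 kb alignment segments
  separated by 2 kb unaligned gaps; the target copy of each segment is
  shifted by +30 kb on the corresponding target chromosome.  One segment
  inside the first query interval is relocated to a different target
  chromosome (a rearrangement), and the segment containing the second
  query interval is deleted from the alignment.
- Query interval 1 covers seven consecutive genes, interval 2 three; the
  ten overlapped genes are the "implicated" set.  Six of them plus six
  other genes form the planted module.
- Two extra target genes inside the lifted region pair with source genes
  *outside* the query (orthologs elsewhere); three extra target genes
  have no ortholog group at all; the three deleted-segment source genes
  have no target counterpart (unique to source).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError
from .genome import GenomicInterval, format_region

__all__ = ["FixtureSpec", "simulate_bundle"]

SEG_PERIOD = 42_000
SEG_LEN = 40_000
GENE_OFFSETS = (4_000, 17_000, 30_000)
TGT_SHIFT = 30_000
TGT_EXTRA_LEN = 200_000
SITE_LEN = 20
EXTRA_GENE_LEN = 1_500
TF_NAMES = ("ARF", "bZIP", "CAMTA", "ERF", "FAR1", "HSF", "MYB", "WRKY")

SOURCE_GENOME = "REF"
TARGET_GENOME = "ALT"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic bundle.  Defaults give a 100-gene genome
    pair and a 100-node network with a 12-gene planted module (within
    edge probability 0.9, unit weights) on an Erdos-Renyi background
    (edge probability 0.05, uniform weights in [0.1, 1])."""

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 100
    n_rearrangements: int = 1
    planted_module_size: int = 12
    planted_within_p: float = 0.9
    background_edge_p: float = 0.05
    n_tfs: int = 8
    planted_tf: str = "ERF"
    n_abstracts: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chroms",
            "chrom_len",
            "n_genes",
            "planted_module_size",
            "n_tfs",
            "n_abstracts",
        ):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if self.n_rearrangements < 0:
            raise ContractError("n_rearrangements must be >= 0")
        for name in ("planted_within_p", "background_edge_p"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ContractError(f"{name} must lie in [0, 1]")
        if self.n_chroms < 2 and self.n_rearrangements > 0:
            raise ContractError("rearrangements need at least 2 chromosomes")
        if self.n_genes // self.n_chroms < 36:
            raise ContractError(
                "need at least 36 genes per chromosome to lay out the query"
            )
        if self.n_tfs > len(TF_NAMES):
            raise ContractError(f"at most {len(TF_NAMES)} TFs supported")
        if self.planted_tf not in TF_NAMES[: self.n_tfs]:
            raise ContractError(
                f"planted_tf must be one of {TF_NAMES[: self.n_tfs]}"
            )


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


def _src_chrom(i: int) -> str:
    return f"Chr{i + 1:02d}"


def _tgt_chrom(i: int) -> str:
    return f"tChr{i + 1:02d}"


def _write_gff3(path: Path, genes: list[_Gene], chrom_sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {chrom_sizes[chrom]}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tpilaf_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _free_slots(
    lo: int,
    hi: int,
    occupied: list[tuple[int, int]],
    count: int,
    length: int = EXTRA_GENE_LEN,
    margin: int = 500,
) -> list[tuple[int, int]]:
    """Up to ``count`` disjoint [s, s+length) slots inside [lo, hi)
    avoiding ``occupied`` spans with ``margin`` clearance."""
    slots: list[tuple[int, int]] = []
    occ = sorted((s, e) for s, e in occupied if e > lo and s < hi)
    cursor = lo + margin
    for s, e in occ + [(hi, hi)]:
        while cursor + length + margin <= s and len(slots) < count:
            slots.append((cursor, cursor + length))
            cursor += length + margin
        cursor = max(cursor, e + margin)
        if len(slots) >= count:
            break
    return slots


def simulate_bundle(spec: FixtureSpec, out_dir) -> dict:
    """Write the full fixture bundle into ``out_dir`` and return the
    manifest (also stored as ``manifest.json``).  Deterministic given
    ``spec.rng_seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    per_chrom = spec.n_genes // spec.n_chroms
    n_segs = 0
    while n_segs * SEG_PERIOD + SEG_LEN <= spec.chrom_len:
        n_segs += 1
    if (per_chrom - 1) // 3 >= n_segs:
        raise ContractError("chromosome too short for the requested gene count")

    src_sizes = {_src_chrom(c): spec.chrom_len for c in range(spec.n_chroms)}
    tgt_sizes = {
        _tgt_chrom(c): spec.chrom_len + TGT_EXTRA_LEN for c in range(spec.n_chroms)
    }

    # --- alignment segments -------------------------------------------------
    # segment record: (src_chrom, s0, s1, tgt_chrom, t0, t1, strand)
    rearranged_segs = {(0, 12 // 3)}  # segment of query gene 12 on chrom 1
    extra_rears = [(0, 6), (0, 8)][: max(0, spec.n_rearrangements - 1)]
    rearranged_segs.update(extra_rears)
    if spec.n_rearrangements == 0:
        rearranged_segs = set()
    deleted_segs = {(0, 30 // 3)}  # segment of query genes 30-32 on chrom 1
    reverse_segs = {(c, 15 - 4 * c) for c in range(spec.n_chroms)}

    segments: list[tuple[str, int, int, str, int, int, str]] = []
    seg_map: dict[tuple[int, int], tuple[str, int, int, str, int, int, str]] = {}
    rear_base = spec.chrom_len + 50_000
    rear_idx = 0
    for c in range(spec.n_chroms):
        for k in range(n_segs):
            if (c, k) in deleted_segs:
                continue
            s0 = k * SEG_PERIOD
            s1 = s0 + SEG_LEN
            strand = "-" if (c, k) in reverse_segs else "+"
            if (c, k) in rearranged_segs:
                tchrom = _tgt_chrom((c + 1) % spec.n_chroms)
                t0 = rear_base + rear_idx * (SEG_LEN + 5_000)
                rear_idx += 1
            else:
                tchrom = _tgt_chrom(c)
                t0 = s0 + TGT_SHIFT
            seg = (_src_chrom(c), s0, s1, tchrom, t0, t0 + SEG_LEN, strand)
            segments.append(seg)
            seg_map[(c, k)] = seg

    # --- source genes -------------------------------------------------------
    src_genes: list[_Gene] = []
    gene_at: dict[tuple[int, int], _Gene] = {}
    gid = 0
    for c in range(spec.n_chroms):
        for i in range(per_chrom):
            seg_k = i // 3
            start = seg_k * SEG_PERIOD + GENE_OFFSETS[i % 3]
            length = 3_000 + (gid * 977) % 4_000
            g = _Gene(
                gene_id=f"S{c + 1:02d}G{i:03d}",
                chrom=_src_chrom(c),
                start=start,
                end=start + length,
                strand="+" if i % 2 == 0 else "-",
            )
            src_genes.append(g)
            gene_at[(c, i)] = g
            gid += 1

    # --- query intervals and implicated genes -------------------------------
    q1_genes = [gene_at[(0, i)] for i in range(10, 17)]
    q2_genes = [gene_at[(0, i)] for i in range(30, 33)]
    interval1 = GenomicInterval(
        SOURCE_GENOME, "Chr01", q1_genes[0].start - 500, q1_genes[-1].end + 500
    )
    interval2 = GenomicInterval(
        SOURCE_GENOME, "Chr01", q2_genes[0].start - 500, q2_genes[-1].end + 500
    )
    query = [interval1, interval2]
    implicated = [g.gene_id for g in q1_genes + q2_genes]

    # --- planted module -----------------------------------------------------
    planted_from_query = [g.gene_id for g in q1_genes[:6]]
    oe_partner_ids = {gene_at[(0, 20)].gene_id, gene_at[(0, 21)].gene_id}
    pool = sorted(
        g.gene_id
        for g in src_genes
        if g.gene_id not in set(implicated) | oe_partner_ids
    )
    n_fill = spec.planted_module_size - len(planted_from_query)
    if n_fill < 0:
        raise ContractError("planted_module_size must be >= 6")
    fill = [str(x) for x in rng.choice(pool, size=n_fill, replace=False)]
    planted_module = sorted(planted_from_query + fill)

    # --- target genes and orthogroups ---------------------------------------
    def project(c: int, k: int, start: int, end: int) -> tuple[str, int, int, str]:
        chrom_s, s0, s1, tchrom, t0, t1, strand = seg_map[(c, k)]
        if strand == "+":
            return tchrom, t0 + (start - s0), t0 + (end - s0), strand
        return tchrom, t1 - (end - s0), t1 - (start - s0), strand

    tgt_genes: list[_Gene] = []
    ortho_rows: list[tuple[str, str, str]] = []
    ogi_of: dict[str, str] = {}
    ogi_counter = 0
    deleted_gene_ids: list[str] = []
    for c in range(spec.n_chroms):
        for i in range(per_chrom):
            g = gene_at[(c, i)]
            seg_k = i // 3
            if (c, seg_k) in deleted_segs:
                deleted_gene_ids.append(g.gene_id)
                continue
            tchrom, t0, t1, seg_strand = project(c, seg_k, g.start, g.end)
            tg = _Gene(
                gene_id="T" + g.gene_id[1:],
                chrom=tchrom,
                start=t0,
                end=t1,
                strand=g.strand if seg_strand == "+" else ("-" if g.strand == "+" else "+"),
            )
            tgt_genes.append(tg)
            ogi_counter += 1
            ogi = f"OGI:{ogi_counter:06d}"
            ogi_of[g.gene_id] = ogi
            ortho_rows.append((ogi, SOURCE_GENOME, g.gene_id))
            ortho_rows.append((ogi, TARGET_GENOME, tg.gene_id))

    # lifted pieces of interval 1 (by construction; interval 2 is deleted)
    pieces: list[tuple[str, int, int, bool]] = []
    for k in range(10 // 3, 16 // 3 + 1):
        if (0, k) not in seg_map:
            continue
        s0, s1 = k * SEG_PERIOD, k * SEG_PERIOD + SEG_LEN
        lo, hi = max(interval1.start, s0), min(interval1.end, s1)
        if lo >= hi:
            continue
        tchrom, t0, t1, _ = project(0, k, lo, hi)
        pieces.append((tchrom, t0, t1, (0, k) in rearranged_segs))
    pieces.sort(key=lambda p: (p[3], p[0], p[1]))  # rearranged pieces last

    occupied: dict[str, list[tuple[int, int]]] = {}
    for tg in tgt_genes:
        occupied.setdefault(tg.chrom, []).append((tg.start, tg.end))

    def take_slots(piece_order: list[tuple[str, int, int, bool]], count: int):
        got: list[tuple[str, int, int]] = []
        for tchrom, lo, hi, _ in piece_order:
            for s, e in _free_slots(lo, hi, occupied.get(tchrom, []), count - len(got)):
                got.append((tchrom, s, e))
                occupied.setdefault(tchrom, []).append((s, e))
            if len(got) >= count:
                break
        if len(got) < count:
            raise ContractError("could not place extra target genes in lifted region")
        return got

    oe_extras: list[_Gene] = []
    for j, (tchrom, s, e) in enumerate(take_slots(pieces, 2), 1):
        oe_extras.append(_Gene(f"TOE{j:03d}", tchrom, s, e, "+"))
    no_extras: list[_Gene] = []
    for j, (tchrom, s, e) in enumerate(take_slots(list(reversed(pieces)), 3), 1):
        no_extras.append(_Gene(f"TNO{j:03d}", tchrom, s, e, "+"))
    tgt_genes.extend(oe_extras + no_extras)

    oe_partners = [gene_at[(0, 20)], gene_at[(0, 21)]]
    for extra, partner in zip(oe_extras, oe_partners):
        ortho_rows.append((ogi_of[partner.gene_id], TARGET_GENOME, extra.gene_id))

    # --- network ------------------------------------------------------------
    node_ids = sorted(g.gene_id for g in src_genes)
    planted_set = set(planted_module)
    edges: list[tuple[str, str, float]] = []
    for idx_a in range(len(node_ids)):
        for idx_b in range(idx_a + 1, len(node_ids)):
            a, b = node_ids[idx_a], node_ids[idx_b]
            if a in planted_set and b in planted_set:
                if rng.random() < spec.planted_within_p:
                    edges.append((a, b, 1.0))
            elif rng.random() < spec.background_edge_p:
                edges.append((a, b, round(0.1 + 0.9 * rng.random(), 6)))

    # --- ontology / pathway gene sets ---------------------------------------
    planted_term = "GO:1000001"
    term_rows: list[tuple[str, str, list[str]]] = [
        (
            planted_term,
            "seed dormancy and germination process",
            sorted(
                set(planted_module[:10])
                | set(rng.choice(node_ids, size=2, replace=False))
            ),
        )
    ]
    for t in range(2, 11):
        size = int(rng.integers(5, 16))
        term_rows.append(
            (
                f"GO:{1000000 + t}",
                f"background process {t}",
                sorted(rng.choice(node_ids, size=size, replace=False)),
            )
        )
    planted_pathway = "PW:0001"
    pathway_rows: list[tuple[str, str, list[str]]] = [
        (
            planted_pathway,
            "starch and sucrose metabolism",
            sorted(
                set(planted_module[:8])
                | set(rng.choice(node_ids, size=4, replace=False))
            ),
        )
    ]
    for t in range(2, 7):
        size = int(rng.integers(8, 21))
        pathway_rows.append(
            (
                f"PW:{t:04d}",
                f"background pathway {t}",
                sorted(rng.choice(node_ids, size=size, replace=False)),
            )
        )

    # --- TF binding sites ----------------------------------------------------
    chrom_names = sorted(src_sizes)
    chrom_lens = np.array([src_sizes[c] for c in chrom_names], dtype=float)
    chrom_probs = chrom_lens / chrom_lens.sum()
    q_lens = np.array([iv.length for iv in query], dtype=float)
    q_probs = q_lens / q_lens.sum()

    def genome_wide_sites(n: int) -> list[tuple[str, int, int]]:
        picks = rng.choice(len(chrom_names), size=n, p=chrom_probs)
        sites = []
        for ci in picks:
            chrom = chrom_names[ci]
            start = int(rng.integers(0, src_sizes[chrom] - SITE_LEN + 1))
            sites.append((chrom, start, start + SITE_LEN))
        return sites

    tf_sites: dict[str, list[tuple[str, int, int]]] = {}
    for tf in TF_NAMES[: spec.n_tfs]:
        if tf == spec.planted_tf:
            sites = []
            picks = rng.choice(len(query), size=40, p=q_probs)
            for qi in picks:
                iv = query[qi]
                start = int(rng.integers(iv.start, iv.end - SITE_LEN + 1))
                sites.append((iv.chrom, start, start + SITE_LEN))
            sites += genome_wide_sites(60)
        else:
            sites = genome_wide_sites(100)
        tf_sites[tf] = sorted(sites)

    # --- literature annotations ----------------------------------------------
    planted_query_text = "preharvest sprouting"
    chemicals = ["gibberellic acid", "abscisic acid"]
    text_rows: list[tuple[str, str, str, str]] = []
    text_genes: list[str] = []
    for i in range(spec.n_abstracts):
        pmid = f"{1000001 + i}"
        if i < min(10, spec.n_abstracts):
            gene = planted_module[i % len(planted_module)]
            text_rows.append((pmid, planted_query_text, "disease/phenotype", ""))
            text_rows.append((pmid, "Oryza sativa", "species", ""))
            text_rows.append((pmid, gene, "gene", gene))
            text_genes.append(gene)
        elif i < min(20, spec.n_abstracts):
            gene = str(rng.choice(node_ids))
            text_rows.append((pmid, chemicals[i % 2], "chemical", ""))
            text_rows.append((pmid, gene, "gene", gene))
        else:
            gene = str(rng.choice(node_ids))
            text_rows.append((pmid, "Oryza sativa", "species", ""))
            text_rows.append((pmid, gene, "gene", gene))

    # --- write everything -----------------------------------------------------
    files = {
        "source_gff": "source.gff3",
        "target_gff": "target.gff3",
        "alignments": "alignments.tsv",
        "orthogroups": "orthogroups.tsv",
        "network": "network.tsv",
        "ontology": "ontology.tsv",
        "pathways": "pathways.tsv",
        "tfbs_dir": "tfbs",
        "chrom_sizes": "chrom_sizes.tsv",
        "text_annotations": "text_annotations.tsv",
        "regions": "regions.txt",
        "config": "config.yaml",
    }
    _write_gff3(out / files["source_gff"], src_genes, src_sizes)
    _write_gff3(out / files["target_gff"], tgt_genes, tgt_sizes)
    with open(out / files["alignments"], "w") as fh:
        fh.write("src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\tstrand\n")
        for seg in segments:
            fh.write("\t".join(str(x) for x in seg) + "\n")
    with open(out / files["orthogroups"], "w") as fh:
        for row in sorted(ortho_rows):
            fh.write("\t".join(row) + "\n")
    with open(out / files["network"], "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
    for fname, rows in (
        (files["ontology"], term_rows),
        (files["pathways"], pathway_rows),
    ):
        with open(out / fname, "w") as fh:
            for term_id, desc, genes in rows:
                fh.write(f"{term_id}\t{desc}\t{','.join(genes)}\n")
    tf_dir = out / files["tfbs_dir"]
    tf_dir.mkdir(exist_ok=True)
    for tf, sites in tf_sites.items():
        with open(tf_dir / f"{tf}.bed", "w") as fh:
            for chrom, s, e in sites:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(out / files["chrom_sizes"], "w") as fh:
        for chrom in sorted(src_sizes):
            fh.write(f"{chrom}\t{src_sizes[chrom]}\n")
    with open(out / files["text_annotations"], "w") as fh:
        for row in text_rows:
            fh.write("\t".join(row) + "\n")
    with open(out / files["regions"], "w") as fh:
        for iv in query:
            fh.write(format_region(iv) + "\n")
    with open(out / files["config"], "w") as fh:
        fh.write(
            "\n".join(
                [
                    f"source_genome: {SOURCE_GENOME}",
                    f"target_genome: {TARGET_GENOME}",
                    f"regions: {files['regions']}",
                    f"source_gff: {files['source_gff']}",
                    f"target_gff: {files['target_gff']}",
                    f"alignments: {files['alignments']}",
                    f"orthogroups: {files['orthogroups']}",
                    f"network: {files['network']}",
                    f"ontology: {files['ontology']}",
                    f"pathways: {files['pathways']}",
                    f"tfbs_dir: {files['tfbs_dir']}",
                    f"chrom_sizes: {files['chrom_sizes']}",
                    f"text_annotations: {files['text_annotations']}",
                    "algorithm: clusterone",
                    "min_density: 0.3",
                    "penalty: 2.0",
                    "min_size: 3",
                    "merge_overlap: 0.8",
                    "wcc_threshold: 0.05",
                    "n_perm: 200",
                ]
            )
            + "\n"
        )

    manifest = {
        "spec": asdict(spec),
        "files": files,
        "source_genome": SOURCE_GENOME,
        "target_genome": TARGET_GENOME,
        "query_regions": [format_region(iv) for iv in query],
        "implicated_genes": sorted(implicated),
        "planted_module": planted_module,
        "planted_module_null": bool(
            spec.planted_within_p <= spec.background_edge_p
        ),
        "planted_term": planted_term,
        "planted_pathway": planted_pathway,
        "planted_tf": spec.planted_tf,
        "text_query": planted_query_text,
        "text_query_genes": sorted(set(text_genes)),
        "expected_partition": {
            "common": sorted(
                [g.gene_id, "T" + g.gene_id[1:]] for g in q1_genes
            ),
            "ortholog_elsewhere": sorted(g.gene_id for g in oe_extras),
            "no_ortholog": sorted(g.gene_id for g in no_extras),
            "unique_to_source": sorted(g.gene_id for g in q2_genes),
        },
        "n_source_interval_genes": len(implicated),
        "n_target_interval_genes": len(q1_genes) + len(oe_extras) + len(no_extras),
    }
    with open(out / "manifest.json", "w") as fh:
        fh.write(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
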