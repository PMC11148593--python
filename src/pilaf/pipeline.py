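"""End-to-end orchestration: regions -> genes -> lift-over -> modules ->
enrichment -> TFBS -> literature -> summary.

The pipeline is driven by a plain YAML config naming all inputs and
parameters (paths are resolved relative to the config file).  Every step
is also available as a standalone library call or CLI subcommand; this
module just wires them together deterministically and writes the
intermediate tables.

Candidate genes are the reference genes overlapping the input intervals,
extended with reference orthologs of lifted-target genes whose ortholog
lies outside the original intervals -- the pangenome view can recover
genes a reference-only scan misses, and those recovered genes take part
in the downstream enrichment analyses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import community, enrichment, genome, liftover, regulatory, summary, textmine
from .errors import ContractError

__all__ = ["load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ContractError("config must be a YAML mapping")
    cfg["_base"] = path.parent
    return cfg


def _path(cfg: dict, key: str) -> Path | None:
    if key not in cfg or cfg[key] in (None, ""):
        return None
    return (cfg["_base"] / str(cfg[key])).resolve()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _detection_params(cfg: dict) -> community.DetectionParams:
    return community.DetectionParams(
        penalty=float(cfg.get("penalty", 2.0)),
        min_density=float(cfg.get("min_density", 0.3)),
        min_size=int(cfg.get("min_size", 3)),
        merge_overlap=float(cfg.get("merge_overlap", 0.8)),
        wcc_threshold=float(cfg.get("wcc_threshold", 0.05)),
    )


def run_pipeline(config_path, out_dir, seed: int = 0) -> dict:
    """Run every configured analysis; returns a results dict and writes
    TSV/JSON tables into ``out_dir``.  Deterministic given (config
    contents, input files, seed)."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    src_genome = str(cfg.get("source_genome", ""))
    tgt_genome = str(cfg.get("target_genome", ""))

    # --- input intervals ---------------------------------------------------
    regions_path = _path(cfg, "regions")
    if regions_path is None:
        raise ContractError("config must name a 'regions' file")
    if regions_path.suffix == ".bed":
        query = genome.read_bed(regions_path, src_genome)
    else:
        with open(regions_path) as fh:
            query = [
                genome.parse_region(line, src_genome)
                for line in fh
                if line.strip() and not line.startswith("#")
            ]
    if not query:
        raise ContractError("no input intervals")

    # --- gene list ----------------------------------------------------------
    src_annot = genome.read_gff3(_path(cfg, "source_gff"), src_genome)
    src_genes = genome.genes_overlapping(query, src_annot)
    gene_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in src_genes],
            "chrom": [g.interval.chrom for g in src_genes],
            "start": [g.interval.start for g in src_genes],
            "end": [g.interval.end for g in src_genes],
            "strand": [g.strand for g in src_genes],
            "description": [g.description for g in src_genes],
        }
    )
    _write(gene_df, out / "gene_list.tsv")
    results: dict = {"query": query, "source_genes": src_genes}

    # --- lift-over -----------------------------------------------------------
    candidate_ids = [g.gene_id for g in src_genes]
    extra_from_liftover: list[str] = []
    lifted_presence: dict[str, set] = {}
    comp = None
    if _path(cfg, "target_gff") and _path(cfg, "alignments"):
        tgt_annot = genome.read_gff3(_path(cfg, "target_gff"), tgt_genome)
        aln = liftover.read_alignments(
            _path(cfg, "alignments"), src_genome, tgt_genome
        )
        orthology = (
            genome.read_orthogroups(_path(cfg, "orthogroups"))
            if _path(cfg, "orthogroups")
            else genome.OrthologyMap()
        )
        comp = liftover.liftover_gene_sets(
            query, src_annot, tgt_annot, aln, orthology
        )
        rows = []
        common_by_tgt: dict[str, list[str]] = {}
        for s, t in sorted(comp.common):
            common_by_tgt.setdefault(t, []).append(s)
        for tg in comp.target_genes:
            if tg.gene_id in common_by_tgt:
                cat, partner = "common", ",".join(common_by_tgt[tg.gene_id])
            elif tg.gene_id in comp.ortholog_elsewhere:
                cat = "ortholog_elsewhere"
                partner = ",".join(
                    sorted(genome.orthologs_of(tg.gene_id, orthology, src_genome))
                )
            else:
                cat, partner = "no_ortholog", ""
            rows.append(
                {
                    "gene_id": tg.gene_id,
                    "genome": tgt_genome,
                    "category": cat,
                    "source_orthologs": partner,
                }
            )
        for sid in sorted(comp.unique_to_source):
            rows.append(
                {
                    "gene_id": sid,
                    "genome": src_genome,
                    "category": "unique_to_source",
                    "source_orthologs": "",
                }
            )
        _write(pd.DataFrame(rows), out / "liftover.tsv")
        # reference orthologs of lifted-only target genes join the
        # candidate list for downstream enrichment
        for t in sorted(comp.ortholog_elsewhere):
            extra_from_liftover.extend(
                sorted(genome.orthologs_of(t, orthology, src_genome))
            )
        extra_from_liftover = sorted(set(extra_from_liftover) - set(candidate_ids))
        candidate_ids = candidate_ids + extra_from_liftover
        lifted_presence[tgt_genome] = {s for s, _ in comp.common}
        results["liftover"] = comp
        results["extra_from_liftover"] = extra_from_liftover

    # --- modules and module enrichment ---------------------------------------
    modules: list[community.Module] = []
    mod_enrich: list[enrichment.EnrichmentResult] = []
    ora_by_module: dict[int, list[enrichment.EnrichmentResult]] = {}
    pathway_membership: dict[str, frozenset] = {}
    network = None
    if _path(cfg, "network"):
        network = community.read_edge_list(_path(cfg, "network"))
        params = _detection_params(cfg)
        algo = str(cfg.get("algorithm", "clusterone")).lower()
        if algo == "clusterone":
            modules = community.cluster_one_detect(network, params)
        elif algo == "fox":
            modules = community.fox_detect(network, params)
        else:
            raise ContractError(f"unknown detection algorithm {algo!r}")
        _write(
            pd.DataFrame(
                [
                    {"module_id": m.module_id, "gene_id": g}
                    for m in modules
                    for g in sorted(m.genes)
                ]
            ),
            out / "modules.tsv",
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "module_id": m.module_id,
                        "size": len(m.genes),
                        "cohesiveness": m.cohesiveness,
                        "density": m.density,
                    }
                    for m in modules
                ]
            ),
            out / "module_stats.tsv",
        )
        if modules:
            mod_enrich = enrichment.enrich_modules(modules, set(candidate_ids))
            _write(
                pd.DataFrame(
                    [
                        {
                            "module_id": r.unit_id,
                            "a": r.table.a,
                            "b": r.table.b,
                            "c": r.table.c,
                            "d": r.table.d,
                            "p_raw": r.p_raw,
                            "p_adj": r.p_adj,
                            "enriched": r.enriched,
                        }
                        for r in mod_enrich
                    ]
                ),
                out / "module_enrichment.tsv",
            )

        # --- per-module ORA (enriched modules only) --------------------------
        namespaces = [
            ("ontology", "gene_ontology"),
            ("pathways", "pathway"),
        ]
        ora_rows = []
        enriched_ids = {int(r.unit_id) for r in mod_enrich if r.enriched}
        for key, namespace in namespaces:
            ann_path = _path(cfg, key)
            if ann_path is None:
                continue
            ann = enrichment.read_gene_sets(ann_path, namespace)
            if namespace == "pathway":
                pathway_membership = {
                    t: genes for t, (_, genes) in ann.terms.items()
                }
            annotated = set().union(*(g for _, g in ann.terms.values()))
            background = annotated & set(network.nodes)
            for m in modules:
                if m.module_id not in enriched_ids:
                    continue
                q = set(m.genes) & background
                if not q:
                    continue
                res = enrichment.ora(q, ann, background)
                ora_by_module.setdefault(m.module_id, []).extend(res)
                ora_rows.extend(
                    {
                        "module_id": m.module_id,
                        "namespace": namespace,
                        "term_id": r.unit_id,
                        "description": r.description,
                        "a": r.table.a,
                        "b": r.table.b,
                        "c": r.table.c,
                        "d": r.table.d,
                        "p_raw": r.p_raw,
                        "p_adj": r.p_adj,
                        "enriched": r.enriched,
                    }
                    for r in res
                )
        if ora_rows:
            _write(pd.DataFrame(ora_rows), out / "module_ora.tsv")
    results["modules"] = modules
    results["module_enrichment"] = mod_enrich
    results["ora_by_module"] = ora_by_module

    # --- TF binding-site enrichment -------------------------------------------
    tfbs_results: list[regulatory.OverlapTestResult] = []
    if _path(cfg, "tfbs_dir") and _path(cfg, "chrom_sizes"):
        collection = regulatory.load_tfbs_dir(_path(cfg, "tfbs_dir"), src_genome)
        sizes = regulatory.read_chrom_sizes(_path(cfg, "chrom_sizes"))
        tfbs_results = regulatory.tfbs_enrichment(
            query,
            collection,
            sizes,
            n_perm=int(cfg.get("n_perm", 1000)),
            seed=seed,
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "tf": r.tf,
                        "observed": r.observed,
                        "null_ge": r.null_ge,
                        "n_perm": r.n_perm,
                        "p_raw": r.p_raw,
                        "p_adj": r.p_adj,
                        "enriched": r.enriched,
                    }
                    for r in tfbs_results
                ]
            ),
            out / "tfbs_enrichment.tsv",
        )
    results["tfbs"] = tfbs_results

    # --- literature ------------------------------------------------------------
    literature: dict[str, set] = {}
    if _path(cfg, "text_annotations"):
        index = textmine.read_annotations(_path(cfg, "text_annotations"))
        literature = textmine.literature_for_genes(index, candidate_ids)
        _write(
            pd.DataFrame(
                [
                    {"gene_id": g, "pmids": ",".join(sorted(literature[g]))}
                    for g in candidate_ids
                ]
            ),
            out / "literature.tsv",
        )
    results["literature"] = literature

    # --- summary ----------------------------------------------------------------
    rows = summary.build_summary(
        genes=candidate_ids,
        modules=modules,
        module_enrichment=mod_enrich,
        ora_results=ora_by_module,
        pathway_membership=pathway_membership,
        literature=literature,
        lifted_presence=lifted_presence,
    )
    rows = summary.sort_summary(
        rows,
        [
            ("n_module_terms", "desc"),
            ("n_pathways", "desc"),
            ("n_articles", "desc"),
            ("gene_id", "asc"),
        ],
    )
    frame = summary.summary_frame(rows)
    _write(frame, out / "summary.tsv")
    with open(out / "summary.json", "w") as fh:
        fh.write(frame.to_json(orient="records", indent=2))
        fh.write("\n")
    results["summary"] = rows
    return results
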