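# pilaf

Post-GWAS/QTL candidate-gene prioritization for plant genomics.

A GWAS peak or a mapped QTL is a genomic interval containing tens to
hundreds of genes, most of them not causal, many of the associated
variants noncoding, and all of it reported in the coordinates of a single
reference assembly.  `pilaf` is a headless toolkit (library + CLI) that
cross-references such intervals with the resources a rice geneticist —
or anyone with equivalent inputs — would consult to shortlist candidate
genes:

- **Gene lists** — genes overlapping the intervals, from a GFF3
  annotation (half-open interval intersection, ≥ 1 bp).
- **Pangenome lift-over** — projection of the intervals onto another
  assembly through precomputed one-to-one whole-genome alignment
  segments, then a four-way partition of the gene content by ortholog
  groups: pairs common to both genomes, target genes whose ortholog lies
  *outside* the original intervals (genes a reference-only scan misses),
  target genes with no ortholog, and reference genes with no counterpart.
- **Coexpression modules** — overlapping community detection in a
  weighted coexpression network, with a cohesiveness-based greedy
  detector (objective `f(V) = w_in / (w_in + w_bound + p·|V|)`) and a
  triangle/WCC-based detector, followed by a one-tailed Fisher exact
  test of each module against the implicated genes (background = union
  of genes across detected modules) with Benjamini–Hochberg FDR control.
- **Ontology / pathway ORA** — hypergeometric overrepresentation of a
  gene set against GMT-style term collections, BH-corrected per
  namespace; a unit is enriched at adjusted *P* < 0.05.
- **Regulatory enrichment** — per-TF binding-site overlap counts with a
  chromosome-aware, length-preserving shuffle null and the add-one
  Monte-Carlo estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)`.
- **Literature mining** — indexing of NER-derived (PubMed id, surface,
  entity type, gene id) tables; genes retrieved by same-abstract
  co-occurrence with trait/chemical/species mentions, and articles per
  gene.
- **Summary** — one prioritization row per candidate gene (pathway
  memberships, enriched module terms, article counts, module ids,
  lift-over presence) with stable multi-column sorting.

A deterministic synthetic-data generator (`pilaf simulate`) produces an
internally consistent bundle of every input format with planted signals
and a ground-truth manifest, so the entire pipeline is testable offline.

## Worked example

Generate a fixture bundle and run the full pipeline:

```sh
pilaf simulate --out demo --seed 7
pilaf run --config demo/config.yaml --out demo_results --seed 1
```

which prints

```
wrote bundle with 12 inputs to demo
12 candidate genes summarized in demo_results/summary.tsv
```

The head of `demo_results/summary.tsv`:

```
gene_id	n_pathways	n_module_terms	n_articles	n_modules	module_ids	in_ALT
S01G011	3	0	1	1	1	True
S01G014	2	0	2	1	1	True
S01G013	2	0	1	1	1	True
```

Reading a row: gene `S01G011` sits in 3 pathways, belongs to module 1,
is mentioned in 1 indexed abstract, and has an ortholog inside the
lifted intervals of the target genome `ALT`.  `demo_results/` also holds
the per-stage tables: `liftover.tsv` (each target gene labelled
`common` / `ortholog_elsewhere` / `no_ortholog`, plus
`unique_to_source` reference genes), `module_enrichment.tsv`
(contingency counts with raw and adjusted *P*), and
`tfbs_enrichment.tsv`, where the binding-site-enriched TF planted by the
simulator (`ERF`) is the top hit at the permutation floor
`p_raw = 1/201 ≈ 0.005`.

Every stage is also a standalone subcommand (`pilaf genes`,
`pilaf liftover`, `pilaf modules detect`, `pilaf enrich
modules|ontology|pathway|tfbs`, `pilaf text query|literature`) and a
plain library call (`pilaf.cluster_one_detect`, `pilaf.enrich_modules`,
`pilaf.tfbs_enrichment`, ...).

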