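# Methods

This note documents the models and procedures implemented in `pilaf`,
the defaults and why they were chosen, the design decisions that were
genuinely open, and what the synthetic fixtures can and cannot show.

## Coordinates and interval algebra

All in-memory coordinates are 0-based half-open (BED arithmetic); the
two 1-based fully-closed conventions that occur in the wild — printed
region strings such as `Chr01:1523,625-1770814` (thousands separators
are stripped) and GFF3 records — are converted once, at the parsing
boundary.  Overlap everywhere means a shared base pair: touching
intervals (`end == start`) do not overlap.  A printed span whose start
equals its end is rejected as empty, so single-base regions are not
expressible as region strings (use BED input for those).  Chromosome
names are compared case-insensitively with a leading `chr` prefix
stripped; names are never assumed comparable across genomes.

## Lift-over through one-to-one alignments

Inputs are ungapped alignment segments — length-preserving affine maps
between a source span and a target span, forward or reverse strand —
with the invariant that no two segments overlap on either genome
(one-to-one: each base aligns to at most one base of the other genome).
Validation rejects violations rather than resolving them, since silent
resolution would hide segmental duplications.  Gapped alignment blocks
should be decomposed into ungapped segments upstream; the ungapped TSV
is the analysis format because it makes the invariants checkable and the
projection exact.

Projecting an interval emits the image of its intersection with every
segment it touches; images abutting on the same chromosome are merged,
but unaligned gaps are never bridged (bridging would fabricate lifted
sequence).  Because segments need not be colinear, one query interval
may project onto several chromosomes — that is how interchromosomal
rearrangements become visible.  For any interval inside a single
segment the round trip source→target→source is the identity, and total
projected length never exceeds query length, with equality exactly when
the query is fully covered.

The gene-set comparison partitions target genes overlapping the lifted
intervals into three disjoint, exhaustive categories via ortholog
groups: *common* (an ortholog pair with both members inside their
intervals), *ortholog elsewhere* (the source ortholog exists but falls
outside the input intervals — the most interesting category, since a
reference-only analysis would never surface these genes), and *no
ortholog*.  Source genes without a counterpart among the target
interval genes are *unique to source*.  A gene queried against its own
genome is a member of its own group, so an identity lift-over reports
every gene as common with itself.  All lifted intervals of ≥ 1 bp are
reported; minimum-length filtering is left to the caller.

## Overlapping module detection

Genes participate in multiple processes, so both detectors allow
overlapping modules.

**Cohesiveness-based detector.**  The cohesiveness of a vertex set V in
a weighted graph is

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + p·|V|)

with `w_in` the internal edge weight, `w_bound` the boundary edge
weight, and `p ≥ 0` a per-vertex penalty modelling unobserved edges.
Growth starts from every vertex not yet covered by a grown group
(seeds in decreasing weighted-degree order) and repeatedly applies the
single boundary-vertex addition or internal-vertex removal that most
increases f, stopping at a local maximum.  Groups below the size or
weighted-density floors are discarded; groups whose overlap score
`ω(A,B) = |A∩B|²/(|A||B|)` reaches the merge threshold are replaced by
the union of their connected component.  A merged union is refined back
to a cohesiveness local optimum and the merge is iterated to a fixpoint
(capped, with a greedy earlier-wins fallback): this deviates from a
plain single-pass union on purpose, so that every *emitted* module is a
local optimum of f — a property a union of two local optima does not
automatically have.  Defaults: `p = 2`, `min_density = 0.3`,
`min_size = 3`, `merge_overlap = 0.8`, following the conventions of
cohesiveness-based detection; all are exposed on the CLI.  Tie-breaks
(equal move gain, equal degree) are lexicographic on node id, which
makes runs bit-reproducible; reference implementations leave tie order
undocumented, so exact output equivalence with them is a non-goal.

A structural consequence worth knowing: a dense set joined to another
dense set through a shared vertex is usually *not* separable by this
objective.  For two unit triangles sharing a hub, extending a triangle
across the hub always increases f (for every p ≥ 0), so the detector
returns the 5-node union rather than the two triangles.  This is a
property of the cohesiveness objective itself, not of the
implementation.

**Triangle/WCC-based detector.**  A normative, deliberately simple
variant of weighted-community-clustering detection, defined by this
package rather than borrowed: seeds are triangle-connected closed
neighborhoods (a node plus every neighbor sharing a common neighbor
with it), taken over uncovered nodes in decreasing weighted-degree
order; then, in a single round evaluated against the seed snapshot,
an outside node u joins seed community S when its approximated
per-node WCC

    ŵcc(u, S) = [C(d_in, 2) · δ(S)] / C(deg(u), 2)

exceeds the join threshold (default 0.05), where `d_in` is u's
in-community degree, `δ(S)` the community's internal edge density —
approximating u's triangle count with S from its in-community degree —
and the denominator u's maximum possible triangle count.  Evaluating
joins against the snapshot keeps total membership monotone
nonincreasing in the threshold, a property the test suite checks.
Triangle-free vertices never seed a community, so an edgeless or
forest-like graph yields nothing.

## Enrichment statistics

Module enrichment and ontology/pathway ORA share one engine: a 2×2
table per tested unit over a background universe, the one-tailed
Fisher exact test `P(X ≥ a)` with
`X ~ Hypergeometric(N, K = a+c, n = a+b)` evaluated through the
hypergeometric survival function (log-space, exact to double
precision), and Benjamini–Hochberg step-up adjustment across the units
of one analysis family.  A unit is enriched when its adjusted *P* is
below 0.05.

Backgrounds are the consequential choice.  For module enrichment the
background is the union of genes across *detected modules* — not the
whole network — and implicated genes outside that union are dropped
before tabulation rather than added, because adding them would break
the 2×2 marginal structure.  For ontology/pathway ORA the default
background is the annotated genes present in the network
(caller-overridable).  BH is applied separately per namespace (gene
ontology, trait ontology, plant ontology, pathway) and per analysis
family; terms sharing no gene with the query are excluded from the
family.  The tests are discrete and therefore conservative; no mid-p
variant is offered.

## TF binding-site overlap test

The statistic per TF is site-centric: the number of binding-site
intervals intersecting at least one query interval, each site counted
once.  Significance comes from a Monte-Carlo null in which every query
interval is independently repositioned uniformly within its own
chromosome, length preserved (no cross-chromosome moves), with the
add-one estimator `p = (1 + #{shuffles ≥ observed}) / (1 + n_perm)`,
so `p ≥ 1/(n_perm+1)` always.  One pool of shuffles is shared across
TFs, making the whole procedure O(n_perm) in shuffles and
deterministic given the seed.  TFs with zero observed overlap are
excluded from testing and from the BH family.  Default
`n_perm = 1000`; the CLI requires an explicit seed.  An exact
dynamic-programming null for interval-overlap statistics exists in the
literature; the shuffle null was chosen because it is self-contained,
its calibration is directly testable (the suite verifies the empirical
type-I error at α = 0.05 over 1,000 null replicates), and it targets
the same question — is the overlap larger than chance placement
predicts.

## Literature annotations

The NER pipeline that produces annotations is out of scope; this
package consumes its tabular output (PubMed id, surface text, one of
four entity types, normalized gene id).  Queries are case-insensitive
substring matches on surface text — predictable and testable; no
stemming or fuzzy matching — and gene–query association is
same-abstract co-occurrence, a normative choice documented here because
"associated with" admits several readings (per-sentence co-occurrence
would be stricter; relation extraction stricter still).

## Summary table

One row per candidate gene.  `n_module_terms` counts enriched
terms/pathways over *all* modules containing the gene, deduplicated by
term id, because double-counting a term shared by two modules would
inflate priority.  Candidate genes are the reference interval genes
plus reference orthologs recovered through lift-over (the
ortholog-elsewhere category).  Sorting is a stable lexicographic pass
over (column, direction) keys, so equal-key rows keep their input
order.  Columns beyond the three core statistics (pathways, module
terms, articles) are implementation-defined.

## Synthetic fixtures

`pilaf simulate` writes a complete input bundle plus a ground-truth
manifest.  The genome pair is schematic: 40 kb alignment segments with
2 kb unaligned gaps, genes on a regular grid strictly inside segments,
a +30 kb target shift, one segment inside the first query interval
relocated to another target chromosome (rearrangement), one segment
deleted.  That rigidity is the point — the expected lift-over partition
(7 common pairs, 2 orthologs-elsewhere, 3 no-ortholog, 3
unique-to-source under defaults) is computable at construction time and
recorded in the manifest, so tests assert against construction, not
against the code under test.

The coexpression network has 100 nodes: a planted 12-gene module with
within-module edge probability 0.9 and unit weights (six of its genes
lie in the query intervals, which overlap 10 genes in total) on an
Erdős–Rényi background with edge probability 0.05 and weights uniform
on [0.1, 1], emulating confidence-scored coexpression edges.  One
ontology term and one pathway contain most of the planted module; one
of eight TFs has 40 of its 100 binding sites concentrated in the query
intervals (≥ 5× the genome-wide density by construction); ten abstracts
pair a planted phenotype surface with planted-module genes.  Everything
derives from one seeded generator, so bundles are byte-reproducible.

What passing tests on these fixtures do **not** show: performance at
genome scale (the real analyses run on networks of tens of thousands of
genes and ~2,600+ modules, where the enrichment background is far
larger and adjusted P values far smaller than the desk-scale fixture
can produce — on a 100-node network the union-of-modules background is
a few dozen genes, which bounds how small a module's adjusted *P* can
get); robustness to messy annotations (overlapping gene models,
trans-spliced genes); or behavior under many-to-many homology, which
the one-to-one alignment model excludes by design.

## Numerical and degenerate-input choices

- Fisher tails via the hypergeometric survival function; `a = 0` short-
  circuits to `p = 1`; results clipped to [0, 1].
- Cohesiveness of a set with `w_in = 0` is 0; empty sets are contract
  errors, as are singleton densities.
- Greedy moves require a strict improvement (`> current + 1e-12`), so
  growth terminates and plateaus do not cycle.
- Readers reject structurally invalid rows (negative spans, nonpositive
  edge weights, unknown entity types, non-one-to-one segments) with a
  warning when a row is skippable and an error when the invariant is
  global.
- Interval shuffling of an interval exactly as long as its chromosome
  yields the forced identity placement; longer intervals are contract
  errors.

## Known limitations

- The cohesiveness objective cannot split dense regions joined through
  articulation vertices (see above); callers wanting finer modules
  should raise the penalty or use the triangle-based detector.
- The module-enrichment background follows the detected modules, so on
  small networks the test has limited power regardless of effect size.
- The shuffle null preserves interval lengths and chromosome assignment
  but not local covariates (GC, gene density); an enrichment against a
  strongly clustered site set reflects that clustering too.
- Text queries are substring-based; short queries can over-match.
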