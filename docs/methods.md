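# Methods

## Orthology model

The unit of input is a pairwise orthology cluster between one reference
species and one target species, in the InParanoid style: a cluster holds
the reference-side genes (the seed ortholog plus any in-paralogs, i.e.
duplicates that arose after the reference/target speciation) and the
target-side genes.  One `OrthologRecord` is materialized per
(cluster, reference gene, target species); the relationship category of a
(gene, species) cell depends only on the cardinalities of the two sides:

| reference side | target side | category |
|---|---|---|
| — | — | none (no cluster) |
| 1 | 1 | 1:1 |
| 1 | ≥2 | 1:M |
| ≥2 | 1 | M:1 |
| ≥2 | ≥2 | M:M |

"Many" is decided by cluster membership (in-paralogs within the same
cluster), not genome-wide family size: that is what the pairwise clusters
actually assert.  Clusters spanning more than two species are rejected —
the tables are pairwise by construction.  A cluster with no target gene is
an input error rather than a silent "none": absence is encoded by the
absence of a cluster.

Profile matrices keep the per-cell ortholog and in-paralog sets so the
tile-level drill-down (which orthologs? which predicted in-paralogs?) can
be answered after assembly.  Gene lists are capped at 1000 per run
(configurable), the customary bulk-query bound for this kind of analysis.

## Architectures

An architecture is the N→C-ordered sequence of Pfam-A accessions on one
protein, restricted to entries typed `Domain` or `Family`; `Repeat`,
`Motif`, `Coiled-coil` and `Disordered` entries are parsed but never enter
architectures, because only the first two behave as independent folding
units.  Accession version suffixes are stripped on input so architectures
compare by accession family across Pfam releases; comparisons use
accessions rather than domain names because names alias.

When a gene has several isoforms, the longest peptide represents it (ties:
lexicographically smallest protein id, which makes the choice independent
of input order).  Within one protein, hits are ordered by alignment start
(ties: end, then accession).  Overlapping hits are resolved greedily by
descending bit score (ties: lower E-value, then accession); greedy
acceptance guarantees the retained spans are mutually non-overlapping.
All coordinates are 1-based and inclusive.

## Parsimony classification

"Parsimonious" is formalized as the minimum insert/delete script between
domain sequences (no substitution operation): cost = |ref| + |tgt| −
2·LCS(ref, tgt).  The classification cascade tries each single-event
explanation in order — identical (conserved); reference a proper
subsequence of the target (gain: a pure-insertion script exists); target a
proper subsequence of the reference (loss); equal multisets, different
order (rearrangement); both empty (no domains) — and anything left is
*complex*: no single event class suffices, so multiple mixed histories of
equal cost exist.  Any multiset-preserving reorder is classified
rearrangement even where an equal-cost gain+loss script also exists
(possible in palindromic cases); the alternative convention would be
defensible but this one keeps the event classes mutually exclusive.

The deterministic script is produced by an LCS backtrace that prefers
deletions over insertions at equal cost, scanning left to right.  Scripts
are replayable (`EditScript.apply`): deletions by reference index, then
insertions by target index.

Granular refinement of gains/losses uses run-length encoding of adjacent
identical accessions: if reference and target collapse to the same
accession sequence and differ only in run lengths, the event is a repeat
expansion/contraction; otherwise cost-1 scripts are single gains/losses
and everything else is mixed.  Repeat counts are compared exactly — a
two-copy difference is still a repeat contraction, but a contraction; no
tolerance is applied.  Empty-versus-nonempty comparisons get their own
granular labels (empty target/reference/both) so proteins with no
detectable domains remain distinguishable from conserved architectures.

For 1:M and M:M cells every target ortholog is classified; the cell
reports the minimum-edit-cost target, with ties resolved toward the more
conservative class (conserved/no-domains < gain/loss < rearrangement <
complex) and then the lexicographically smallest gene id.  The full
per-ortholog table is always retained, so the aggregation discards no
information.  This aggregation rule is a design choice: the cell should
show the most parsimonious available explanation, while the summary table
carries the rest.

## Adjacency networks

Nodes are accessions; a directed edge A→B is created for each consecutive
pair within an architecture, weighted by occurrence count and carrying the
contributing protein ids as provenance.  Direction is never collapsed
(A→B ≠ B→A) and tandem pairs of identical domains produce self-loops —
the direct reading of "consecutive in the N→C sequence".

Exploration state is part of the graph so sessions are scriptable: seed
architectures create `core` nodes; `expand_neighbors` records discovered
neighbors and their adjacency edges as `transient` without touching core
content (re-expansion is idempotent — weights only grow toward the
proteome-wide occurrence count); `commit_neighbor` flips exactly one
transient node to `committed`, after which it can seed further expansion.
Pattern search is ordered subsequence containment (greedy two-pointer; an
optional strict flag requires contiguity), and matched proteins' full
architectures merge into the graph as committed content.  No operation
removes nodes or edges, so exploration is monotone.

Graph exports: a JSON schema with full provenance
(`{"nodes": {acc: {count, status}}, "edges": [{source, target, weight,
provenance}], "seed_proteins": [...], "architectures": {...}}`, validated
field-by-field on read) and GraphML with set-valued attributes flattened
to sorted comma-joined strings.

## Clustering

Rows of a numeric profile matrix are clustered agglomeratively.  Metrics:
Euclidean, city-block, centered Pearson (1 − r), uncentered Pearson
(1 − Σxy/√(Σx²Σy²)), Spearman (centered Pearson on ranks).  Where a
correlation is undefined (constant row for centered/Spearman, zero-norm
row for uncentered) the distance is defined as the metric's maximum, 2.0.
Linkages: single, complete, average (UPGMA, via the exact Lance–Williams
recurrences) and centroid, where centroid distance is the chosen metric
between cluster mean vectors so that it stays defined under correlation
metrics.  The agglomeration is implemented in the package because the
deterministic conventions below are part of its contract and centroid
linkage under non-Euclidean metrics is outside what standard linkage
routines support; scipy provides the distance primitives.

Determinism conventions: at each step the minimum-distance pair merges;
among pairs within 1e-12 of the minimum (an exact-tie band that absorbs
floating-point noise in the distance updates), the pair whose clusters
contain the smallest original row indices wins.  Leaf order places the
smaller subtree first, ties broken by the smallest original index in the
subtree.  Defaults are uncentered correlation with average linkage, the
customary configuration for expression-style heatmap clustering.
Dendrograms export as JSON and as Newick with branch lengths taken from
merge-height differences.

Species columns are never clustered; they stay in the supplied
(phylogenetic) order in every view.

## Heatmaps

Rendering writes SVG directly — one `<rect>` per cell, rows in clustered
order, fixed integer geometry — which makes output byte-identical for
identical input.  Palettes map every category code and must map absence to
black; defaults are documented in `cluster_heatmap` (binary presence,
5-category relationship, 7-category architecture-conservation with codes
no_ortholog=0, no_domains=1, complex=2, rearrangement=3, loss=4, gain=5,
conserved=6).  An unknown code raises an error naming the offending cell.

## Synthetic data

The generator emulates the full input surface: a simple-TSV orthology
table, per-species pfam_scan-format hit tables, proteome FASTA files, and
two truth tables (relationship category and architecture event per cell).
Defaults are 200 genes × 20 target species, a 30-accession domain
alphabet, architectures up to 8 domains, relationship probabilities
(none 0.20, 1:1 0.40, 1:M 0.15, M:1 0.15, M:M 0.10) and an event mix
(conserved 0.30, gain 0.14, loss 0.14, rearrangement 0.10, complex 0.12,
repeat expansion 0.10, repeat contraction 0.10) — a regime in which every
class is well represented while conservation remains the modal outcome,
as in real eukaryote-wide panels.

Events are realized constructively so truth is exact, not statistical:
gain inserts an accession absent from the reference; loss deletes a
singleton run; rearrangement swaps two distinct adjacent domains; complex
deletes a singleton and inserts a novel accession; repeat
expansion/contraction adds/removes one copy inside a run.  Every reference
architecture is drawn so that all events are realizable on it (it contains
a tandem run, a singleton run, a distinct-adjacent pair, and fewer
accessions than the alphabet), and each transformed target is re-checked
with the classifier at generation time; a transform that failed the check
would be retried, never silently mislabeled.  Each planted event is
applied once per (gene, species) cell, with all in-paralog targets of the
cell sharing the transformed architecture.

Domain hits are laid out at a fixed 60-aa pitch with 50-aa spans; one
decoy `Motif` hit per protein is planted beyond the last domain so the
entry-type filter is exercised on every round trip.  FASTA sequences are
filler residues of consistent declared length — the generator emulates
record structure, not sequence evolution, substitution processes,
tree-correlated presence/absence, annotation noise or missing data.
Passing recovery tests therefore demonstrates correctness of the
bookkeeping and classification logic under clean inputs, not robustness
to the noise sources of real proteomes.  Species names come from a fixed
fictional list; determinism is per-seed and byte-exact (one
`random.Random` stream drives all draws).

## Problem sizes and numerical notes

The exhaustive classifier check covers all 121² = 14 641 pairs of
architectures of length ≤ 4 over a 3-symbol alphabet, a size at which
brute-force enumeration of insert/delete scripts is exact and fast.
Clustering oracle comparisons use 5–8 row matrices, where a from-scratch
O(n³) agglomeration is itself trivially auditable.  The planted-event
recovery study runs at the default 200 × 20 scenario (4000 cells).
Degenerate inputs: empty architectures are valid everywhere (empty graph,
NO_DOMAINS class); a single-row matrix is rejected for clustering rather
than returning a trivial tree; NaN in a matrix is an error, not imputed.

## Known limitations

* The complex class is assigned by elimination; no enumeration of
  equally-parsimonious histories is attempted beyond the cascade's logic.
* Multi-ortholog cells are summarized by the minimum-edit-cost target;
  other conventions (e.g. majority class) are not offered.
* No ancestral-state reconstruction on a species tree; comparisons are
  strictly pairwise against the reference.
* Centroid linkage can produce non-monotone merge heights (inversions);
  they are reported as computed.
* GraphML export flattens provenance sets to strings; only the JSON format
  round-trips losslessly.
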