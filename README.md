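# phyloprofiler

Phylogenetic profiles, domain-architecture conservation and domain-adjacency
networks for eukaryotic ortholog sets.

Given (i) pairwise orthology assignments between a reference species and a
panel of target species (InParanoid-style clusters, which distinguish
in-paralogs arising from lineage-specific duplication) and (ii) Pfam-A
domain annotations for every proteome, `phyloprofiler` answers three
questions for a list of query genes:

1. **Where is each gene conserved, and how?**  For every (gene, target
   species) pair one of five homology relationships is assigned — no
   detectable ortholog, 1:1, 1:M, M:1 or M:M — and collated into a
   phylogenetic profile matrix that can be clustered and rendered as a
   heatmap (colored tile = ortholog present, black = absent).
2. **How has the protein's domain architecture changed?**  Architectures
   (the N→C-ordered sequence of Pfam-A Domain/Family accessions on a gene's
   longest peptide) are compared parsimoniously, classifying each ortholog
   as *conserved*, *gain*, *loss*, *rearrangement* or *complex*, with a
   repeat-aware granular layer separating tandem-repeat copy-number changes
   (repeat expansion/contraction) from single-domain events.
3. **Which domains co-occur, and in what order?**  A directed
   domain-adjacency network links domains that are consecutive within
   architectures (direction matters: A→B ≠ B→A).  The graph supports
   neighbor expansion against a species proteome, transient/committed
   exploration state, and ordered non-contiguous pattern search — the query
   `A,B,C` matches a protein with architecture `A,D,B,C`.

## The core model

For reference gene *g* and target species *s*, an orthology cluster
contributes a reference in-paralog set *R* (with *g* ∈ *R*) and a target
ortholog set *T*.  The relationship category is determined by the
cardinality quadrant: |R| = 1 ∧ |T| = 1 ⇒ 1:1, |R| = 1 ∧ |T| ≥ 2 ⇒ 1:M,
|R| ≥ 2 ∧ |T| = 1 ⇒ M:1, both ≥ 2 ⇒ M:M; no cluster ⇒ absent.

Architecture comparison uses minimum insert/delete scripts over domain
sequences.  For reference architecture *a* and target *b* the edit cost is

```
cost(a, b) = |a| + |b| − 2·LCS(a, b)
```

where LCS is the longest common subsequence.  The classification cascade
is: identical ⇒ conserved; *a* a proper subsequence of *b* ⇒ gain (a pure
insertion script exists); *b* a proper subsequence of *a* ⇒ loss; equal
multisets in different order ⇒ rearrangement; otherwise complex (no single
event class explains the difference — several mixed histories are equally
parsimonious).  Run-length encoding of adjacent identical accessions
refines gains/losses into repeat expansions/contractions versus single or
mixed domain events.

Profile rows are clustered agglomeratively (Euclidean, city-block, centered
or uncentered Pearson, or Spearman distances; single, complete, average or
centroid linkage) with fully deterministic tie-breaking; species columns
always stay in the supplied phylogenetic order.

## Worked example

```python
from phyloprofiler import classify_pair, search_pattern
from phyloprofiler.arch_compare import Architecture

# A target ortholog carrying one fewer copy of a tandem EGF repeat:
ref = ("LRR", "LRR", "EGF", "EGF", "EGF", "LamG")
tgt = ("LRR", "LRR", "EGF", "EGF", "LamG")
cls, gran, script = classify_pair(ref, tgt)
print(f"class={cls.value} granular={gran.value} edit_cost={script.cost}")

# Ordered but non-contiguous domain pattern search:
proteome = [Architecture("SLIT-like", ("LRR", "Ig", "EGF", "LamG")),
            Architecture("reversed", ("LamG", "EGF", "LRR"))]
print("pattern hits:", search_pattern(["LRR", "EGF", "LamG"], proteome))
```

prints

```
class=loss granular=repeat_contraction edit_cost=1
pattern hits: ['SLIT-like']
```

— the repeat-aware layer recognizes the missing EGF copy as a contraction
of a tandem repeat (a single-deletion loss), and the pattern matches the
protein containing `LRR…EGF…LamG` in order despite the intervening Ig
domain, while the reversed architecture does not match.

The synthetic-data module generates a complete seeded study (orthology
table, per-species pfam_scan-style hits, proteomes, truth tables) with
planted relationship categories and architecture events:

```python
import tempfile
from phyloprofiler import ScenarioConfig, generate_scenario, write_scenario, verify_recovery

scenario = generate_scenario(ScenarioConfig(seed=1))   # 200 genes x 20 species
with tempfile.TemporaryDirectory() as tmp:
    write_scenario(scenario, tmp)
    report = verify_recovery(tmp)
print(f"cells={report.n_cells} relationship_recovery={report.relationship_accuracy:.3f} "
      f"event_recovery={report.event_accuracy:.3f}")
```

prints

```
cells=4000 relationship_recovery=1.000 event_recovery=1.000
```

— running the full pipeline over the emitted files recovers every planted
relationship category and architecture event exactly, because events are
realized constructively at generation time.

The same pipeline is available from the shell:

```
phyloprofiler simulate --seed 5 --n-genes 30 --n-species 6 --out demo
phyloprofiler profile --genes demo/genes.txt --orthologs demo/orth.tsv \
    --species-order demo/species_order.txt --encode binary --out demo/profile.tsv
phyloprofiler cluster --matrix demo/profile.tsv --heatmap demo/heatmap.svg \
    --order demo/order.txt --newick demo/tree.nwk
phyloprofiler domcons --genes demo/genes.txt --orthologs demo/orth.tsv \
    --ref-species Archetypus_primus --species-order demo/species_order.txt \
    --arch-dir demo/arch --out demo/domcons.tsv --summary demo/summary.tsv
phyloprofiler network search --pattern PF10001,PF10005 \
    --arch-dir demo/arch --species Archetypus_primus
```

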