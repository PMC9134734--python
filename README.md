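# plastosynapo

Comparative plastome structural variation on a fixed phylogeny.

Plastid genomes are circular quadripartite molecules — large and small
single-copy regions (LSC, SSC) separated by an inverted repeat pair
(IRa/IRb).  Their rare structural changes are prized characters for deep
plant phylogeny: large inversions (V), IR boundary shifts (R), losses of
protein-coding genes or introns (G), tRNA losses and anticodon changes
(T), and in-frame codon indels (D).  `plastosynapo` is for
phylogeneticists who have a set of annotated plastomes and a rooted
species tree and want a reproducible, branch-placed ledger of those five
event classes, with each event classified as synapomorphy, autapomorphy
or homoplasy.

What it computes, per genome and per branch:

* quadripartite partition from exact-seed detection of the inverted
  repeat (SSC may be as small as 0 bp), and per-gene region assignment
  including boundary-partial genes;
* canonical signed gene orders (IR-collapsed, anchor-rotated) and exact
  minimum reversal scenarios — an A* search with the breakpoint-graph
  cycle bound `n + 1 − c`, charged to branches by a stepwise
  parent-to-child comparison down the tree;
* gene presence under the pseudogene rule used for RNA-editing-rich
  plastids: lost only when ORF integrity or similarity drops below 0.70
  against an intact relative; internal stops and odd start/stop codons
  are notes, never losses; single-sample losses are set aside;
* structural tRNA validation (cloverleaf fold + anticodon/isotype
  consistency) distinguishing real loci, anticodon changes and
  hypothetical losses;
* codon-aware CDS alignments (translate → align → back-thread) and
  frame-preserving indels with carrier sets;
* Fitch/Dollo parsimony mapping of all characters onto the input tree
  (Dollo for losses, per-class resolution defaults documented in
  `docs/methods.md`), plus a two-topology character-cost comparison.

A fully seeded simulator (`plastosynapo.synthetic_data`) evolves
annotated plastomes along a tree with all five event classes and a
replayable truth ledger, so the entire pipeline is testable without any
downloads; `figure2_scenario()` packages a fern family-level scenario
with 9 V + 7 R + 10 G + 7 T + 19 D events on named branches.

## Worked example

Simulate the packaged scenario, then run the full pipeline against the
Osmundaceae-like reference:

```bash
plastosynapo simulate --seed 1 --out demo/
plastosynapo run --genomes demo/ --tree demo/tree.nwk \
    --reference Osmundaceae_1 --out demo_reports/
```

which prints

```
wrote 51 genomes + tree + ledger to demo
64 mapped events; reports in demo_reports
```

`demo_reports/ledger.json` holds the branch-placed events.  The entry
for the clade uniting Dipteridaceae, Matoniaceae, Schizaeales and the
core leptosporangiates reads (span genes elided):

```json
"v5_clade": [
  {"label": "V5", "class": "V", "direction": "gain",
   "classification": "synapomorphy",
   "detail": {"left": "psbA", "right": "rpoC2", "span_genes": ["rpoC2", "..."]}},
  {"label": "R5", "class": "R", "direction": "gain",
   "classification": "synapomorphy",
   "detail": {"gained": [], "lost": [], "partial": [["ndhB", "exon2"]],
              "side": "LSC"}}
]
```

i.e. one large LSC inversion and an IR expansion that duplicates only
the second exon of ndhB, both placed as synapomorphies on that stem —
the co-occurring V+R pair whose distribution argues for the paraphyly of
Gleicheniales.  The same comparison in library form:

```python
from plastosynapo import Phylogeny, compare_topologies
from plastosynapo.synthetic_data import (figure2_tree_newick,
                                         gleicheniales_monophyletic_newick)

tree = Phylogeny.from_newick(figure2_tree_newick())
alt = Phylogeny.from_newick(gleicheniales_monophyletic_newick())
# states: 1 for every leaf of the clade carrying the inversion
# compare_topologies(states, tree, alt)  ->  (1, 2)
```

One parsimony step on the reference topology versus two (an extra,
reversed inversion) when Gleicheniales are forced monophyletic.

Per-genome scanning works on any annotated GenBank file:

```bash
plastosynapo scan --genbank demo/Osmundaceae_1.gb --anchor psbA
```

prints the LSC/IRa/SSC/IRb table (1-based, inclusive) and the canonical
signed gene order.

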