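# Methods

## The analysis

Plastid genomes (plastomes) of land plants are circular, quadripartite
molecules: a large and a small single-copy region (LSC, SSC) separated by
two reverse-complementary copies of an inverted repeat (IRa, IRb).  Their
structural rearrangements — large inversions, expansions and contractions
of the repeat boundary, losses of protein-coding genes, introns and
tRNAs, tRNA anticodon changes, and frame-preserving (codon) indels inside
protein-coding genes — are rare, complex events and therefore carry
strong, low-homoplasy phylogenetic signal.  `plastosynapo` turns the
comparative protocol used for such analyses in ferns into a tested
pipeline: annotated genomes in, a branch-placed ledger of structural
events out, with every event classified as synapomorphy, autapomorphy or
homoplasy on a fixed rooted tree.

The five event classes are abbreviated throughout as V (inversion),
R (IR boundary shift), G (protein-coding gene or intron loss), T (tRNA
loss or anticodon change) and D (codon indel).

## Models and procedures

### Quadripartite partitioning

The repeat pair is found from exact 25-mer seeds between the sequence
and its reverse complement, chained on diagonals into maximal exact
reverse-complementary repeats and, when the required identity is below
1.0, extended outward greedily while the running identity stays above
the threshold.  The highest-scoring disjoint pair wins; ties minimize
the LSC start coordinate.  A perfect palindrome (SSC of length zero) is
split into two adjacent copies.  Defaults: minimum repeat length 1000 bp;
identity 0.99 for real data, 1.0 for simulator output (where the two
repeat copies are identical by construction, as concerted evolution
keeps them in real plastomes).  Direct repeats are never returned.
Repeats spanning the sequence origin are not searched; rotate the record
first.  By convention the circle reads LSC → IRa → SSC → IRb and
|LSC| ≥ |SSC|; coordinates are 1-based inclusive everywhere.

### Canonical gene orders and inversions

Each genome's annotation is collapsed to a signed circular gene order:
genes sorted by position, IRb copies dropped (the IRa copy carries the
repeat-internal orientation), the order rotated and, if necessary,
reflected so a fixed anchor gene comes first with positive sign.  The
default anchor for single-genome reports is psbA; the pipeline
canonicalizes on ycf1 because the SSC is untouched by every large
rearrangement reported in fern plastomes, whereas psbA sits inside known
inversion spans — a linear frame anchored inside an inverted block would
turn one reversal into its circular complement.

A sample order is encoded against a reference as a signed permutation
over the shared genes; absentees are dropped and reported.  Inversion
scenarios are exact: maximal colinear runs collapse to blocks, and an
A* search over reversal space — with the admissible cycle bound
n + 1 − c of the breakpoint graph (a reversal changes the cycle count by
at most one) — returns a provably minimum-length reversal sequence.
Among co-optimal scenarios, a depth-first pass reports the
lexicographically first one, for determinism.  Caps (14 blocks, 6 events
per comparison, both configurable) return an explicit "unresolved"
status with the breakpoint distance rather than a guess.  Every returned
scenario is replayed and asserted to sort the permutation.

Branch placement is hierarchical, mirroring the stepwise protocol of
adding genomes along the tree: each internal node inherits its parent's
reconstructed order; each child subtree nominates its least-derived leaf
(minimal breakpoint distance, then fewest missing genes); a reversal is
charged to the branch only when every child subtree's delta contains it
(matched by span-gene set on the genes both representatives retain); the
node's order is the parent order with those shared reversals applied.
Leaf branches take their full remaining delta.  This keeps every search
instance small, where exactness is cheap, and resolves nested inversions
accumulated over successive branches without factorization ambiguity.

### Boundary shifts

Gene-to-region assignment distinguishes LSC/SSC/IR and boundary-partial
genes (some but not all exons inside the repeat, e.g. a two-exon gene
with only its second exon duplicated).  Against the reference
assignment, each gene that entered or left the repeat — and each partial
exon tag — becomes a binary character.  Mapping uses DELTRAN (below);
per-branch gains are then grouped into one boundary-shift event per
branch, with the side (LSC/SSC/both) read off the reference region of
the moved genes.

### Gene, intron and tRNA content

A protein-coding gene is compared with an intact reference copy by
global pairwise alignment (match 1, mismatch −1, gap open −4, extend −1).
Integrity is the fraction of reference positions covered by aligned
candidate bases; similarity is identity over aligned columns.  The gene
is lost when either metric falls below 0.70 (strict inequality; a
conjunctive variant is available as a switch).  Internal stop codons and
abnormal start/stop codons are recorded as notes but never trigger a
loss by themselves, because RNA editing routinely repairs such sites in
fern plastid transcripts.  One refinement: a candidate whose length
deficit is a frame-preserving internal deletion — reference covered end
to end with terminal aligned blocks of at least ten codons, similarity
at or above threshold — is a gene carrying a large in-frame indel, not a
pseudogene; it stays present (flagged `in-frame-indel`) and the deletion
is scored by the codon-indel stage instead.  Without this rule a
~1 kb in-frame deletion would masquerade as a gene loss while also being
an indel character.  Genes absent from the reference taxon itself (the
reference lineage may carry the loss under study) are scored against the
copy from the alphabetically first taxon still possessing them.

Losses observed in exactly one sample are demoted to ambiguous and
excluded from character building: one-off absences are more often
assembly or annotation artifacts than phylogenetic signal.

Intron loss is called per junction by matching sample exon parts to runs
of consecutive reference exons by cumulative length (tolerating 10% or
30 bp of indel drift): a fused span covering a junction means that
intron is gone.

tRNA loci are validated structurally rather than by similarity: a
candidate must fold into a cloverleaf — acceptor stem with at least 6 of
7 complementary pairs (G·U allowed), D- and T-arm stems of at least 3
pairs, anticodon stem of 4–5 fully paired bases around an exactly
7-nucleotide loop, with 0–4 trailing nucleotides — and the anticodon
(loop positions 2–4) must decode an amino acid matching the isotype in
the locus name (CAU is accepted for both methionine and isoleucine
isoacceptors, which differ by a base modification invisible in the
gene).  A folding, isotype-consistent locus whose anticodon differs from
the annotated one is an anticodon change; anything else is a
hypothetical loss.  This built-in validator approximates covariance
-model scoring with a deterministic structural test; it accepts all 30
packaged canonical fern tRNAs and rejects each of their
acceptor-scrambled counterparts.

### Codon indels

Coding sequences are aligned codon-wise by construction: translate,
align peptides, back-thread nucleotides, so every gap run is a whole
number of codons (a run that is not a codon multiple is a hard error).
The peptide alignment is a star alignment around the reference row with
BLOSUM62 scoring (open −11, extend −1).  Because equivalent gap
placements are score ties — and near-ties under substitution noise —
independently aligned rows can report one ancestral indel a few residues
apart or split a long gap around a chance match; a normalization pass
therefore snaps runs row-wise (same-length runs within 10 residues to
the majority start; split runs re-merged; a less widely shared run
adopting the start of a more widely shared neighbour, with ties going to
the shorter run, so stacked indels decompose cleanly).  Snapping moves
gap columns only; a row's sequence never changes.  Pseudogene rows are
excluded from the alignment so degraded copies cannot inject spurious
characters.

Maximal gap runs are decomposed into atomic sub-intervals at all run
boundaries; each atom is one indel with its carrier set.  Polarity is
provisionally assigned by majority state (ties toward deletion) and
re-expressed after tree mapping: a mapped "loss" of a minority state is
reported as the complementary event on that branch.  Indels carried by a
single taxon are flagged autapomorphic and excluded, consistent with the
singleton-loss policy.  Positions are reported both as alignment columns
and as reference-CDS coordinates.

### Parsimony mapping

Binary characters are mapped with a unit-cost dynamic programme over
node states, which equals Fitch length on bifurcating trees and stays
exact on polytomies; missing entries ('?') contribute no cost.
ACCTRAN/DELTRAN are tie-breaking rules in the top-down pass (change
early vs late); both resolutions always place exactly the minimal number
of changes.  Root-state ties resolve to absent, and the two root-adjacent
edges of a two-child rooted tree are folded onto the ingroup stem when
ledgers are compared (they are one unrooted edge).

Defaults per class: gene, intron and tRNA losses map under Dollo
parsimony (ancestrally present, unlimited independent losses, no
regain) — plastid genes are easy to lose and effectively impossible to
regain.  Boundary-shift and codon-indel characters map under DELTRAN
regardless of the global setting: repeat expansions recur independently
across lineages, and an exact back-mutation restoring deleted codons is
implausible, so ambiguous placements resolve as independent recurrences
rather than as a deep gain followed by reversals.  Inversions are placed
directly by the hierarchical branch inference.  The global default for
everything else is ACCTRAN, the conventional choice.  A change is a
synapomorphy when the character fits the tree in one step on an internal
branch, an autapomorphy on a terminal branch, homoplasy otherwise.
Event labels (V1…, R1…, …) are assigned per class in preorder.

## The simulator

The synthetic-data module is first-class, tested code: it defines the
conditions every end-to-end result refers to.

The ancestral genome is a fern-like quadripartite plastome built from a
fixed roster: 50 LSC genes, a 9-gene repeat hosting the rRNA cluster
(rrn16–rrn23–rrn4.5–rrn5 plus five tRNAs), 12 SSC genes; 30 tRNAs in
total; intron-bearing rps16, clpP (two introns), ndhA, ndhB and the
3' half of trans-spliced rps12.  Coding sequences are random sense
codons between ATG and TAA; tRNAs come from a generator that builds a
clean cloverleaf around any requested anticodon; spacers are uniform
random DNA.  Gene lengths follow typical plastid values where a fixture
depends on them (ycf2 5250 bp, rpoC2 2850 bp, matK and ndhB 1530 bp,
psbA 1062 bp, petA 963 bp, chlL 900 bp, rps4 606 bp, …).  Two presets:
`scaled` (60 bp spacers, ≈42 kb — the default for tests and the
packaged scenario) and `full` (1300 bp spacers, ≈150 kb).  The first and
last SSC bases are forced non-complementary so the exact repeat ends
precisely at the designed boundaries.

Evolution proceeds root-to-tip.  Explicit events are applied in listed
order per branch; each realized event is appended to a truth ledger, and
replaying the same inputs yields byte-identical genomes.  Inversions
reverse a contiguous block between two named genes (breakpoints in
spacers, strands flipped, same region only); boundary shifts move whole
genes between a single-copy tail and the adjacent repeat end, or split
the boundary gene so only its terminal exon is duplicated; gene losses
delete cleanly or pseudogenize (a frameshifting deletion of ~40% of the
CDS, leaving integrity near 0.60); tRNA events delete, scramble the
acceptor stem, or mutate the anticodon in place; codon indels apply
signed codon-multiple lengths at ancestral CDS coordinates, with
per-lineage offset bookkeeping and label-seeded insertion content so the
same event on two branches inserts identical sequence.  An event whose
target was destroyed earlier raises a ledger error naming the event.

Background substitutions are single-parameter (Jukes–Cantor-style)
per-site replacements on coding, rRNA, intron and spacer positions,
default 0.01 per site per branch in the packaged scenario.  tRNAs are
exempt: plastid tRNAs evolve under strong structural purifying
selection, and since the validator downstream treats any broken
cloverleaf as a loss, neutral noise there would amount to injecting
unledgered T events.  A Poisson rate mode draws event counts per branch
for open-ended property tests.

### The packaged family-level scenario

`figure2_scenario` encodes a fern family-level topology — 25 families,
two sampled leaves each (the singleton filter operates at sample level,
as in multi-accession studies), one outgroup — and 52 branch-placed
events: 9 inversions, 7 boundary shifts, 10 gene/intron losses, 6 tRNA
losses plus one anticodon change, and 19 codon indels whose positions
and signed lengths follow the published table for this system (+138,
−15, +9, −3, −108, +24, −9, −6, −1032, −84, +6, −6, −9 twice, −9, −12,
−63, +6, +21, +6).  Event placements stated only ambiguously in prose
carry `placement_stated=False` in the fixture (the Polypodiales-level
boundary shift; several deep tRNA-loss branches; which part of ndhB one
expansion covers).  Three fixture-level reconciliations are deliberate:
the Hymenophyllaceae repeat expansion excludes trnL-CAA because that
tRNA is independently lost in the same lineage; the repeat-internal
inversion of the rRNA cluster is encoded with the repeat's own terminal
tRNAs as flanks; and the large LSC inversion of the
Dipteridaceae–Matoniaceae–Schizaeales–core-leptosporangiate clade is
encoded psbA→rpoC2 so that ndhB stays at the boundary for the partial
exon-2 expansion that accompanies it.  A second topology,
`gleicheniales_monophyletic_newick`, differs only in making
Gleicheniales monophyletic; on it the V5-distribution character costs
two steps instead of one — the "reversed inversion" argument for
Gleicheniales paraphyly, reproduced as a computation.

## What passing tests do and do not show

The simulator produces clean annotations, identical repeat copies,
uniform substitution rates, and indels/inversions placed away from each
other except where the scenario stacks them on purpose.  Full ledger
recovery under these conditions demonstrates that the machinery is
correct and exact at desk scale; it does not demonstrate robustness to
mis-annotation, assembly artifacts, repeat-copy divergence, highly
repetitive spacers, saturated substitution levels, or inversions with
breakpoints inside genes (explicitly out of scope).  The
boundary-accuracy guarantee (±0 bp) holds at identity 1.0; below that,
greedy extension can overshoot by up to the mismatch budget.

## Numerical and procedural choices

* Problem sizes: the packaged scenario uses the `scaled` preset
  (51 leaves × ≈42 kb) and sub_rate 0.01; the oracle-agreement checks use
  500 random signed permutations of length ≤ 8 and 200 random characters
  on trees of ≤ 8 leaves.
* The reversal-distance oracle used in the acceptance checks is the
  breakpoint-graph closed form d = n + 1 − c + h (cycles, hurdles:
  minimal unoriented components plus a greatest component enclosing all
  others; fortresses cannot arise at these sizes).  It is cross-validated
  against exhaustive breadth-first search over all permutations of
  length ≤ 4 and random samples at lengths 5–6 in the test suite, and is
  independent of the package's A* search.
* Thresholds: loss 0.70 (strict), repeat ≥ 1000 bp, identity 1.0 for
  simulated genomes, inversion caps 14 blocks / 6 events, indel snap
  window 10 residues.  Recovery scoring tolerates 15 bp of
  indel-position drift (gap-placement ties under noise shift reported
  positions by one or two codons) and accepts one long indel reported
  as co-located fragments whose signed lengths sum to it (a score-tie
  in a single row's pairwise path can split an insertion block).
* Determinism: every random draw is seeded; per-branch and per-purpose
  RNG streams are derived from (seed, label) pairs, so ledgers replay
  byte-identically across runs and platforms.

## Known limitations

Direct-repeat genome architectures, heteroplasmy and flip-flop SSC
orientation isomers are out of scope.  Translocations and transpositions
are not primitive events; a gene order needing them comes back
"unresolved" rather than force-fitted.  The tRNA validator is a
structural approximation, not a covariance model; borderline real loci
deserve external confirmation.  The family-collapse behaviour of the
published analysis is represented by sampling two concordant leaves per
family rather than by a separate collapse step; polymorphic families
would map at sample level.
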