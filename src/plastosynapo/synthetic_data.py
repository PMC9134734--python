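"""Plastome evolution simulator with a replayable truth ledger.

The simulator builds an ancestral fern-like quadripartite plastome
(a gene roster laid out as LSC | IRa | SSC | IRb with the rRNA cluster in
the repeat) and evolves it along a rooted tree, applying branch-placed
events of five classes:

* V - large inversions (reversal of a contiguous gene block, breakpoints
  in intergenic spacers, strands flipped);
* R - inverted-repeat boundary shifts (whole genes duplicated into or
  released from the repeat; optionally only the terminal exon of the
  boundary gene, producing a boundary-partial gene);
* G - protein-coding gene loss (clean deletion or pseudogenization that
  degrades ORF integrity below the 0.70 loss threshold) and intron loss;
* T - tRNA loss, structural scrambling, or anticodon mutation;
* D - in-frame codon indels (signed lengths, multiples of 3), positioned
  in ancestral CDS coordinates;

plus Jukes-Cantor-style background substitutions on CDS, rRNA, intron and
spacer sequence.  tRNA genes receive no background substitutions: plastid
tRNAs are under strong structural purifying selection, and the structural
validator downstream treats any broken cloverleaf as a loss event, so
neutral noise there would amount to injecting unledgered T events.

Every realized event is recorded in a :class:`TruthLedger`; replaying the
same (spec, events, seed) gives byte-identical leaf genomes.  The packaged
:func:`figure2_scenario` encodes a family-level fern phylogeny carrying 9
inversions, 7 boundary shifts, 10 gene/intron losses, 7 tRNA events and 19
codon indels on their stated branches, two sampled leaves per family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .plastome_io import GeneFeature, GeneSymbol, GenomeRecord, normalize_gene_symbol
from .parsimony_map import Phylogeny

__all__ = [
    "RosterGene",
    "AncestralSpec",
    "EventSpec",
    "TruthLedger",
    "ancestral_spec",
    "build_ancestral_genome",
    "evolve",
    "figure2_scenario",
    "figure2_tree_newick",
    "gleicheniales_monophyletic_newick",
    "make_quadripartite",
    "canonical_trna",
    "scramble_trna",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE = [c for c in _CODONS if c not in _STOPS and c != "ATG"]


def _rng(*keys) -> np.random.Generator:
    seeds = []
    for k in keys:
        if isinstance(k, str):
            seeds.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            seeds.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(seeds)


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_cds(rng, n: int) -> str:
    assert n % 3 == 0 and n >= 9
    body = "".join(rng.choice(_SENSE, size=n // 3 - 2))
    return "ATG" + body + "TAA"


# ---------------------------------------------------------------------------
# tRNA sequence design

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _stem_pair(rng, n: int) -> tuple[str, str]:
    five = "".join(rng.choice(list("ACGT"), size=n))
    three = "".join(_WC[b] for b in reversed(five))
    return five, three


def canonical_trna(anticodon: str, rng=None) -> tuple[str, int]:
    """Design a DNA tRNA gene with a clean cloverleaf and the given
    anticodon.  Returns (sequence, 0-based anticodon offset)."""
    if rng is None:
        rng = _rng("trna", anticodon)
    ac_dna = anticodon.replace("U", "T")
    while True:
        a5, a3 = _stem_pair(rng, 7)
        d5, d3 = _stem_pair(rng, 4)
        c5, c3 = _stem_pair(rng, 5)
        t5, t3 = _stem_pair(rng, 5)
        d_loop = _random_dna(rng, 8)
        t_loop = _random_dna(rng, 7)
        ac_loop = "CT" + ac_dna + "AA"
        seq = a5 + "T" + d5 + d_loop + d3 + "A" + c5 + ac_loop + c3 + t5 + t_loop + t3 + a3 + "A"
        ac_off = len(a5) + 1 + 2 * len(d5) + len(d_loop) + 1 + len(c5) + 2
        from .gene_content import validate_trna  # local import avoids a cycle

        sym = GeneSymbol("trnX", anticodon)
        v = validate_trna(seq, sym)
        if v.structure_pass and v.anticodon_observed == anticodon:
            return seq, ac_off


def scramble_trna(sequence: str) -> str:
    """Destroy the acceptor stem (both arms to poly-A), keeping length."""
    return "A" * 7 + sequence[7:-8] + "A" * 8


# ---------------------------------------------------------------------------
# Ancestral roster

@dataclass(frozen=True)
class RosterGene:
    name: str
    kind: str  # CDS | tRNA | rRNA
    region: str  # LSC | IR | SSC
    exons: tuple[int, ...]
    introns: tuple[int, ...] = ()
    strand: str = "+"
    anticodon: str | None = None
    part: str | None = None

    @property
    def symbol(self) -> GeneSymbol:
        return GeneSymbol(self.name, self.anticodon, self.part)


def _t(name: str, region: str = "LSC") -> RosterGene:
    base, ac = name.rsplit("-", 1)
    return RosterGene(base, "tRNA", region, (72,), anticodon=ac.replace("T", "U"))


_LSC_ROSTER: tuple[RosterGene, ...] = (
    _t("trnH-GUG"),
    RosterGene("psbA", "CDS", "LSC", (1062,), strand="-"),
    RosterGene("matK", "CDS", "LSC", (1530,)),
    _t("trnK-UUU"),
    RosterGene("rps16", "CDS", "LSC", (120, 270), (200,), strand="-"),
    _t("trnQ-UUG"),
    _t("trnS-GCU"),
    _t("trnG-GCC"),
    RosterGene("atpA", "CDS", "LSC", (300,), strand="-"),
    _t("trnR-UCU"),
    _t("trnT-GGU"),
    RosterGene("rps12", "CDS", "LSC", (114,), strand="-", part="5p"),
    RosterGene("rps4", "CDS", "LSC", (606,)),
    _t("trnT-UGU"),
    _t("trnL-UAA"),
    _t("trnF-GAA"),
    RosterGene("ndhJ", "CDS", "LSC", (300,), strand="-"),
    RosterGene("ndhK", "CDS", "LSC", (300,), strand="-"),
    RosterGene("ndhC", "CDS", "LSC", (300,), strand="-"),
    _t("trnV-UAC"),
    _t("trnM-CAU"),
    RosterGene("atpE", "CDS", "LSC", (300,)),
    _t("trnS-CGA"),
    _t("trnS-UGA"),
    RosterGene("psbB", "CDS", "LSC", (300,)),
    _t("trnD-GUC"),
    _t("trnY-GUA"),
    _t("trnE-UUC"),
    _t("trnC-GCA"),
    RosterGene("psbM", "CDS", "LSC", (120,), strand="-"),
    RosterGene("ycf12", "CDS", "LSC", (300,)),
    RosterGene("psaM", "CDS", "LSC", (120,)),
    RosterGene("chlB", "CDS", "LSC", (300,)),
    RosterGene("chlL", "CDS", "LSC", (900,)),
    RosterGene("chlN", "CDS", "LSC", (300,)),
    RosterGene("petA", "CDS", "LSC", (963,)),
    _t("trnW-CCA"),
    _t("trnP-UGG"),
    RosterGene("clpP", "CDS", "LSC", (69, 294, 228), (150, 150), strand="-"),
    _t("trnG-UCC"),
    RosterGene("rpoC2", "CDS", "LSC", (2850,)),
    RosterGene("ycf94", "CDS", "LSC", (300,)),
    _t("trnI-CAU"),
    _t("trnR-CCG"),
    _t("trnfM-CAU"),
    RosterGene("ycf2", "CDS", "LSC", (5250,)),
    _t("trnL-CAA"),
    RosterGene("rps12", "CDS", "LSC", (120, 114), (150,), part="3p"),
    RosterGene("rps7", "CDS", "LSC", (468,)),
    RosterGene("ndhB", "CDS", "LSC", (774, 756), (200,)),
)

_IR_ROSTER: tuple[RosterGene, ...] = (
    _t("trnV-GAC", "IR"),
    _t("trnI-GAU", "IR"),
    _t("trnA-UGC", "IR"),
    RosterGene("rrn16", "rRNA", "IR", (1490,)),
    RosterGene("rrn23", "rRNA", "IR", (2810,)),
    RosterGene("rrn4.5", "rRNA", "IR", (100,)),
    RosterGene("rrn5", "rRNA", "IR", (120,)),
    _t("trnR-ACG", "IR"),
    _t("trnN-GUU", "IR"),
)

_SSC_ROSTER: tuple[RosterGene, ...] = (
    RosterGene("psaC", "CDS", "SSC", (246,), strand="-"),
    RosterGene("rpl32", "CDS", "SSC", (171,)),
    RosterGene("ndhF", "CDS", "SSC", (300,), strand="-"),
    RosterGene("ccsA", "CDS", "SSC", (300,)),
    RosterGene("ndhD", "CDS", "SSC", (300,), strand="-"),
    RosterGene("ndhE", "CDS", "SSC", (300,), strand="-"),
    RosterGene("ndhG", "CDS", "SSC", (300,), strand="-"),
    RosterGene("ndhI", "CDS", "SSC", (300,), strand="-"),
    RosterGene("ndhA", "CDS", "SSC", (540, 540), (180,), strand="-"),
    RosterGene("ndhH", "CDS", "SSC", (300,), strand="-"),
    RosterGene("rps15", "CDS", "SSC", (273,)),
    RosterGene("ycf1", "CDS", "SSC", (1500,)),
)


@dataclass
class AncestralSpec:
    """Ancestral genome blueprint: ordered roster + spacer sizing."""

    lsc: tuple[RosterGene, ...] = _LSC_ROSTER
    ir: tuple[RosterGene, ...] = _IR_ROSTER
    ssc: tuple[RosterGene, ...] = _SSC_ROSTER
    spacer_len: int = 60
    preset: str = "scaled"

    @property
    def roster(self) -> tuple[RosterGene, ...]:
        return self.lsc + self.ir + self.ssc

    def n_genes(self) -> int:
        return len(self.roster)


def ancestral_spec(preset: str = "scaled") -> AncestralSpec:
    """Packaged presets: ``scaled`` (~35 kb, fast tests) and ``full``
    (~150 kb via proportionally longer intergenic spacers)."""
    if preset == "scaled":
        return AncestralSpec(spacer_len=60, preset="scaled")
    if preset == "full":
        return AncestralSpec(spacer_len=1300, preset="full")
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Mutable genome state

@dataclass
class Element:
    kind: str  # CDS | tRNA | rRNA | spacer
    symbol: GeneSymbol | None
    strand: str
    exons: list[str]
    introns: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def clone(self) -> "Element":
        meta = {k: (list(v) if isinstance(v, list) else v)
                for k, v in self.meta.items()}
        return Element(self.kind, self.symbol, self.strand, list(self.exons),
                       list(self.introns), meta)

    @property
    def is_gene(self) -> bool:
        return self.kind != "spacer"

    def cds(self) -> str:
        return "".join(self.exons)


@dataclass
class GenomeState:
    lsc: list[Element]
    ir: list[Element]
    ssc: list[Element]
    ir_partial: bool = False  # last LSC gene's last exon lies inside the IR

    def clone(self) -> "GenomeState":
        return GenomeState([e.clone() for e in self.lsc],
                           [e.clone() for e in self.ir],
                           [e.clone() for e in self.ssc], self.ir_partial)

    def regions(self):
        return (("LSC", self.lsc), ("IR", self.ir), ("SSC", self.ssc))

    def find_gene(self, symbol: GeneSymbol):
        for rname, elems in self.regions():
            for i, e in enumerate(elems):
                if e.is_gene and e.symbol == symbol:
                    return rname, i
        return None, None


def _spacer(rng, n: int) -> Element:
    return Element("spacer", None, "+", [_random_dna(rng, n)])


def _gene_element(rng, g: RosterGene) -> Element:
    if g.kind == "CDS":
        total = sum(g.exons)
        cds = _random_cds(rng, total)
        exons, p = [], 0
        for ln in g.exons:
            exons.append(cds[p : p + ln])
            p += ln
        introns = [_random_dna(rng, ln) for ln in g.introns]
        return Element("CDS", g.symbol, g.strand, exons, introns)
    if g.kind == "tRNA":
        seq, off = canonical_trna(g.anticodon, _rng("trna", g.name, g.anticodon))
        return Element("tRNA", g.symbol, g.strand, [seq], meta={"ac_offset": off})
    return Element("rRNA", g.symbol, g.strand, [_random_dna(rng, g.exons[0])])


def _initial_state(spec: AncestralSpec, seed: int) -> GenomeState:
    rng = _rng(seed, "ancestral")

    def region(roster):
        elems = [_spacer(rng, spec.spacer_len)]
        for g in roster:
            elems.append(_gene_element(rng, g))
            elems.append(_spacer(rng, spec.spacer_len))
        return elems

    return GenomeState(region(spec.lsc), region(spec.ir), region(spec.ssc))


# ---------------------------------------------------------------------------
# Building a GenomeRecord from a state

def _gene_block(e: Element) -> tuple[str, list[tuple[int, int]]]:
    """Physical block sequence and relative exon spans (0-based, genome
    order) for a gene element."""
    parts = []
    seq_parts = []
    p = 0
    for i, ex in enumerate(e.exons):
        seq_parts.append(ex)
        parts.append((p, p + len(ex) - 1))
        p += len(ex)
        if i < len(e.introns):
            seq_parts.append(e.introns[i])
            p += len(e.introns[i])
    block = "".join(seq_parts)
    if e.strand == "-":
        n = len(block)
        block = str(Seq(block).reverse_complement())
        parts = [(n - 1 - b, n - 1 - a) for a, b in parts][::-1]
    return block, parts


def _feature_for(e: Element, offset: int, block_parts) -> GeneFeature:
    spans = [(offset + a + 1, offset + b + 1, e.strand) for a, b in block_parts]
    if e.strand == "-":
        spans = spans[::-1]  # 5'->3' on the coding strand
    return GeneFeature(symbol=e.symbol, kind=e.kind, parts=spans)


def build_genome(state: GenomeState, record_id: str) -> GenomeRecord:
    """Assemble sequence + annotation: LSC | IRa | SSC | IRb(=revcomp IRa).

    IRb copies of IR genes are annotated with mirrored coordinates; the
    IRb copy of a boundary-partial exon is left unannotated, as in real
    submissions.  The first/last SSC bases are forced non-complementary so
    the exact repeat ends exactly at the designed boundaries.
    """
    chunks: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0

    def emit(e: Element):
        nonlocal pos
        if e.is_gene:
            block, parts = _gene_block(e)
            feats.append(_feature_for(e, pos, parts))
            chunks.append(block)
            pos += len(block)
        else:
            chunks.append(e.exons[0])
            pos += len(e.exons[0])

    lsc_elems = list(state.lsc)
    partial_gene = None
    if state.ir_partial:
        gi = max(i for i, e in enumerate(lsc_elems) if e.is_gene)
        partial_gene = lsc_elems[gi]
        trailing = lsc_elems[gi + 1 :]
        lsc_elems = lsc_elems[:gi]
        if partial_gene.strand != "+" or len(partial_gene.exons) < 2:
            raise ValueError("boundary-partial gene must be + strand with >= 2 exons")
    for e in lsc_elems:
        emit(e)
    ira_start = None
    if partial_gene is not None:
        # exons[:-1] (+ introns) stay in the LSC; the last exon opens the IR
        head = Element(partial_gene.kind, partial_gene.symbol, "+",
                       partial_gene.exons[:-1], partial_gene.introns)
        hblock, hparts = _gene_block(head)
        ira_start = pos + len(hblock)
        last = partial_gene.exons[-1]
        spans = [(pos + a + 1, pos + b + 1, "+") for a, b in hparts]
        spans.append((ira_start + 1, ira_start + len(last), "+"))
        feats.append(GeneFeature(symbol=partial_gene.symbol, kind=partial_gene.kind,
                                 parts=spans))
        chunks.append(hblock + last)
        pos += len(hblock) + len(last)
        for e in trailing:
            emit(e)
    else:
        ira_start = pos
    ira_feat_start = len(feats)
    for e in state.ir:
        emit(e)
    ira_end = pos  # exclusive
    ira_seq = "".join(chunks)[ira_start:]
    ssc_start = pos
    for e in state.ssc:
        emit(e)
    ssc_end = pos
    # IRb
    irb_seq = str(Seq(ira_seq).reverse_complement())
    chunks.append(irb_seq)
    n_total = pos + len(irb_seq)
    for f in list(feats[ira_feat_start:]):
        if f.parts[0][0] <= ira_start or f.parts[0][0] > ira_end:
            continue
        mirrored = []
        for s, e0, st in f.parts:
            ms = ssc_end + (ira_end - e0) + 1
            me = ssc_end + (ira_end - s) + 1
            mirrored.append((ms, me, "-" if st == "+" else "+"))
        feats.append(GeneFeature(symbol=f.symbol, kind=f.kind, parts=mirrored))
    seq = "".join(chunks)
    # break chance complementarity across the IRa|SSC vs SSC|IRb junction
    if ssc_end > ssc_start:
        s = list(seq)
        first, last = s[ssc_start], s[ssc_end - 1]
        if _WC[first] == last:
            s[ssc_start] = {"A": "C", "C": "A", "G": "T", "T": "G"}[first]
        seq = "".join(s)
    assert len(seq) == n_total
    feats.sort(key=lambda f: f.parts[0][0])
    return GenomeRecord(id=record_id, sequence=seq, features=feats)


def build_ancestral_genome(spec: AncestralSpec, seed: int) -> GenomeRecord:
    """Ancestral quadripartite genome for a spec (deterministic in seed)."""
    if not spec.roster:
        raise ValueError("empty gene roster")
    return build_genome(_initial_state(spec, seed), "ancestral")


# ---------------------------------------------------------------------------
# Events

@dataclass
class EventSpec:
    label: str
    cls: str  # V | R | G | T | D
    branch: str  # child-node label of the branch the event acts on
    params: dict
    placement_stated: bool = True


@dataclass
class RealizedEvent:
    label: str
    cls: str
    branch: str
    detail: dict


@dataclass
class TruthLedger:
    seed: int
    events: list[RealizedEvent] = field(default_factory=list)

    def by_class(self, cls: str) -> list[RealizedEvent]:
        return [e for e in self.events if e.cls == cls]

    def labels(self) -> set[str]:
        return {e.label for e in self.events}


class LedgerError(ValueError):
    pass


def _gene_indices(elems: list[Element]):
    return [i for i, e in enumerate(elems) if e.is_gene]


def _apply_inversion(state: GenomeState, ev: EventSpec) -> dict:
    left = _sym(ev.params["left"])
    right = _sym(ev.params["right"])
    rl, il = state.find_gene(left)
    rr, ir_ = state.find_gene(right)
    if il is None or ir_ is None:
        missing = left if il is None else right
        raise LedgerError(
            f"{ev.label}: inversion endpoint {missing} absent (destroyed by an earlier event?)")
    if rl != rr:
        raise LedgerError(f"{ev.label}: endpoints lie in different regions ({rl} vs {rr})")
    elems = dict(state.regions())[rl]
    i, j = sorted((il, ir_))
    if state.ir_partial and rl == "LSC":
        last_gene = max(_gene_indices(state.lsc))
        if j >= last_gene:
            raise LedgerError(f"{ev.label}: inversion would break the boundary-partial gene")
    seg = elems[i : j + 1]
    flipped = []
    for e in reversed(seg):
        c = e.clone()
        if c.is_gene:
            c.strand = "+" if c.strand == "-" else "-"
        else:
            c.exons = [str(Seq(c.exons[0]).reverse_complement())]
        flipped.append(c)
    elems[i : j + 1] = flipped
    span = [str(e.symbol) for e in seg if e.is_gene]
    return {"region": rl, "span_genes": span, "left": str(left), "right": str(right)}


def _apply_boundary_shift(state: GenomeState, ev: EventSpec) -> dict:
    mode = ev.params["mode"]
    if mode == "partial_lsc":
        if state.ir_partial:
            raise LedgerError(f"{ev.label}: boundary-partial already set")
        gi = max(_gene_indices(state.lsc))
        g = state.lsc[gi]
        if g.strand != "+" or len(g.exons) < 2:
            raise LedgerError(f"{ev.label}: boundary gene {g.symbol} cannot be split")
        state.ir_partial = True
        part = f"exon{len(g.exons)}"
        return {"gained": [], "partial": [(str(g.symbol), part)], "side": "LSC"}
    n = int(ev.params["n_genes"])
    if mode == "expand_lsc":
        gidx = _gene_indices(state.lsc)
        if len(gidx) < n + 1:
            raise LedgerError(f"{ev.label}: not enough LSC genes to expand over")
        cut = gidx[-n]
        moved = state.lsc[cut:]
        del state.lsc[cut:]
        state.ir[0:0] = moved
        gained = [str(e.symbol) for e in moved if e.is_gene]
        if state.ir_partial:
            raise LedgerError(f"{ev.label}: LSC expansion over a boundary-partial gene")
        return {"gained": gained, "partial": [], "side": "LSC"}
    if mode == "expand_ssc":
        gidx = _gene_indices(state.ssc)
        if len(gidx) < n + 1:
            raise LedgerError(f"{ev.label}: not enough SSC genes to expand over")
        cut = gidx[n - 1] + 1
        moved = state.ssc[:cut]
        del state.ssc[:cut]
        state.ir.extend(moved)
        gained = [str(e.symbol) for e in moved if e.is_gene]
        return {"gained": gained, "partial": [], "side": "SSC"}
    raise LedgerError(f"{ev.label}: unknown boundary-shift mode {mode}")


def _apply_gene_event(state: GenomeState, ev: EventSpec, seed: int) -> dict:
    sym = _sym(ev.params["gene"])
    region, i = state.find_gene(sym)
    if i is None:
        raise LedgerError(f"{ev.label}: gene {sym} absent")
    elems = dict(state.regions())[region]
    if "intron" in ev.params:
        k = int(ev.params["intron"])
        g = elems[i]
        if len(g.introns) < k:
            raise LedgerError(f"{ev.label}: {sym} has no intron {k}")
        g.introns.pop(k - 1)
        g.exons[k - 1 : k + 1] = [g.exons[k - 1] + g.exons[k]]
        return {"gene": str(sym), "intron": k, "mode": "intron-loss"}
    mode = ev.params.get("mode", "delete")
    if mode == "delete":
        del elems[i]
        return {"gene": str(sym), "mode": "delete", "region": region}
    if mode == "pseudogenize":
        # frameshifting deletion of ~40% of the CDS: the remnant keeps high
        # local similarity but integrity drops to ~0.60 and the ORF breaks
        g = elems[i]
        cds = g.cds()
        n = len(cds)
        start = (n // 3) // 3 * 3
        del_len = int(0.40 * n) // 3 * 3 + 1  # +1 shifts the frame
        g.exons = [cds[:start] + cds[start + del_len :]]
        g.introns = []
        return {"gene": str(sym), "mode": "pseudogenize", "region": region}
    raise LedgerError(f"{ev.label}: unknown gene-event mode {mode}")


def _apply_trna_event(state: GenomeState, ev: EventSpec) -> dict:
    sym = _sym(ev.params["trna"])
    region, i = state.find_gene(sym)
    if i is None:
        raise LedgerError(f"{ev.label}: tRNA {sym} absent")
    elems = dict(state.regions())[region]
    mode = ev.params.get("mode", "delete")
    if mode == "delete":
        del elems[i]
        return {"trna": str(sym), "mode": "delete"}
    g = elems[i]
    if mode == "scramble":
        g.exons = [scramble_trna(g.exons[0])]
        return {"trna": str(sym), "mode": "scramble"}
    if mode == "anticodon":
        new = ev.params["new_anticodon"].replace("U", "T")
        off = g.meta["ac_offset"]
        s = g.exons[0]
        g.exons = [s[:off] + new + s[off + 3 :]]
        return {"trna": str(sym), "mode": "anticodon",
                "new_anticodon": ev.params["new_anticodon"]}
    raise LedgerError(f"{ev.label}: unknown tRNA-event mode {mode}")


def _apply_codon_indel(state: GenomeState, ev: EventSpec, seed: int) -> dict:
    sym = _sym(ev.params["gene"])
    region, i = state.find_gene(sym)
    if i is None:
        raise LedgerError(f"{ev.label}: gene {sym} absent")
    g = dict(state.regions())[region][i]
    anc_pos = int(ev.params["pos"])  # 1-based ancestral CDS coordinate
    length = int(ev.params["length"])
    if length % 3:
        raise LedgerError(f"{ev.label}: indel length {length} not a codon multiple")
    applied = g.meta.setdefault("indels", [])
    shift = sum(l for p, l in applied if p < anc_pos)
    cur = anc_pos + shift  # 1-based current CDS coordinate
    cds = g.cds()
    if length < 0:
        if cur - 1 + (-length) > len(cds):
            raise LedgerError(f"{ev.label}: deletion runs past the CDS end")
        new = cds[: cur - 1] + cds[cur - 1 - length :]
    else:
        rng = _rng(seed, "indel", ev.label)
        ins = "".join(rng.choice(_SENSE, size=length // 3))
        new = cds[: cur - 1] + ins + cds[cur - 1 :]
    # re-split into the existing exon-length layout, adjusting the exon
    # containing the indel
    lens = [len(x) for x in g.exons]
    acc, k = 0, 0
    for k, ln in enumerate(lens):
        if cur - 1 < acc + ln or k == len(lens) - 1:
            break
        acc += ln
    lens[k] += length if length > 0 else length
    exons, p = [], 0
    for ln in lens:
        exons.append(new[p : p + ln])
        p += ln
    assert p == len(new), "indel must fall inside a single exon"
    g.exons = exons
    applied.append((anc_pos, length))
    return {"gene": str(sym), "pos": anc_pos, "length": length}


def _sym(s) -> GeneSymbol:
    if isinstance(s, GeneSymbol):
        return s
    return normalize_gene_symbol(s, "tRNA" if s.startswith("trn") else "CDS")


def _substitute(state: GenomeState, rate: float, rng: np.random.Generator) -> None:
    """JC-style background substitutions on CDS/rRNA/intron/spacer sites.

    tRNA elements are skipped (structural purifying selection; see module
    docstring)."""
    if rate <= 0:
        return
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for _, elems in state.regions():
        for e in elems:
            if e.kind == "tRNA":
                continue
            seqs = e.exons if e.is_gene else e.exons
            new_exons = [_mutate_seq(s, rate, rng, alphabet) for s in e.exons]
            e.exons = new_exons
            e.introns = [_mutate_seq(s, rate, rng, alphabet) for s in e.introns]
            del seqs


def _mutate_seq(s: str, rate: float, rng, alphabet) -> str:
    if not s:
        return s
    arr = np.frombuffer(s.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return s
    repl = alphabet[rng.integers(0, 4, size=len(hits))]
    arr[hits] = repl
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Evolution along a tree

def evolve(
    tree: Phylogeny,
    spec: AncestralSpec | None = None,
    events: list[EventSpec] | None = None,
    rates: dict | None = None,
    sub_rate: float = 0.0,
    seed: int = 0,
):
    """Evolve the ancestral genome along ``tree`` root-to-tip.

    Explicit ``events`` (keyed by child-node label, applied in listed
    order per branch) are exactly reproducible; ``rates`` draws per-branch
    Poisson event counts instead.  Returns ``({leaf: GenomeRecord},
    TruthLedger)``.  An event whose target was destroyed by an earlier
    event raises :class:`LedgerError` naming the event.
    """
    if spec is None:
        spec = ancestral_spec("scaled")
    if events is None and rates is None:
        events = []
    node_labels = {n.plabel for n in tree.preorder()}
    by_branch: dict[str, list[EventSpec]] = {}
    for ev in events or []:
        if ev.branch not in node_labels:
            raise LedgerError(f"{ev.label}: branch {ev.branch!r} not in the tree")
        by_branch.setdefault(ev.branch, []).append(ev)
    ledger = TruthLedger(seed=seed)
    states = {id(tree.root): _initial_state(spec, seed)}
    leaves: dict[str, GenomeRecord] = {}
    for node in tree.preorder():
        if node is tree.root:
            state = states[id(node)]
        else:
            state = states[id(node.parent_node)].clone()
            for ev in by_branch.get(node.plabel, []):
                detail = _apply_event(state, ev, seed)
                ledger.events.append(RealizedEvent(ev.label, ev.cls, node.plabel, detail))
            if rates:
                _apply_rate_events(state, node.plabel, rates, seed, ledger)
            _substitute(state, sub_rate, _rng(seed, "subs", node.plabel))
            states[id(node)] = state
        if node.is_leaf():
            leaves[node.plabel] = build_genome(state, node.plabel)
    return leaves, ledger


def _apply_event(state: GenomeState, ev: EventSpec, seed: int) -> dict:
    if ev.cls == "V":
        return _apply_inversion(state, ev)
    if ev.cls == "R":
        return _apply_boundary_shift(state, ev)
    if ev.cls == "G":
        return _apply_gene_event(state, ev, seed)
    if ev.cls == "T":
        return _apply_trna_event(state, ev)
    if ev.cls == "D":
        return _apply_codon_indel(state, ev, seed)
    raise LedgerError(f"{ev.label}: unknown event class {ev.cls}")


def _apply_rate_events(state, branch: str, rates: dict, seed: int, ledger: TruthLedger):
    rng = _rng(seed, "rates", branch)
    k = 0
    for cls, rate in sorted(rates.items()):
        for _ in range(rng.poisson(rate)):
            k += 1
            label = f"{cls}@{branch}#{k}"
            try:
                ev = _draw_event(state, cls, label, branch, rng)
            except LedgerError:
                continue
            if ev is None:
                continue
            detail = _apply_event(state, ev, seed)
            ledger.events.append(RealizedEvent(label, cls, branch, detail))


def _draw_event(state, cls, label, branch, rng) -> EventSpec | None:
    lsc_genes = [e for e in state.lsc if e.is_gene]
    if cls == "V":
        if len(lsc_genes) < 3:
            return None
        i, j = sorted(rng.choice(len(lsc_genes), size=2, replace=False))
        if i == j:
            return None
        return EventSpec(label, "V", branch,
                         {"left": str(lsc_genes[i].symbol), "right": str(lsc_genes[j].symbol)})
    if cls == "G":
        cands = [e for e in lsc_genes if e.kind == "CDS"]
        if not cands:
            return None
        g = cands[int(rng.integers(0, len(cands)))]
        return EventSpec(label, "G", branch, {"gene": str(g.symbol), "mode": "delete"})
    if cls == "T":
        cands = [e for e in lsc_genes if e.kind == "tRNA"]
        if not cands:
            return None
        g = cands[int(rng.integers(0, len(cands)))]
        return EventSpec(label, "T", branch, {"trna": str(g.symbol), "mode": "delete"})
    if cls == "D":
        cands = [e for e in lsc_genes if e.kind == "CDS" and len(e.exons) == 1
                 and len(e.cds()) >= 60]
        if not cands:
            return None
        g = cands[int(rng.integers(0, len(cands)))]
        n = len(g.cds())
        pos = int(rng.integers(1, n // 3 - 8)) * 3 + 1
        length = int(rng.integers(1, 5)) * 3 * (1 if rng.random() < 0.5 else -1)
        return EventSpec(label, "D", branch, {"gene": str(g.symbol), "pos": pos,
                                              "length": length})
    return None


# ---------------------------------------------------------------------------
# Constructed quadripartite genomes (IR-detection fixtures)

def make_quadripartite(seed: int, lsc_len: int = 10000, ir_len: int = 3000,
                       ssc_len: int = 2000) -> tuple[GenomeRecord, dict]:
    """Random genome LSC | IRa | SSC | IRb with known coordinates.

    Junction bases are forced non-complementary so the maximal exact
    repeat equals the construction exactly.  Returns (record, truth) with
    truth coordinates 1-based inclusive.
    """
    rng = _rng(seed, "quad")
    lsc = _random_dna(rng, lsc_len)
    ira = _random_dna(rng, ir_len)
    ssc = _random_dna(rng, ssc_len)
    irb = str(Seq(ira).reverse_complement())

    def uncomp(x: str) -> str:
        return {"A": "C", "C": "A", "G": "T", "T": "G"}[x]

    if ssc_len:
        if _WC[ssc[0]] == ssc[-1]:
            ssc = uncomp(ssc[0]) + ssc[1:]
    if lsc_len:
        # LSC end abuts IRa start; LSC start abuts IRb end (circle)
        if _WC[lsc[-1]] == lsc[0]:
            lsc = lsc[:-1] + uncomp(_WC[lsc[0]])
    seq = lsc + ira + ssc + irb
    truth = {
        "lsc": (1, lsc_len),
        "ira": (lsc_len + 1, lsc_len + ir_len),
        "ssc": (lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len) if ssc_len else (0, -1),
        "irb": (lsc_len + ir_len + ssc_len + 1, lsc_len + 2 * ir_len + ssc_len),
        "ir_length": ir_len,
    }
    return GenomeRecord(id=f"quad{seed}", sequence=seq, features=[]), truth


# ---------------------------------------------------------------------------
# The packaged family-level scenario

_FAMILIES = [
    "Equisetaceae", "Ophioglossaceae", "Psilotaceae", "Marattiaceae",
    "Osmundaceae", "Hymenophyllaceae", "Gleicheniaceae", "Dipteridaceae",
    "Matoniaceae", "Schizaeaceae", "Anemiaceae", "Salviniaceae",
    "Culcitaceae", "Loxsomataceae", "Plagiogyriaceae", "Cibotiaceae",
    "Metaxyaceae", "Cyatheaceae", "Dicksoniaceae", "Lindsaeaceae",
    "Lonchitidaceae", "Dennstaedtiaceae", "Pteridaceae", "Dryopteridaceae",
    "Aspleniaceae",
]


def _fam(name: str) -> str:
    return f"({name}_1,{name}_2){name}"


def figure2_tree_newick() -> str:
    """Family-level fern topology (two sampled leaves per family, one
    outgroup), with labeled internal nodes."""
    f = _fam
    cyatheales = (f"(({f('Culcitaceae')},({f('Loxsomataceae')},{f('Plagiogyriaceae')})"
                  f"loxo_plagio)culc_clade,({f('Cibotiaceae')},({f('Metaxyaceae')},"
                  f"({f('Cyatheaceae')},{f('Dicksoniaceae')})cya_dick)met_cya)cibo_clade)"
                  "cyatheales")
    polypodiales = (f"(({f('Lindsaeaceae')},{f('Lonchitidaceae')})linds_lonch,"
                    f"({f('Dennstaedtiaceae')},({f('Pteridaceae')},"
                    f"({f('Dryopteridaceae')},{f('Aspleniaceae')})eupolypods)"
                    "pterid_eupoly)dennst_clade)polypodiales")
    core = (f"({f('Salviniaceae')},({cyatheales},{polypodiales})cya_poly)core_lepto")
    schizo_core = (f"(({f('Schizaeaceae')},{f('Anemiaceae')})schizaeales,{core})schizo_core")
    v5 = (f"(({f('Dipteridaceae')},{f('Matoniaceae')})dip_mat,{schizo_core})v5_clade")
    gleich_rest = f"({f('Gleicheniaceae')},{v5})gleich_rest"
    lepto = (f"({f('Osmundaceae')},({f('Hymenophyllaceae')},{gleich_rest})"
             "lepto_minus_osm)leptosporangiates")
    ferns = (f"(({f('Equisetaceae')},({f('Ophioglossaceae')},{f('Psilotaceae')})"
             f"ophio_psilo)eusporangiate_a,({f('Marattiaceae')},{lepto})"
             "marattiales_lepto)ferns")
    return f"(Outgroup_1,{ferns})root;"


def gleicheniales_monophyletic_newick() -> str:
    """Alternative topology with Gleicheniaceae sister to Dipteridaceae +
    Matoniaceae (Gleicheniales monophyletic); otherwise identical."""
    f = _fam
    cyatheales = (f"(({f('Culcitaceae')},({f('Loxsomataceae')},{f('Plagiogyriaceae')})"
                  f"loxo_plagio)culc_clade,({f('Cibotiaceae')},({f('Metaxyaceae')},"
                  f"({f('Cyatheaceae')},{f('Dicksoniaceae')})cya_dick)met_cya)cibo_clade)"
                  "cyatheales")
    polypodiales = (f"(({f('Lindsaeaceae')},{f('Lonchitidaceae')})linds_lonch,"
                    f"({f('Dennstaedtiaceae')},({f('Pteridaceae')},"
                    f"({f('Dryopteridaceae')},{f('Aspleniaceae')})eupolypods)"
                    "pterid_eupoly)dennst_clade)polypodiales")
    core = (f"({f('Salviniaceae')},({cyatheales},{polypodiales})cya_poly)core_lepto")
    schizo_core = (f"(({f('Schizaeaceae')},{f('Anemiaceae')})schizaeales,{core})schizo_core")
    gleicheniales = (f"({f('Gleicheniaceae')},({f('Dipteridaceae')},{f('Matoniaceae')})"
                     "dip_mat)gleicheniales")
    rest = f"({gleicheniales},{schizo_core})gleich_rest"
    lepto = (f"({f('Osmundaceae')},({f('Hymenophyllaceae')},{rest})"
             "lepto_minus_osm)leptosporangiates")
    ferns = (f"(({f('Equisetaceae')},({f('Ophioglossaceae')},{f('Psilotaceae')})"
             f"ophio_psilo)eusporangiate_a,({f('Marattiaceae')},{lepto})"
             "marattiales_lepto)ferns")
    return f"(Outgroup_1,{ferns})root;"


def figure2_events() -> list[EventSpec]:
    """The published event ledger on its stated branches.

    Placements the source prose leaves open are flagged
    ``placement_stated=False``.  Events within one branch are applied in
    list order.
    """
    E = EventSpec
    ev: list[EventSpec] = []
    # --- inversions (9) ------------------------------------------------
    ev += [
        E("V1", "V", "ferns", {"left": "psbM", "right": "ycf2"}),
        E("V2", "V", "ferns", {"left": "trnG-GCC", "right": "trnT-GGU"}),
        E("V3", "V", "ferns", {"left": "trnD-GUC", "right": "trnY-GUA"}),
        # R4 precedes V4 so trnL-CAA..trnV-GAC is a repeat-internal block
        E("R4", "R", "Gleicheniaceae", {"mode": "expand_lsc", "n_genes": 4}),
        E("V4", "V", "Gleicheniaceae", {"left": "trnL-CAA", "right": "trnV-GAC"}),
        E("V5", "V", "v5_clade", {"left": "psbA", "right": "rpoC2"}),
        E("R5", "R", "v5_clade", {"mode": "partial_lsc"}),
        E("V6", "V", "Matoniaceae", {"left": "trnC-GCA", "right": "ndhC"}),
        E("V7", "V", "schizo_core", {"left": "trnV-GAC", "right": "trnN-GUU"}),
        E("V8", "V", "core_lepto", {"left": "trnE-UUC", "right": "trnC-GCA"}),
        E("V9", "V", "culc_clade", {"left": "trnD-GUC", "right": "trnE-UUC"}),
    ]
    # --- remaining IR boundary shifts (R1-R3, R6, R7) -------------------
    ev += [
        E("R1", "R", "polypodiales", {"mode": "expand_ssc", "n_genes": 3},
          placement_stated=False),
        E("R2", "R", "Psilotaceae", {"mode": "expand_lsc", "n_genes": 1}),
        E("R2", "R", "Psilotaceae", {"mode": "expand_ssc", "n_genes": 1}),
        E("R3", "R", "Marattiaceae", {"mode": "expand_lsc", "n_genes": 4}),
        # Hymenophyllaceae: trnL-CAA is deleted (T6) before the expansion,
        # so the repeat gains only the three protein-coding genes
        E("T6", "T", "Hymenophyllaceae", {"trna": "trnL-CAA", "mode": "delete"}),
        E("R3", "R", "Hymenophyllaceae", {"mode": "expand_lsc", "n_genes": 3}),
        E("R6", "R", "Schizaeaceae", {"mode": "expand_ssc", "n_genes": 1}),
        E("R7", "R", "Salviniaceae", {"mode": "expand_ssc", "n_genes": 2}),
    ]
    # --- protein-coding gene / intron losses (G1-G10) -------------------
    ev += [
        E("G1", "G", "Salviniaceae", {"gene": "chlB", "mode": "delete"},
          placement_stated=False),
        E("G2", "G", "eusporangiate_a", {"gene": "rps16", "mode": "delete"}),
        E("G2", "G", "Lindsaeaceae", {"gene": "rps16", "mode": "delete"}),
        E("G3", "G", "eusporangiate_a", {"gene": "rps12::3p", "intron": 1}),
        E("G4", "G", "Equisetaceae", {"gene": "ycf12", "mode": "pseudogenize"},
          placement_stated=False),
        E("G5", "G", "Psilotaceae", {"gene": "rps15", "mode": "delete"},
          placement_stated=False),
        E("G6", "G", "Hymenophyllaceae", {"gene": "clpP", "intron": 1},
          placement_stated=False),
    ]
    for g in ("ndhF", "ndhD", "ndhE", "ndhG", "ndhI", "ndhA", "ndhH", "ndhC"):
        ev.append(E("G7", "G", "Schizaeaceae", {"gene": g, "mode": "delete"}))
    ev += [
        E("G8", "G", "schizaeales", {"gene": "psaM", "mode": "delete"}),
        E("G8", "G", "polypodiales", {"gene": "psaM", "mode": "delete"}),
        E("G9", "G", "Schizaeaceae", {"gene": "ycf94", "mode": "delete"}),
        E("G10", "G", "Lindsaeaceae", {"gene": "ndhA", "intron": 1}),
    ]
    # --- tRNA losses / anticodon change (T1-T7; T6 above) ---------------
    ev += [
        E("T1", "T", "leptosporangiates", {"trna": "trnS-CGA", "mode": "delete"},
          placement_stated=False),
        E("T2", "T", "core_lepto", {"trna": "trnT-UGU", "mode": "delete"},
          placement_stated=False),
        E("T3", "T", "Ophioglossaceae", {"trna": "trnA-UGC", "mode": "delete"}),
        E("T4", "T", "polypodiales", {"trna": "trnK-UUU", "mode": "delete"},
          placement_stated=False),
        E("T5", "T", "gleich_rest", {"trna": "trnL-UAA", "mode": "anticodon",
                                     "new_anticodon": "CAA"}),
        E("T6", "T", "schizo_core", {"trna": "trnL-CAA", "mode": "delete"}),
        E("T7", "T", "schizo_core", {"trna": "trnV-GAC", "mode": "delete"}),
    ]
    # --- codon indels (D1-D19, Table-2-style positions/lengths) ---------
    d = [
        ("D1", "Psilotaceae", "rps4", 118, +138),
        ("D2", "core_lepto", "matK", 193, -15),
        ("D3", "core_lepto", "ndhB", 1354, +9),
        ("D4", "cyatheales", "ycf2", 3610, -3),
        ("D5", "cibo_clade", "ycf2", 970, -108),
        ("D6", "polypodiales", "ycf2", 3613, +24),
        ("D7", "polypodiales", "rps4", 469, -9),
        ("D8", "linds_lonch", "ndhB", 1414, -6),
        ("D9", "Lonchitidaceae", "rpoC2", 1615, -1032),
        ("D10", "Lonchitidaceae", "ycf2", 2527, -84),
        ("D11", "dennst_clade", "rps4", 70, +6),
        ("D12", "dennst_clade", "ycf2", 2620, -6),
        ("D13", "Dennstaedtiaceae", "ndhB", 205, -9),
        ("D13", "Pteridaceae", "ndhB", 205, -9),
        ("D14", "Pteridaceae", "ycf2", 2626, -9),
        ("D15", "eupolypods", "ycf2", 862, -12),
        ("D16", "eupolypods", "ycf2", 3217, -63),
        ("D17", "eupolypods", "ycf2", 5128, +6),
        ("D18", "eupolypods_ii", "chlL", 853, +21),
        ("D19", "eupolypods_i", "petA", 46, +6),
    ]
    branch_alias = {"eupolypods_ii": "Aspleniaceae", "eupolypods_i": "Dryopteridaceae"}
    for label, branch, gene, pos, length in d:
        branch = branch_alias.get(branch, branch)
        sym = gene if gene != "rps12" else "rps12::3p"
        ev.append(E(label, "D", branch, {"gene": sym, "pos": pos, "length": length}))
    # events listed per branch must run in the order given above
    return ev


def figure2_scenario(seed: int = 0, sub_rate: float = 0.01,
                     preset: str = "scaled"):
    """Build the packaged end-to-end scenario.

    Returns ``(tree, leaves, ledger, events)`` where ``leaves`` maps the 51
    leaf names to annotated GenomeRecords.
    """
    tree = Phylogeny.from_newick(figure2_tree_newick())
    events = figure2_events()
    leaves, ledger = evolve(tree, ancestral_spec(preset), events=events,
                            sub_rate=sub_rate, seed=seed)
    return tree, leaves, ledger, events
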