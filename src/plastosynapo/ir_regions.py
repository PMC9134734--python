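"""Inverted-repeat detection, LSC/IRa/SSC/IRb partitioning, boundary shifts.

A typical plastome carries two reverse-complementary repeat copies (IRa,
IRb) separated by a large and a small single-copy region.  Expansion or
contraction of the repeat moves genes into or out of the duplicated state;
those boundary shifts are phylogenetic characters in their own right.

Detection strategy: exact k-mer seeds (k = 25) between the sequence and its
reverse complement are chained on diagonals into maximal exact
reverse-complementary repeat pairs, then extended outward allowing
mismatches down to the requested identity.  The highest-scoring disjoint
pair wins; ties pick the pair minimizing the LSC start coordinate.  Direct
(non-inverted) repeats are never returned.  Repeats straddling the
sequence origin are not searched; rotate the record first if the repeat
may wrap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .plastome_io import GeneSymbol, GenomeRecord, _pos_in

__all__ = [
    "RegionPartition",
    "BoundaryShift",
    "find_inverted_repeat",
    "assign_regions",
    "call_boundary_shift",
    "partition_table",
]

_SEED_K = 25


@dataclass
class RegionPartition:
    """LSC/IRa/SSC/IRb intervals, 1-based inclusive; LSC may wrap the origin.

    The four intervals tile the circle; |IRa| == |IRb|; by convention the
    circle reads LSC, IRa, SSC, IRb clockwise and |LSC| >= |SSC| >= 0.
    An SSC of length 0 is encoded as (0, -1).
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    ir_length: int
    identity: float
    genome_length: int

    def interval_length(self, iv: tuple[int, int]) -> int:
        s, e = iv
        if s == 0:
            return 0
        return e - s + 1 if s <= e else self.genome_length - s + 1 + e

    def region_of_position(self, p: int) -> str:
        for name, iv in (("IRa", self.ira), ("IRb", self.irb),
                         ("LSC", self.lsc), ("SSC", self.ssc)):
            if iv[0] != 0 and _pos_in(p, iv[0], iv[1], self.genome_length):
                return name
        return "LSC"


@dataclass
class BoundaryShift:
    """IR gene-content difference of a sample against a reference."""

    taxon: str
    gained: set[GeneSymbol] = field(default_factory=set)
    lost: set[GeneSymbol] = field(default_factory=set)
    side: str = ""
    partial_genes: set[tuple[GeneSymbol, str]] = field(default_factory=set)

    @property
    def empty(self) -> bool:
        return not self.gained and not self.lost and not self.partial_genes


def _maximal_ir_pairs(seq: str, min_len: int):
    """Yield (a_start, b_start, length) 0-based maximal exact pairs with
    seq[a:a+len] == revcomp(seq[b:b+len]) and a < b, non-overlapping."""
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    pos = defaultdict(list)
    for j in range(n - _SEED_K + 1):
        pos[rc[j : j + _SEED_K]].append(j)
    # chain seeds along diagonals d = i - j
    diag_hits = defaultdict(list)
    for i in range(n - _SEED_K + 1):
        kmer = seq[i : i + _SEED_K]
        for j in pos.get(kmer, ()):
            diag_hits[i - j].append(i)
    pairs = []
    for d, hits in diag_hits.items():
        hits.sort()
        run_start = prev = hits[0]
        for i in hits[1:] + [None]:
            if i is not None and i <= prev + _SEED_K:
                prev = i
                continue
            length = prev + _SEED_K - run_start
            a = run_start
            b = n - (run_start - d) - length  # revcomp coordinate flip
            lo, hi = (a, b) if a <= b else (b, a)
            if lo == hi and length % 2 == 0:
                # perfect palindrome: two adjacent copies, SSC of length 0
                half = length // 2
                if half >= min_len:
                    pairs.append((lo, lo + half, half))
            elif length >= min_len and lo + length <= hi:  # disjoint copies
                pairs.append((lo, hi, length))
            if i is not None:
                run_start = prev = i
    # deduplicate (a palindromic pair is found on both strands' diagonals)
    return sorted(set(pairs), key=lambda t: (-t[2], t[0]))


def _extend_pair(seq: str, a: int, b: int, length: int, min_identity: float):
    """Greedy outward extension allowing mismatches while the running
    identity of the whole repeat stays >= min_identity."""
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    matches = length
    total = length
    # extend left of a / right of b (they move together under revcomp pairing)
    while a > 0 and b + length < n and (a - 1) + length <= b - 1 + 1:
        x, y = seq[a - 1], seq[b + length]
        ok = comp.get(x) == y
        if (matches + (1 if ok else 0)) / (total + 1) < min_identity:
            break
        a -= 1
        matches += 1 if ok else 0
        total += 1
        length += 1
    # extend right of a / left of b
    while a + length < n and b > 0 and a + length <= b - 1:
        x, y = seq[a + length], seq[b - 1]
        ok = comp.get(x) == y
        if (matches + (1 if ok else 0)) / (total + 1) < min_identity:
            break
        b -= 1
        matches += 1 if ok else 0
        total += 1
        length += 1
    return a, b, length, matches / total if total else 0.0


def find_inverted_repeat(
    record: GenomeRecord, min_len: int = 1000, min_identity: float = 0.99
) -> RegionPartition | None:
    """Detect the IR pair and partition the genome into LSC/IRa/SSC/IRb.

    Returns ``None`` when no disjoint reverse-complementary repeat of at
    least ``min_len`` at ``min_identity`` exists (including records shorter
    than twice ``min_len``).  The SSC may have length 0.
    """
    if min_len < _SEED_K:
        raise ValueError(f"min_len must be >= {_SEED_K}")
    if not 0.8 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.8, 1.0]")
    seq = record.sequence.upper()
    n = len(seq)
    if n < 2 * min_len:
        return None
    best = None
    for a, b, length in _maximal_ir_pairs(seq, min(min_len, _SEED_K * 2)):
        if min_identity < 1.0:
            a, b, length, ident = _extend_pair(seq, a, b, length, min_identity)
        else:
            ident = 1.0
        if length < min_len or ident < min_identity:
            continue
        cand = (length, -(a + 1), a, b, ident)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return None
    length, _, a, b, ident = best
    # two single-copy gaps: between copy1 end and copy2 start, and the wrap
    gap1 = (a + length + 1, b)            # 1-based inclusive, may be empty
    gap2 = (b + length + 1, a)            # wraps through the origin
    len1 = b - (a + length)
    len2 = n - (b + length) + a
    # IRa = the repeat copy immediately clockwise of the LSC
    if len1 >= len2:
        lsc, ssc = gap1, gap2
        ira, irb = (b + 1, b + length), (a + 1, a + length)
        lsc_len, ssc_len = len1, len2
    else:
        lsc, ssc = gap2, gap1
        ira, irb = (a + 1, a + length), (b + 1, b + length)
        lsc_len, ssc_len = len2, len1
    # normalize wrapping intervals; empty interval -> (0, -1)
    def norm(iv, ln):
        if ln == 0:
            return (0, -1)
        s, e = iv
        s = (s - 1) % n + 1
        e = (e - 1) % n + 1
        return (s, e)

    return RegionPartition(
        lsc=norm(lsc, lsc_len), ira=ira, ssc=norm(ssc, ssc_len), irb=irb,
        ir_length=length, identity=ident, genome_length=n,
    )


def assign_regions(partition: RegionPartition, record: GenomeRecord) -> dict:
    """Map each gene symbol to LSC / SSC / IR / boundary-partial.

    A gene is IR iff all its bases lie inside IRa or IRb; boundary-partial
    iff some but not all bases are inside the repeat.  For boundary-partial
    genes the value is the tuple ``("boundary-partial", part_tag)`` where
    ``part_tag`` names the exon part(s) inside the repeat.
    """
    out: dict[GeneSymbol, object] = {}
    n = record.length
    for feat in record.features:
        ins, outs = 0, 0
        parts_in: list[str] = []
        for idx, (s, e, _) in enumerate(feat.parts, start=1):
            span = [(s, e)] if s <= e else [(s, n), (1, e)]
            part_in = part_out = 0
            for ss, ee in span:
                for p in range(ss, ee + 1):
                    if (_pos_in(p, *partition.ira, n) if partition.ira[0] else False) or (
                        _pos_in(p, *partition.irb, n) if partition.irb[0] else False
                    ):
                        part_in += 1
                    else:
                        part_out += 1
            ins += part_in
            outs += part_out
            if part_in and not part_out:
                parts_in.append(f"exon{idx}")
        sym = feat.symbol
        if ins and outs:
            out[sym] = ("boundary-partial", "+".join(parts_in) or "partial")
        elif ins:
            prev = out.get(sym)
            out[sym] = "IR"
            if prev is not None and prev != "IR":
                out[sym] = prev  # keep single-copy call from the other copy
        else:
            s = feat.parts[0][0]
            out.setdefault(sym, partition.region_of_position(s))
    return out


def call_boundary_shift(sample_assign: dict, reference_assign: dict,
                        taxon: str = "") -> BoundaryShift:
    """IR membership difference of a sample against a reference assignment.

    gained = genes duplicated into the IR in the sample only; lost = genes
    that left the repeat.  The side is inferred from the reference region
    of each moved gene (the sample region for genes the reference lacks).
    """
    def ir_set(assign):
        return {s for s, v in assign.items() if v == "IR"}

    def partial_set(assign):
        return {(s, v[1]) for s, v in assign.items()
                if isinstance(v, tuple) and v[0] == "boundary-partial"}

    s_ir, r_ir = ir_set(sample_assign), ir_set(reference_assign)
    gained = s_ir - r_ir
    lost = r_ir - s_ir
    partials = partial_set(sample_assign) - partial_set(reference_assign)
    sides = set()
    for sym in gained:
        region = reference_assign.get(sym, sample_assign.get(sym))
        if isinstance(region, tuple):
            region = "LSC"
        if region in ("LSC", "SSC"):
            sides.add(region)
    for sym in lost:
        # a released gene lands in a single-copy region of the sample
        region = sample_assign.get(sym)
        if region in ("LSC", "SSC"):
            sides.add(region)
    for sym, _tag in partials:
        region = reference_assign.get(sym)
        if region in ("LSC", "SSC"):
            sides.add(region)
    side = "both" if len(sides) > 1 else (sides.pop() if sides else "")
    return BoundaryShift(taxon=taxon, gained=gained, lost=lost, side=side,
                         partial_genes=partials)


def partition_table(taxon: str, partition: RegionPartition):
    """Partition report rows (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for name in ("lsc", "ira", "ssc", "irb"):
        iv = getattr(partition, name)
        rows.append({"taxon": taxon, "region": name.upper(), "start": iv[0],
                     "end": iv[1], "length": partition.interval_length(iv)})
    return pd.DataFrame(rows)
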