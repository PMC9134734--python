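"""Reading, writing and canonicalizing annotated plastomes.

A plastid genome is modelled as a circular sequence plus an ordered list of
typed gene features.  Everything downstream (inverted-repeat detection,
signed gene orders, gene-content scoring) works on these records, so the
parser normalizes the common annotation dialects up front: both ``gene``
and typed ``CDS/tRNA/rRNA`` features are accepted, tRNA names carry their
anticodon, and a packaged synonym table maps spelling variants to one
canonical symbol.

Coordinates are 1-based inclusive throughout (GenBank convention); features
may wrap the origin of a circular record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSymbol",
    "GeneFeature",
    "GenomeRecord",
    "SignedGeneOrder",
    "normalize_gene_symbol",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "extract_gene_order",
    "gene_order_table",
]

# Synonym table: lowercase raw name -> canonical name.  Covers the spelling
# variants seen across plastome submissions for the genes this pipeline cares
# about; unknown names pass through with whitespace/case normalization only.
_SYNONYMS = {
    "psba": "psbA",
    "ycf2": "ycf2",
    "rps12a": "rps12",
    "rps12b": "rps12",
    "5'rps12": "rps12",
    "3'rps12": "rps12",
    "rrn16s": "rrn16",
    "rrn23s": "rrn23",
    "16s rrna": "rrn16",
    "23s rrna": "rrn23",
    "4.5s rrna": "rrn4.5",
    "5s rrna": "rrn5",
    "trnk": "trnK",
    "infa": "infA",
}

_TRNA_RE = re.compile(r"^(trn[A-Za-z]{1,3})[-_ ]?([ACGTUacgtu]{3})?$")


@dataclass(frozen=True, order=True)
class GeneSymbol:
    """Canonical gene identity.

    ``anticodon`` is set for tRNAs (RNA alphabet, e.g. ``UAA``); ``part``
    distinguishes physically disjoint loci of one gene (the trans-spliced
    rps12 5'/3' halves) and exon parts referenced by boundary shifts.
    """

    name: str
    anticodon: str | None = None
    part: str | None = None

    def __str__(self) -> str:
        s = self.name
        if self.anticodon:
            s += f"-{self.anticodon}"
        if self.part:
            s += f"::{self.part}"
        return s

    @property
    def base(self) -> "GeneSymbol":
        """The symbol without its part tag."""
        return replace(self, part=None) if self.part else self

    @property
    def is_trna(self) -> bool:
        return self.name.startswith("trn")


@dataclass
class GeneFeature:
    """One annotated gene with its exon spans.

    ``parts`` are (start, end, strand) tuples, 1-based inclusive, ordered
    5'->3' on the coding strand.  A span with start > end wraps the origin
    of a circular record.
    """

    symbol: GeneSymbol
    kind: str  # CDS | tRNA | rRNA
    parts: list[tuple[int, int, str]]
    locus_note: str = ""

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.symbol} has no location parts")

    @property
    def strand(self) -> str:
        return self.parts[0][2]

    @property
    def start(self) -> int:
        return min(p[0] for p in self.parts)

    def span_length(self, genome_length: int) -> int:
        total = 0
        for s, e, _ in self.parts:
            total += (e - s + 1) if s <= e else (genome_length - s + 1 + e)
        return total

    def extract(self, sequence: str) -> str:
        """Concatenated coding-strand sequence of all parts."""
        n = len(sequence)
        chunks = []
        for s, e, strand in self.parts:
            chunk = sequence[s - 1 : e] if s <= e else sequence[s - 1 :] + sequence[:e]
            if strand == "-":
                chunk = str(Seq(chunk).reverse_complement())
            chunks.append(chunk)
        # parts are ordered 5'->3' on the coding strand already
        del n
        return "".join(chunks)


@dataclass
class GenomeRecord:
    """Circular annotated plastome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def symbols(self) -> list[GeneSymbol]:
        return [f.symbol for f in self.features]

    def find(self, symbol: GeneSymbol) -> list[GeneFeature]:
        return [f for f in self.features if f.symbol == symbol]


@dataclass
class SignedGeneOrder:
    """Canonical circular gene order: (symbol, sign) pairs starting at the
    anchor with sign '+'.  With ``ir_collapsed`` the IRb copy of every
    duplicated gene has been dropped."""

    taxon: str
    order: list[tuple[GeneSymbol, str]]
    anchor: GeneSymbol
    ir_collapsed: bool = False

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("empty gene order")
        if self.order[0][0] != self.anchor or self.order[0][1] != "+":
            raise ValueError("order must start at the anchor with sign +")

    def symbols(self) -> list[GeneSymbol]:
        return [s for s, _ in self.order]


def normalize_gene_symbol(
    raw_name: str, kind: str = "CDS", anticodon: str | None = None
) -> GeneSymbol:
    """Map a raw annotation name to a canonical :class:`GeneSymbol`.

    tRNA symbols render as name-anticodon (``trnL-CAA``).  A tRNA whose
    anticodon cannot be resolved from the name or the ``anticodon`` argument
    is flagged rather than rejected, since downstream validation can still
    read the anticodon off the sequence.
    """
    name = raw_name.strip()
    if not name:
        raise ValueError("empty gene name")
    part = None
    m = re.search(r"::(\w+)$", name)
    if m:
        part = m.group(1)
        name = name[: m.start()]
    low = name.lower()
    if low in _SYNONYMS:
        name = _SYNONYMS[low]
    tm = _TRNA_RE.match(name)
    if kind == "tRNA" or tm:
        base = tm.group(1) if tm else name
        base = "trn" + base[3:]  # keep isotype letter case as given
        ac = anticodon or (tm.group(2) if tm else None)
        if ac:
            ac = ac.upper().replace("T", "U")
            return GeneSymbol(base, ac, part)
        return GeneSymbol(base, None, "anticodon-unknown" if part is None else part)
    # CDS/rRNA: case-normalize against synonym table only; otherwise keep as-is
    return GeneSymbol(name, None, part)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O (Biopython-backed)

_KIND_BY_GB_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}

# name -> kind lookup used when a bare `gene` feature has no typed child
def _kind_from_name(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "CDS"


def _location_parts(feat: SeqFeature, length: int) -> list[tuple[int, int, str]]:
    locs = feat.location.parts if isinstance(feat.location, CompoundLocation) else [feat.location]
    out = []
    for loc in locs:
        strand = "-" if loc.strand == -1 else "+"
        out.append((int(loc.start) + 1, int(loc.end), strand))
    # merge an origin-split pair (..,L)+(1,..) back into one wrapping span
    if len(out) == 2 and out[0][1] == length and out[1][0] == 1 and out[0][2] == out[1][2]:
        out = [(out[0][0], out[1][1], out[0][2])]
    if out and out[0][2] == "-":
        out = out[::-1]  # Biopython lists minus-strand parts 3'->5' positionally
    return out


def read_genbank(path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    All gene/CDS/tRNA/rRNA features are captured with strand and multi-part
    spans; origin-spanning features are preserved as wrapping spans.
    """
    try:
        rec: SeqRecord = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ValueError(f"{path}: no GenBank record found")
    except Exception as exc:  # Biopython raises plain ValueError with line info
        raise ValueError(f"{path}: malformed GenBank file: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 10:
        raise ValueError(f"{path}: record has no sequence")
    topology = rec.annotations.get("topology", "circular")
    features: list[GeneFeature] = []
    seen: set[tuple] = set()
    typed = [f for f in rec.features if f.type in _KIND_BY_GB_TYPE]
    bare_genes = [f for f in rec.features if f.type == "gene"]
    for f in typed:
        features.append(_to_gene_feature(f, len(seq)))
        seen.add(_fingerprint(f, len(seq)))
    for f in bare_genes:
        if _fingerprint(f, len(seq)) in seen:
            continue
        features.append(_to_gene_feature(f, len(seq)))
    features.sort(key=lambda gf: gf.start)
    return GenomeRecord(id=rec.id or rec.name, sequence=seq, features=features, topology=topology)


def _fingerprint(feat: SeqFeature, length: int) -> tuple:
    name = _raw_name(feat)
    parts = tuple(_location_parts(feat, length))
    return (name.lower(), parts)


def _raw_name(feat: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return "unknown"


def _to_gene_feature(feat: SeqFeature, length: int) -> GeneFeature:
    raw = _raw_name(feat)
    kind = _KIND_BY_GB_TYPE.get(feat.type) or _kind_from_name(raw.strip())
    anticodon = None
    if "anticodon" in feat.qualifiers:
        m = re.search(r"seq:([acgtu]{3})", feat.qualifiers["anticodon"][0], re.I)
        if m:
            anticodon = m.group(1)
    if "part" in feat.qualifiers:
        raw = raw + "::" + feat.qualifiers["part"][0]
    symbol = normalize_gene_symbol(raw, kind, anticodon)
    note = feat.qualifiers.get("note", [""])[0]
    return GeneFeature(symbol=symbol, kind=kind, parts=_location_parts(feat, length), locus_note=note)


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trips with
    :func:`read_genbank`)."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="plastome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for gf in record.features:
        locs = []
        for s, e, strand in gf.parts:
            st = -1 if strand == "-" else 1
            if s <= e:
                locs.append(SimpleLocation(s - 1, e, strand=st))
            else:  # origin wrap -> split into two joined spans
                locs.append(SimpleLocation(s - 1, record.length, strand=st))
                locs.append(SimpleLocation(0, e, strand=st))
        if gf.strand == "-":
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [gf.symbol.name if not gf.symbol.is_trna
                          else f"{gf.symbol.name}-{gf.symbol.anticodon or ''}".rstrip("-")]}
        if gf.symbol.part and gf.symbol.part != "anticodon-unknown":
            quals["part"] = [gf.symbol.part]
        if gf.symbol.anticodon:
            quals["anticodon"] = [f"(pos:complement,aa:X,seq:{gf.symbol.anticodon.lower()})"]
        if gf.locus_note:
            quals["note"] = [gf.locus_note]
        rec.features.append(SeqFeature(loc, type=gf.kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def write_fasta(record: GenomeRecord, path) -> None:
    SeqIO.write([SeqRecord(Seq(record.sequence), id=record.id, description="")],
                str(path), "fasta")


def read_fasta(path) -> GenomeRecord:
    """Read a bare (unannotated) sequence as a GenomeRecord."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), features=[])


# ---------------------------------------------------------------------------
# Canonical signed gene orders


def _circular_position(feat: GeneFeature, length: int) -> int:
    return feat.start if feat.parts[0][0] <= feat.parts[0][1] else feat.parts[0][0]


def extract_gene_order(
    record: GenomeRecord,
    partition=None,
    anchor: GeneSymbol | None = None,
) -> SignedGeneOrder:
    """Canonical signed gene order of ``record``.

    Genes are ordered by position around the circle starting at ``anchor``
    on the strand that makes the anchor '+'.  When a
    :class:`~plastosynapo.ir_regions.RegionPartition` is given, the IRb copy
    of each duplicated gene is dropped (``ir_collapsed``), so IR-internal
    orientation is carried by the retained IRa copy.

    The result is invariant to rotation of the input circle and to taking
    its reverse complement.
    """
    if anchor is None:
        anchor = GeneSymbol("psbA")
    feats = list(record.features)
    if partition is not None:
        feats = [f for f in feats if not _in_interval_full(f, partition.irb, record.length)]
    if not feats:
        raise ValueError("record has no gene features")
    feats.sort(key=lambda f: (_circular_position(f, record.length), str(f.symbol)))
    symbols = [f.symbol for f in feats]
    anchors = [i for i, s in enumerate(symbols) if s == anchor or s.base == anchor]
    if not anchors:
        avail = ", ".join(sorted({str(s) for s in symbols}))
        raise ValueError(f"anchor {anchor} absent; available symbols: {avail}")
    i0 = anchors[0]
    rotated = feats[i0:] + feats[:i0]
    order = [(f.symbol, f.strand) for f in rotated]
    if order[0][1] == "-":
        # reflect: reverse order and flip all signs, keep anchor first
        flipped = [(s, "+" if sg == "-" else "-") for s, sg in order]
        order = [flipped[0]] + flipped[1:][::-1]
    return SignedGeneOrder(taxon=record.id, order=order, anchor=anchor,
                           ir_collapsed=partition is not None)


def _in_interval_full(feat: GeneFeature, interval: tuple[int, int], length: int) -> bool:
    """True iff every base of the feature lies inside the (possibly wrapping)
    1-based inclusive interval."""
    s0, e0 = interval
    for s, e, _ in feat.parts:
        positions = [s, e] if s <= e else [s, length, 1, e]
        for p in positions:
            if not _pos_in(p, s0, e0, length):
                return False
    return True


def _pos_in(p: int, s: int, e: int, length: int) -> bool:
    if s <= e:
        return s <= p <= e
    return p >= s or p <= e


def gene_order_table(order: SignedGeneOrder, region_of=None):
    """Gene order as a pandas DataFrame (taxon, index, symbol, sign, region).

    Coordinates/indices are 1-based; stated here once and in file headers.
    """
    import pandas as pd

    rows = []
    for i, (sym, sign) in enumerate(order.order, start=1):
        region = region_of.get(sym, "") if region_of else ""
        rows.append({"taxon": order.taxon, "index": i, "symbol": str(sym),
                     "sign": sign, "region": region})
    return pd.DataFrame(rows)
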