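"""Gene, intron and tRNA presence/loss scoring.

Fern plastids edit their transcripts heavily, so apparent internal stop
codons or odd start/stop codons are not evidence of pseudogenization.  A
protein-coding gene is therefore called lost only when the ORF's integrity
(fraction of the reference covered) or similarity (identity over the
aligned span) drops below 0.70 against an intact relative; start/stop
anomalies are recorded as notes only.  tRNA loci are validated
structurally: a candidate must fold into a cloverleaf (acceptor, D,
anticodon and T arms) and its anticodon must decode an amino acid matching
the isotype in its name; a structurally sound tRNA whose anticodon differs
from the ancestral locus is an anticodon change, anything else is a
hypothetical loss.  Losses seen in a single sample are demoted, since
one-off absences are more often assembly or annotation artifacts than
phylogenetic signal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .plastome_io import GeneFeature, GeneSymbol

__all__ = [
    "GeneStatus",
    "TrnaValidation",
    "IntronStatus",
    "assess_gene",
    "validate_trna",
    "detect_intron_loss",
    "apply_singleton_filter",
    "LOSS_THRESHOLD",
]

LOSS_THRESHOLD = 0.70


@dataclass
class GeneStatus:
    taxon: str
    symbol: GeneSymbol
    integrity: float
    similarity: float
    status: str  # present | lost | ambiguous
    notes: set[str] = field(default_factory=set)


@dataclass
class TrnaValidation:
    taxon: str
    locus_symbol: GeneSymbol
    structure_pass: bool
    anticodon_observed: str | None
    isotype_consistent: bool
    verdict: str  # validated | anticodon-change | hypothetical-loss


@dataclass
class IntronStatus:
    taxon: str
    symbol: GeneSymbol
    intron_index: int
    status: str  # retained | lost | gene-absent


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


def assess_gene(
    candidate_region: str | None,
    reference_cds: str,
    taxon: str = "",
    symbol: GeneSymbol | None = None,
    threshold: float = LOSS_THRESHOLD,
    require_both_below: bool = False,
) -> GeneStatus:
    """Score a candidate gene region against an intact reference CDS.

    integrity = aligned reference positions covered by candidate bases /
    reference length; similarity = matches / aligned (both-non-gap)
    columns.  Lost iff integrity < threshold OR similarity < threshold
    (strictly less; the conjunctive reading is available via
    ``require_both_below``).  Internal stops and abnormal start/stop codons
    become notes, never loss calls on their own.
    """
    if symbol is None:
        symbol = GeneSymbol("gene")
    ref = reference_cds.upper()
    if len(ref) < 3 or len(ref) % 3 != 0:
        raise ValueError("reference CDS length must be >= 3 and divisible by 3")
    if not candidate_region:
        return GeneStatus(taxon, symbol, 0.0, 0.0, "lost", {"absent"})
    cand = candidate_region.upper()
    aln = _aligner().align(ref, cand)[0]
    covered = 0
    matches = 0
    cols = 0
    blocks = list(zip(*aln.aligned))
    for (rs, re_), (qs, qe) in blocks:
        covered += re_ - rs
        cols += re_ - rs
        for k in range(re_ - rs):
            if ref[rs + k] == cand[qs + k]:
                matches += 1
    # "ends covered" needs substantial terminal aligned blocks (>= 10
    # codons), not a couple of chance-matching bases at a truncation edge
    ends_covered = (
        bool(blocks)
        and blocks[0][0][0] == 0
        and blocks[-1][0][1] == len(ref)
        and blocks[0][0][1] - blocks[0][0][0] >= 30
        and blocks[-1][0][1] - blocks[-1][0][0] >= 30
    )
    integrity = covered / len(ref)
    similarity = matches / cols if cols else 0.0
    notes = set()
    prot = str(Seq(cand[: len(cand) - len(cand) % 3]).translate())
    if "*" in prot[:-1]:
        notes.add("internal-stop")
    if not cand.startswith("ATG"):
        notes.add("abnormal-start")
    if prot and prot[-1] != "*":
        notes.add("abnormal-stop")
    below = (integrity < threshold, similarity < threshold)
    lost = all(below) if require_both_below else any(below)
    # A candidate whose length deficit is a frame-preserving internal
    # deletion (reference covered end to end, high identity where aligned)
    # is a gene carrying a large in-frame indel, not a pseudogene: indels
    # are scored in their own evolutionary context downstream.  Truncations
    # and frameshifts never qualify.
    if lost and similarity >= threshold and ends_covered \
            and (len(ref) - len(cand)) % 3 == 0:
        notes.add("in-frame-indel")
        lost = False
    return GeneStatus(taxon, symbol, integrity, similarity,
                      "lost" if lost else "present", notes)


# ---------------------------------------------------------------------------
# tRNA cloverleaf validation

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _pairs(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


def _stem_matches(seq: str, i: int, j: int, length: int) -> int:
    """Number of complementary pairs in a stem of given length with 5' arm
    starting at i (ascending) and 3' arm ending at j (descending)."""
    return sum(1 for k in range(length) if _pairs(seq[i + k], seq[j - k]))


def _fold_cloverleaf(seq: str):
    """Search for a canonical cloverleaf.

    Layout searched (5'->3'): acceptor 5' arm (7) | D-arm stem (3-4) +
    loop (4-12) + stem' | anticodon stem (4-5) + loop (exactly 7) + stem' |
    variable loop (0-23) | T-arm stem (3-5) + loop (5-9) + stem' |
    acceptor 3' arm (7) | 0-4 trailing nt.  Requirements: acceptor >= 6/7
    pairs (G.U allowed), D and T stems fully paired at >= 3, anticodon stem
    fully paired at 4-5.  Returns the anticodon or None.
    """
    n = len(seq)
    for trail in range(0, 5):
        j_acc = n - 1 - trail  # last base of acceptor 3' arm
        if j_acc < 20:
            continue
        if _stem_matches(seq, 0, j_acc, 7) < 6:
            continue
        acc3_start = j_acc - 6
        # D-arm search
        for d_start in range(7, 12):
            for d_len in (4, 3):
                for d_loop in range(4, 13):
                    d_end = d_start + 2 * d_len + d_loop  # exclusive
                    if d_end >= acc3_start:
                        continue
                    if _stem_matches(seq, d_start, d_end - 1, d_len) < d_len:
                        continue
                    # anticodon arm directly after (allow 0-2 spacer nt)
                    for sp in range(0, 3):
                        a_start = d_end + sp
                        for a_len in (5, 4):
                            a_end = a_start + 2 * a_len + 7
                            if a_end >= acc3_start:
                                continue
                            if _stem_matches(seq, a_start, a_end - 1, a_len) < a_len:
                                continue
                            loop_start = a_start + a_len
                            anticodon = seq[loop_start + 2 : loop_start + 5]
                            # T-arm somewhere in the variable region
                            for t_start in range(a_end, acc3_start - 6):
                                for t_len in (5, 4, 3):
                                    for t_loop in range(5, 10):
                                        t_end = t_start + 2 * t_len + t_loop
                                        if t_end > acc3_start:
                                            continue
                                        if _stem_matches(seq, t_start, t_end - 1, t_len) >= t_len:
                                            return anticodon
    return None


def _isotype_of_anticodon(anticodon: str) -> str | None:
    """Amino-acid one/three-letter isotype decoded by an anticodon."""
    codon = str(Seq(anticodon.replace("U", "T")).reverse_complement())
    table = CodonTable.unambiguous_dna_by_id[11]
    if codon in table.stop_codons:
        return None
    return table.forward_table.get(codon)


_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "fM": "M",
}


def _isotype_letter(symbol: GeneSymbol) -> str | None:
    tag = symbol.name[3:]
    if not tag:
        return None
    if tag in _AA3_TO_1:
        return _AA3_TO_1[tag]
    return tag[0].upper() if tag[0].isalpha() else None


def validate_trna(sequence: str, locus_symbol: GeneSymbol, taxon: str = "") -> TrnaValidation:
    """Structurally validate a candidate tRNA locus.

    Verdicts: ``validated`` (folds, isotype-consistent, anticodon as
    named), ``anticodon-change`` (folds and isotype-consistent but the
    observed anticodon differs from the locus name), ``hypothetical-loss``
    (no cloverleaf, or anticodon inconsistent with the named isotype).
    """
    seq = sequence.upper().replace("T", "U")
    if not 50 <= len(seq) <= 120:
        return TrnaValidation(taxon, locus_symbol, False, None, False,
                              "hypothetical-loss")
    anticodon = _fold_cloverleaf(seq)
    structure_pass = anticodon is not None
    iso_ok = False
    if anticodon:
        decoded = _isotype_of_anticodon(anticodon)
        want = _isotype_letter(locus_symbol)
        # trnM/trnI both read CAU (lysidine modification distinguishes them)
        iso_ok = decoded is not None and want is not None and (
            decoded == want or (anticodon == "CAU" and want in ("M", "I"))
        )
    if structure_pass and iso_ok:
        named = locus_symbol.anticodon
        verdict = "validated" if (named is None or named == anticodon) else "anticodon-change"
    else:
        verdict = "hypothetical-loss"
    return TrnaValidation(taxon, locus_symbol, structure_pass, anticodon,
                          iso_ok, verdict)


# ---------------------------------------------------------------------------
# Intron loss


def detect_intron_loss(
    sample_feature: GeneFeature | None,
    reference_feature: GeneFeature,
    taxon: str = "",
) -> list[IntronStatus]:
    """Compare exon structures; intron i is lost when the sample's exons
    spanning the reference's i-th junction are contiguous (fused).

    Sample exon parts are matched to runs of consecutive reference exons by
    cumulative length (tolerating +-10% or 30 bp drift from indels).
    Returns one status per reference intron.
    """
    symbol = reference_feature.symbol
    n_ref = len(reference_feature.parts)
    n_introns = n_ref - 1
    if n_introns < 1:
        return []
    if sample_feature is None:
        return [IntronStatus(taxon, symbol, i, "gene-absent")
                for i in range(1, n_introns + 1)]
    ref_lens = [abs(e - s) + 1 for s, e, _ in reference_feature.parts]
    smp_lens = [abs(e - s) + 1 for s, e, _ in sample_feature.parts]
    # greedily consume reference exons per sample part
    statuses = []
    ri = 0
    for sl in smp_lens:
        consumed = ref_lens[ri] if ri < len(ref_lens) else 0
        used = [ri]
        ri += 1
        while ri < len(ref_lens) and consumed + 1e-9 < sl and not _close(consumed, sl):
            consumed += ref_lens[ri]
            used.append(ri)
            ri += 1
        for a, b in zip(used, used[1:]):
            statuses.append(IntronStatus(taxon, symbol, a + 1, "lost"))
            del b
    lost = {st.intron_index for st in statuses}
    return [IntronStatus(taxon, symbol, i, "lost" if i in lost else "retained")
            for i in range(1, n_introns + 1)]


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= max(30.0, 0.10 * b)


def apply_singleton_filter(calls: list[GeneStatus]) -> list[GeneStatus]:
    """Demote loss calls supported by exactly one taxon to ambiguous.

    One-sample losses are likelier autapomorphies or artifacts; they are
    excluded from character building.  Losses shared by >= 2 taxa are kept.
    """
    by_gene: dict[GeneSymbol, list[GeneStatus]] = defaultdict(list)
    for c in calls:
        if c.status == "lost":
            by_gene[c.symbol].append(c)
    demote = {id(c) for syms in by_gene.values() if len({x.taxon for x in syms}) == 1
              for c in syms}
    out = []
    for c in calls:
        if id(c) in demote:
            out.append(replace_status(c, "ambiguous"))
        else:
            out.append(c)
    return out


def replace_status(call: GeneStatus, status: str) -> GeneStatus:
    return replace(call, status=status, notes=set(call.notes) | {"singleton"})
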