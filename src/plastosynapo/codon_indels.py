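"""Codon-aware CDS alignment and in-frame indel calling.

Protein-coding indels that preserve the reading frame (lengths divisible
by 3) and are shared across a clade are strong, low-homoplasy characters.
Alignment is codon-aware by construction: each CDS is translated, the
peptides are aligned, and the nucleotides are back-threaded through the
peptide alignment, so every gap run is a whole number of codons.

The peptide multiple alignment is a star alignment around a designated
center row (the reference taxon when present, else the longest sequence),
merging pairwise alignments under the once-a-gap-always-a-gap rule.  This
keeps the stage dependency-free and deterministic; for divergent data an
external aligner can be swapped in upstream, the indel caller only needs
the frame-valid alignment.

Indel polarity (insertion vs deletion) is assigned by the majority state
across rows, ties toward deletion; parsimony mapping downstream refines
polarity against the tree.  Overlapping gap runs that share boundaries
(nested indels stacked on one lineage) are decomposed into atomic
sub-intervals so each historical event surfaces as one indel with its own
carrier set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .plastome_io import GeneSymbol

__all__ = [
    "CodonAlignment",
    "CodonIndel",
    "codon_align",
    "detect_codon_indels",
    "indels_to_characters",
]


@dataclass
class CodonAlignment:
    gene: GeneSymbol
    taxa: list[str]
    rows: list[str]  # aligned nucleotide strings, equal length
    frame_valid: bool = True
    trimmed: dict[str, int] = field(default_factory=dict)  # taxon -> bp trimmed at 3'

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class CodonIndel:
    """One in-frame indel; columns are 1-based alignment coordinates.

    ``length`` is signed bp: + insertion / - deletion relative to the
    majority state.  ``ref_position`` is the 1-based reference-CDS
    coordinate of the first deleted base (deletions) or of the base before
    which the insertion sits plus one (insertions), when a reference row is
    available.
    """

    gene: GeneSymbol
    start_col: int
    end_col: int
    length: int
    carriers: frozenset[str]
    ref_position: int | None = None


def _pep_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _translate(cds: str) -> tuple[str, int]:
    trim = len(cds) % 3
    cds = cds[: len(cds) - trim] if trim else cds
    pep = str(Seq(cds).translate())
    if pep.endswith("*"):
        pep = pep[:-1] + "#"  # keep terminal stop as an alignable column
    pep = pep.replace("*", "X")  # internal stops (RNA editing) align as X
    return pep, trim


def codon_align(cds_set: dict[str, str], gene: GeneSymbol | None = None,
                center: str | None = None,
                snap_window: int = 10) -> CodonAlignment:
    """Codon-unit multiple alignment of one gene's CDS set.

    Translate -> star-align peptides around ``center`` -> normalize indel
    placement across rows -> back-thread nucleotides.  Rows that cannot be
    translated (all-N) are dropped with a warning note in ``trimmed``.

    Normalization: equivalent gap placements are score-ties (or near-ties
    under substitution noise), so independently aligned rows can report
    one ancestral indel at positions a few residues apart, or split one
    long gap around a chance match.  Runs are therefore snapped row-wise:
    same-length runs within ``snap_window`` residues move to the start
    used by most rows; split runs are re-merged when the fusion matches a
    more widely shared run; and a rarer run starting near a more widely
    shared run adopts its start (so stacked indels decompose cleanly).
    Any gap placement of the same run is a valid alignment of the row, so
    snapping never changes a row's sequence, only its column layout.
    """
    if gene is None:
        gene = GeneSymbol("gene")
    taxa = [t for t in cds_set if cds_set[t]]
    peps = {}
    trimmed = {}
    for t in taxa:
        seq = cds_set[t].upper()
        if set(seq) <= {"N"}:
            trimmed[t] = -1  # dropped
            continue
        pep, trim = _translate(seq)
        peps[t] = pep
        trimmed[t] = trim
    taxa = [t for t in taxa if t in peps]
    if not taxa:
        raise ValueError("no translatable CDS rows")
    if center is None or center not in peps:
        center = max(taxa, key=lambda t: (len(peps[t]), t))
    others = [t for t in taxa if t != center]
    aligner = _pep_aligner()
    center_pep = peps[center]
    n_center = len(center_pep)
    dels: dict[str, list] = {}  # taxon -> [(center_start, length)]
    inss: dict[str, list] = {}  # taxon -> [(center_pos, length)]
    for t in others:
        aln = aligner.align(center_pep.replace("#", "W"), peps[t].replace("#", "W"))[0]
        path = _alignment_path(aln, n_center, len(peps[t]))
        dels[t], inss[t] = _path_runs(path)
    _snap_runs(dels, snap_window, n_center, kind="del")
    _snap_runs(inss, snap_window, n_center, kind="ins")
    inserts = [0] * (n_center + 1)
    for t in others:
        for cpos, ln in inss[t]:
            inserts[cpos] = max(inserts[cpos], ln)
    rows = []
    for t in taxa:
        if t == center:
            pep_row = _thread_center(center_pep, inserts)
        else:
            pep_row = _thread_from_runs(peps[t], dels[t], inss[t], inserts, n_center)
        rows.append(_backthread(pep_row, cds_set[t].upper(), trimmed[t]))
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, "-") for r in rows]
    return CodonAlignment(gene=gene, taxa=taxa, rows=rows, frame_valid=True,
                          trimmed=trimmed)


def _path_runs(path):
    """Deletion runs [(center_start, len)] and insertion runs
    [(center_pos, len)] of one pairwise path."""
    dels, inss = [], []
    del_start = None
    ins_len = 0
    cpos = 0
    for c, q in path:
        if c is None:
            ins_len += 1
            continue
        if ins_len:
            inss.append((cpos, ins_len))
            ins_len = 0
        if q is None:
            if del_start is None:
                del_start = c
        else:
            if del_start is not None:
                dels.append((del_start, c - del_start))
                del_start = None
        cpos = c + 1
    if ins_len:
        inss.append((cpos, ins_len))
    if del_start is not None:
        dels.append((del_start, cpos - del_start))
    return dels, inss


def _snap_runs(runs_by_row: dict, window: int, n_center: int, kind: str) -> None:
    """Normalize run placement across rows, in place (see codon_align)."""
    def counts():
        c = {}
        for rs in runs_by_row.values():
            for r in rs:
                c[r] = c.get(r, 0) + 1
        return c

    # 1. re-merge split runs.  A long gap interrupted by a short chance
    #    match is one indel, so runs separated by <= window//2 matched
    #    residues fuse unconditionally; if other rows kept separate runs
    #    there, the atom decomposition downstream re-splits the fusion.
    #    Runs further apart fuse only when the fusion matches a more
    #    widely shared run.
    c = counts()
    for t, rs in runs_by_row.items():
        rs.sort()
        merged = True
        while merged:
            merged = False
            for i in range(len(rs) - 1):
                (s1, l1), (s2, l2) = rs[i], rs[i + 1]
                gap_between = s2 - (s1 + l1)
                if gap_between < 0:
                    continue
                fused_len = l1 + l2
                support = max((c.get((s, fused_len), 0)
                               for s in range(max(0, s1 - window), s1 + window + 1)),
                              default=0)
                if gap_between <= max(1, window // 2) or (
                    gap_between <= window and support > c.get((s1, l1), 0)
                ):
                    rs[i : i + 2] = [(s1, fused_len)]
                    merged = True
                    break
    # 2. same-length clusters -> majority start (ties to the smaller start)
    c = counts()
    moves = {}
    for (s, ln), k in c.items():
        best = max(((c[(s2, l2)], -s2, s2) for (s2, l2) in c
                    if l2 == ln and abs(s2 - s) <= window),
                   default=(k, -s, s))
        moves[(s, ln)] = (best[2], ln)
    for rs in runs_by_row.values():
        rs[:] = [moves.get(r, r) for r in rs]
    # 3. adopt the start of a more widely shared neighbouring run; on equal
    #    support the longer run adopts the shorter one's start (stacked
    #    indels share their ancestral boundary)
    c = counts()
    for rs in runs_by_row.values():
        for i, (s, ln) in enumerate(rs):
            own = c.get((s, ln), 0)
            cand = [(k, -s2, s2) for (s2, l2), k in c.items()
                    if (s2, l2) != (s, ln) and abs(s2 - s) <= window
                    and (k > own or (k == own and l2 < ln))]
            if cand:
                cand.sort(reverse=True)
                rs[i] = (cand[0][2], ln)
    # clamp and deduplicate overlapping runs per row
    for rs in runs_by_row.values():
        rs.sort()
        cleaned = []
        for s, ln in rs:
            s = max(0, min(s, n_center if kind == "ins" else max(0, n_center - ln)))
            if cleaned and kind == "del" and s < cleaned[-1][0] + cleaned[-1][1]:
                ps, pl = cleaned[-1]
                cleaned[-1] = (ps, max(pl, s + ln - ps))
            else:
                cleaned.append((s, ln))
        rs[:] = cleaned


def _thread_from_runs(pep: str, del_runs, ins_runs, inserts, n_center: int) -> str:
    """Build an aligned peptide row from normalized run lists."""
    deleted = set()
    for s, ln in del_runs:
        deleted.update(range(s, s + ln))
    ins_at = {cpos: ln for cpos, ln in ins_runs}
    out = []
    k = 0  # next residue of pep
    for i in range(n_center + 1):
        ln = ins_at.get(i, 0)
        out.append(pep[k : k + ln].ljust(inserts[i], "-"))
        k += ln
        if i < n_center:
            if i in deleted:
                out.append("-")
            else:
                out.append(pep[k] if k < len(pep) else "-")
                k += 1
    # any residues not consumed (bookkeeping drift) are appended; the
    # backthreading assert guards against real inconsistency
    if k < len(pep):
        out.append(pep[k:])
    return "".join(out)


def _alignment_path(aln, n_center: int, n_other: int):
    """Pairwise alignment as a list of (center_idx | None, other_idx | None)."""
    path = []
    (tb, qb) = (0, 0)
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for k in range(tb, ts):
            path.append((k, None))
        for k in range(qb, qs):
            path.append((None, k))
        for k in range(te - ts):
            path.append((ts + k, qs + k))
        tb, qb = te, qe
    for k in range(tb, n_center):
        path.append((k, None))
    for k in range(qb, n_other):
        path.append((None, k))
    return path



def _thread_center(pep: str, inserts):
    out = []
    for i, aa in enumerate(pep):
        out.append("-" * inserts[i])
        out.append(aa)
    out.append("-" * inserts[len(pep)])
    return "".join(out)



def _backthread(pep_row: str, cds: str, trim: int) -> str:
    usable = cds[: len(cds) - trim] if trim else cds
    out = []
    k = 0
    for aa in pep_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(usable[k : k + 3])
            k += 3
    assert k == len(usable), "back-threading must consume the whole CDS"
    return "".join(out)


def detect_codon_indels(alignment: CodonAlignment,
                        reference: str | None = None) -> list[CodonIndel]:
    """Call in-frame indels from a codon alignment.

    Each maximal gap run yields indel intervals; runs sharing boundaries
    across rows are decomposed into atomic sub-intervals (a row carries an
    atom iff its gap covers it).  Any gap run with length not divisible by
    3 raises a frame error.  Polarity: rows gapped at an atom are deletion
    carriers when they are the minority, otherwise the non-gap rows carry
    an insertion; ties break toward deletion.
    """
    if not alignment.frame_valid:
        raise ValueError("alignment is not frame-valid")
    runs_by_row = {}
    boundaries = set()
    for t, row in zip(alignment.taxa, alignment.rows):
        runs = _gap_runs(row)
        for s, e in runs:
            if (e - s + 1) % 3:
                raise ValueError(
                    f"gap run of length {e - s + 1} in row {t} breaks the reading frame")
            boundaries.add(s)
            boundaries.add(e + 1)
        runs_by_row[t] = runs
    if not boundaries:
        return []
    cuts = sorted(boundaries)
    atoms = [(a, b - 1) for a, b in zip(cuts, cuts[1:])]
    n_rows = len(alignment.taxa)
    ref_row = alignment.row(reference) if reference in (alignment.taxa or []) else None
    indels = []
    for a, b in atoms:
        gapped = frozenset(
            t for t in alignment.taxa
            if any(s <= a and b <= e for s, e in runs_by_row[t])
        )
        if not gapped:
            continue
        length = b - a + 1
        if 2 * len(gapped) <= n_rows:  # gapped rows minority (or tie) -> deletion
            carriers, signed = gapped, -length
        else:
            carriers = frozenset(alignment.taxa) - gapped
            signed = +length
        ref_pos = _reference_position(ref_row, a, signed) if ref_row else None
        indel = CodonIndel(gene=alignment.gene, start_col=a + 1,
                           end_col=b + 1, length=signed,
                           carriers=carriers, ref_position=ref_pos)
        if ref_row is not None and reference not in carriers:
            _refine_ref_position(alignment, ref_row, indel)
        indels.append(indel)
    return indels


def _refine_ref_position(alignment, ref_row: str, indel: CodonIndel,
                         window: int = 15, flank: int = 45) -> None:
    """Nucleotide-level position refinement.

    A peptide alignment cannot distinguish gap placements that yield the
    same protein (synonymous flanking codons), so the reported reference
    position can sit a codon or two off the placement the nucleotides
    support.  Slide the indel in codon steps within ``window`` nt and
    adopt a shifted position only when reconstructing the carrier from
    the reference at that position matches the carrier sequence
    perfectly over ``flank`` nucleotides on both sides; otherwise the
    alignment-derived position stands.
    """
    ref_seq = ref_row.replace("-", "")
    carrier = sorted(indel.carriers)[0]
    car_seq = alignment.row(carrier).replace("-", "")
    m = abs(indel.length)
    p0 = indel.ref_position
    best = None
    for dp in range(-window, window + 1, 3):
        p = p0 + dp
        if p < 1:
            continue
        if indel.length < 0:
            if p - 1 + m > len(ref_seq):
                continue
            recon = ref_seq[: p - 1] + ref_seq[p - 1 + m :]
        else:
            if p - 1 + m > len(car_seq):
                continue
            content = car_seq[p - 1 : p - 1 + m]
            recon = ref_seq[: p - 1] + content + ref_seq[p - 1 :]
        if len(recon) != len(car_seq):
            continue
        a = max(0, p - 1 - flank)
        b = min(len(car_seq), p - 1 + m + flank)
        if recon[a:b] == car_seq[a:b]:
            cand = (abs(dp), dp)
            if best is None or cand < best:
                best = cand
    if best is not None:
        indel.ref_position = p0 + best[1]


def _gap_runs(row: str):
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(row) - 1))
    # terminal runs are alignment padding, not indels
    return [(s, e) for s, e in runs if s != 0 and e != len(row) - 1]


def _reference_position(ref_row: str, col0: int, signed: int) -> int:
    bases_before = sum(1 for ch in ref_row[:col0] if ch != "-")
    return bases_before + 1


def indels_to_characters(indels: list[CodonIndel], taxa: list[str],
                         matrix=None, prefix: str = "D"):
    """Turn indels into binary character columns (carrier = 1).

    Single-carrier indels are flagged autapomorphic and excluded from the
    synapomorphy search, consistent with the singleton-loss policy.
    Returns ``(matrix, autapomorphic_indels)``; pass an existing
    StructuralCharacterMatrix to append in place.
    """
    from .parsimony_map import StructuralCharacterMatrix

    if matrix is None:
        matrix = StructuralCharacterMatrix(taxa=list(taxa))
    auto = []
    k = sum(1 for cid, cls, _ in matrix.characters if cls == "D")
    for indel in sorted(indels, key=lambda d: (str(d.gene), d.start_col, d.length)):
        if len(indel.carriers) < 2:
            auto.append(indel)
            continue
        k += 1
        desc = (f"{indel.gene} cols {indel.start_col}-{indel.end_col} "
                f"{'+' if indel.length > 0 else ''}{indel.length}")
        matrix.add(f"{prefix}{k}", "D", desc, set(indel.carriers))
    return matrix, auto
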