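"""End-to-end orchestration: scan -> compare -> indels -> map.

The pipeline mirrors the step-by-step comparative protocol: every genome
is scanned (repeat partition, canonical gene order, gene content, tRNA
validation), compared against a designated reference taxon (boundary
shifts, codon indels), and the resulting binary characters are mapped
onto the fixed input tree by parsimony.  Inversions are inferred
branch-wise down the tree: each internal node inherits its parent's
reconstructed gene order, a least-derived leaf of the subtree provides
the node's order, and the minimal reversal scenario between the two is
charged to that branch.  This keeps per-branch scenarios small (where
exact search is trustworthy) and naturally expresses nested inversions
accumulated across successive branches.

Character-to-parsimony defaults follow the loss asymmetry of plastid
genes: gene/intron/tRNA losses map under Dollo (ancestrally present,
losses only), inversions, boundary shifts, codon indels and anticodon
changes under Fitch.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .plastome_io import GeneSymbol, GenomeRecord, extract_gene_order
from .ir_regions import assign_regions, call_boundary_shift, find_inverted_repeat
from .synteny_inversions import (
    breakpoint_distance,
    infer_inversions,
    to_signed_permutation,
)
from .gene_content import (
    apply_singleton_filter,
    assess_gene,
    detect_intron_loss,
    validate_trna,
)
from .codon_indels import codon_align, detect_codon_indels, indels_to_characters
from .parsimony_map import (
    MappedChange,
    Phylogeny,
    StructuralCharacterMatrix,
    dollo_map,
    fitch_map,
)

__all__ = ["RunConfig", "ReportBundle", "MappedEvent", "run_pipeline",
           "canonical_branch"]


@dataclass
class RunConfig:
    reference: str
    anchor: str = "ycf1"
    loss_threshold: float = 0.70
    ir_min_len: int = 1000
    ir_min_identity: float = 1.0
    max_events: int = 6
    resolution: str = "ACCTRAN"
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(repr(sorted(self.__dict__.items())).encode()).hexdigest()[:16]


@dataclass
class MappedEvent:
    """One labeled, branch-placed structural event in the output ledger."""

    label: str
    cls: str  # V | R | G | T | D
    branch: str  # child-node label
    direction: str
    classification: str
    detail: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    config: RunConfig
    taxa: list[str]
    partitions: dict
    orders: dict
    gene_status: list
    trna_reports: dict
    boundary_shifts: dict
    indels: list
    matrix: StructuralCharacterMatrix
    events: list[MappedEvent]
    manifest: dict

    def events_by_class(self, cls: str) -> list[MappedEvent]:
        return [e for e in self.events if e.cls == cls]

    def ledger_json(self) -> str:
        per_branch: dict[str, list] = {}
        for ev in self.events:
            per_branch.setdefault(ev.branch, []).append(
                {"label": ev.label, "class": ev.cls, "direction": ev.direction,
                 "classification": ev.classification, "detail": ev.detail})
        return json.dumps({"manifest": self.manifest, "branches": per_branch},
                          indent=2, sort_keys=True, default=str)


def canonical_branch(tree: Phylogeny, child_label: str) -> str:
    """Canonical name for a branch: the two root-adjacent edges of a rooted
    two-child tree are the same unrooted edge, so both map to the larger
    (ingroup-side) child."""
    node = tree.node(child_label)
    parent = node.parent_node
    if parent is tree.root and len(tree.root.child_nodes()) == 2:
        kids = tree.root.child_nodes()
        big = max(kids, key=lambda k: (len(tree.leaf_set(k)), k.plabel))
        return big.plabel
    return child_label


# ---------------------------------------------------------------------------
# Stage 1: scan


def _scan(records: dict[str, GenomeRecord], config: RunConfig):
    anchor = GeneSymbol(config.anchor)
    partitions, orders, assigns = {}, {}, {}
    for taxon, rec in records.items():
        part = find_inverted_repeat(rec, config.ir_min_len, config.ir_min_identity)
        if part is None:
            raise RuntimeError(f"scan: no inverted repeat found in {taxon}")
        partitions[taxon] = part
        orders[taxon] = extract_gene_order(rec, part, anchor)
        assigns[taxon] = assign_regions(part, rec)
    return partitions, orders, assigns


def _reference_sequences(records: dict, reference: str):
    """Reference CDS/tRNA catalog over the union of annotated genes.

    A gene the reference taxon itself lacks (it may carry the loss under
    study) is represented by the copy from the alphabetically first taxon
    still possessing it.
    """
    cds, trna, multi_exon = {}, {}, {}
    order = [reference] + sorted(t for t in records if t != reference)
    for taxon in order:
        rec = records[taxon]
        for f in rec.features:
            if f.kind == "CDS" and f.symbol not in cds:
                cds[f.symbol] = f.extract(rec.sequence)
                if len(f.parts) > 1:
                    multi_exon[f.symbol] = f
            elif f.kind == "tRNA" and f.symbol not in trna:
                trna[f.symbol] = f.extract(rec.sequence)
    return cds, trna, multi_exon


def _gene_content(records, config: RunConfig):
    ref_cds, ref_trna, ref_multi = _reference_sequences(records, config.reference)
    statuses = []
    trna_reports = {}
    intron_statuses = []
    for taxon, rec in records.items():
        feats = {}
        for f in rec.features:
            feats.setdefault(f.symbol, f)
        for sym, ref_seq in ref_cds.items():
            cand = feats[sym].extract(rec.sequence) if sym in feats else None
            statuses.append(assess_gene(cand, ref_seq, taxon=taxon, symbol=sym,
                                        threshold=config.loss_threshold))
        for sym, ref_feat in ref_multi.items():
            intron_statuses.extend(
                detect_intron_loss(feats.get(sym), ref_feat, taxon=taxon))
        reports = []
        for sym in ref_trna:
            if sym in feats:
                seq = feats[sym].extract(rec.sequence)
                reports.append(validate_trna(seq, sym, taxon=taxon))
            else:
                reports.append(_absent_trna(taxon, sym))
        trna_reports[taxon] = reports
    statuses = apply_singleton_filter(statuses)
    return statuses, trna_reports, intron_statuses


def _absent_trna(taxon, sym):
    from .gene_content import TrnaValidation

    return TrnaValidation(taxon, sym, False, None, False, "hypothetical-loss")


# ---------------------------------------------------------------------------
# Stage 2: branch-wise inversion inference


def _subtree_rep(tree, node, orders, parent_order):
    """Least-derived leaf of a subtree relative to the parent order:
    minimal breakpoint distance, then fewest dropped genes, then name."""
    def key(leaf):
        perm = to_signed_permutation(orders[leaf], parent_order)
        return (breakpoint_distance(perm),
                len(perm.dropped_sample) + len(perm.dropped_reference), leaf)

    leaves = [node.plabel] if node.is_leaf() else sorted(tree.leaf_set(node))
    return min(leaves, key=key)


def _delta_events(orders, rep, parent_order, max_events):
    perm = to_signed_permutation(orders[rep], parent_order)
    events, status = infer_inversions(perm, max_events=max_events)
    shared = {str(s) for s in perm.shared_genes}
    return events, status, shared


def _spans_match(s1, s2, shared1, shared2):
    both = shared1 & shared2
    a, b = s1 & both, s2 & both
    return bool(a) and a == b


def _apply_span_to_order(order, span_syms: set):
    """Reverse the minimal contiguous slice of ``order`` covering
    ``span_syms`` (sign-flipping).  Returns a new order list."""
    idx = [i for i, (s, _) in enumerate(order) if str(s) in span_syms]
    if not idx:
        return list(order)
    i, j = min(idx), max(idx)
    seg = [(s, "+" if g == "-" else "-") for s, g in order[i : j + 1]][::-1]
    return list(order[:i]) + seg + list(order[j + 1 :])


def infer_branch_inversions(tree: Phylogeny, orders, config: RunConfig):
    """Charge minimal reversal scenarios to tree branches, top-down.

    Each internal node's branch receives only the reversals shared by all
    of its child subtrees (each subtree speaking through its least-derived
    leaf); the node's reconstructed order is the parent order with those
    shared reversals applied.  Leaf branches receive their full remaining
    delta.  Events are matched across subtrees by span-gene set restricted
    to the genes both representatives retain, so losses below one child do
    not obscure a shared inversion.

    Returns a list of (branch_child_label, events, status) triples.
    """
    results = []
    node_orders = {}
    root = tree.root
    node_orders[id(root)] = orders[config.reference]
    for node in tree.preorder():
        if node is root:
            continue
        parent_order = node_orders[id(node.parent_node)]
        if node.is_leaf():
            events, status, _ = _delta_events(orders, node.plabel, parent_order,
                                              config.max_events)
            if events or status == "unresolved":
                results.append((node.plabel, events, status))
            node_orders[id(node)] = orders[node.plabel]
            continue
        deltas = []
        unresolved = False
        for child in node.child_nodes():
            rep = _subtree_rep(tree, child, orders, parent_order)
            events, status, shared = _delta_events(orders, rep, parent_order,
                                                   config.max_events)
            if status == "unresolved":
                unresolved = True
            deltas.append((events, shared))
        if unresolved:
            results.append((node.plabel, [], "unresolved"))
            node_orders[id(node)] = parent_order
            continue
        # branch events = reversals present in every child subtree's delta
        first_events, first_shared = deltas[0]
        common = []
        for ev in first_events:
            span = {str(s) for s in ev.span_genes}
            if all(any(_spans_match(span, {str(s) for s in e2.span_genes},
                                    first_shared, sh2) for e2 in evs2)
                   for evs2, sh2 in deltas[1:]):
                common.append(ev)
        new_order = list(parent_order.order)
        for ev in common:
            new_order = _apply_span_to_order(new_order, {str(s) for s in ev.span_genes})
        if common:
            results.append((node.plabel, common, "resolved"))
        node_orders[id(node)] = type(parent_order)(
            taxon=node.plabel, order=new_order, anchor=parent_order.anchor,
            ir_collapsed=True)
    return results


# ---------------------------------------------------------------------------
# Stage 3: character building


def _region_char_states(assigns, ref_assign, taxa):
    """Per-gene IR-membership characters vs the reference assignment.

    One character per gene that entered the repeat somewhere ("in"), one
    per reference-IR gene that left it ("out"), one per boundary-partial
    exon tag.  Taxa lacking the gene score '?'.
    """
    chars = {}  # (sym_str, tag) -> {taxon: state}
    all_syms = sorted({s for a in assigns.values() for s in a}, key=str)
    for sym in all_syms:
        ref_state = ref_assign.get(sym)
        ref_in_ir = ref_state == "IR"
        col_in, col_out = {}, {}
        partial_tags = set()
        for taxon in taxa:
            a = assigns[taxon]
            if sym not in a:
                col_in[taxon] = col_out[taxon] = "?"
                continue
            v = a[sym]
            col_in[taxon] = "1" if v == "IR" else "0"
            col_out[taxon] = "1" if v != "IR" else "0"
            if isinstance(v, tuple):
                partial_tags.add(v[1])
        if not ref_in_ir and any(x == "1" for x in col_in.values()):
            chars[(str(sym), "in")] = col_in
        if ref_in_ir and any(x == "1" for x in col_out.values()):
            chars[(str(sym), "out")] = col_out
        ref_tag = ref_state[1] if isinstance(ref_state, tuple) else None
        for tag in sorted(partial_tags):
            if tag == ref_tag:
                continue
            full = {}
            for taxon in taxa:
                a = assigns[taxon]
                if sym not in a:
                    full[taxon] = "?"
                else:
                    v = a[sym]
                    full[taxon] = "1" if (isinstance(v, tuple) and v[1] == tag) else "0"
            chars[(str(sym), tag)] = full
    return chars


def run_pipeline(records: dict[str, GenomeRecord], tree: Phylogeny,
                 config: RunConfig) -> ReportBundle:
    """Run the full analysis on in-memory records.

    ``records`` must cover every leaf of ``tree``; ``config.reference``
    names the reference taxon (a leaf).
    """
    if config.reference not in records:
        raise ValueError(f"reference taxon {config.reference!r} not among inputs")
    missing = set(tree.leaves()) - set(records)
    if missing:
        raise ValueError(f"genomes missing for leaves: {sorted(missing)}")
    taxa = sorted(records)

    partitions, orders, assigns = _scan(records, config)
    statuses, trna_reports, intron_statuses = _gene_content(records, config)
    ref_assign = assigns[config.reference]
    shifts = {t: call_boundary_shift(assigns[t], ref_assign, taxon=t)
              for t in taxa}

    # codon indels over every shared protein-coding gene; pseudogene rows
    # (status != present) are excluded so degraded copies cannot inject
    # spurious indel characters
    ref_cds, _, _ = _reference_sequences(records, config.reference)
    present = {(st.taxon, str(st.symbol)) for st in statuses
               if st.status == "present"}
    all_indels = []
    for sym in sorted(ref_cds, key=str):
        cds_set = {}
        for taxon, rec in records.items():
            if (taxon, str(sym)) not in present:
                continue
            for f in rec.features:
                if f.symbol == sym and f.kind == "CDS":
                    cds_set[taxon] = f.extract(rec.sequence)
                    break
        if len(cds_set) < 2:
            continue
        aln = codon_align(cds_set, gene=sym, center=config.reference)
        all_indels.extend(detect_codon_indels(aln, reference=config.reference))

    matrix = StructuralCharacterMatrix(taxa=list(taxa))
    events: list[MappedEvent] = []

    # --- V: branch-wise inversion inference ---------------------------
    v_results = infer_branch_inversions(tree, orders, config)
    vk = 0
    for branch, evs, status in v_results:
        if status == "unresolved":
            events.append(MappedEvent(label=f"V?{branch}", cls="V", branch=branch,
                                      direction="gain", classification="unresolved",
                                      detail={"status": "unresolved"}))
            continue
        for ev in evs:
            vk += 1
            label = f"V{vk}"
            carriers = set(tree.leaf_set(tree.node(branch)))
            matrix.add(label, "V", f"inversion {ev.left_flank}..{ev.right_flank}",
                       carriers)
            events.append(MappedEvent(
                label=label, cls="V", branch=branch, direction="gain",
                classification="synapomorphy" if len(carriers) >= 2 else "autapomorphy",
                detail={"left": str(ev.left_flank), "right": str(ev.right_flank),
                        "span_genes": [str(s) for s in ev.span_genes]}))

    # --- R: per-gene IR membership characters --------------------------
    # Boundary-shift characters map DELTRAN regardless of the global
    # resolution: repeat expansions recur independently across lineages,
    # and pulling ambiguous gains rootward would invent contractions the
    # samples do not show.
    r_chars = _region_char_states(assigns, ref_assign, taxa)
    r_branch_gains: dict[str, dict] = {}
    for (sym_str, tag), states in sorted(r_chars.items()):
        steps, changes = fitch_map(tree, states, resolution="DELTRAN",
                                   character_id=f"{sym_str}:{tag}")
        for ch in changes:
            branch = ch.branch[1]
            slot = r_branch_gains.setdefault(
                branch, {"gained": [], "lost": [], "partial": [],
                         "classification": ch.classification})
            if tag == "in" and ch.direction == "gain":
                slot["gained"].append(sym_str)
            elif tag == "out" and ch.direction == "gain":
                slot["lost"].append(sym_str)
            elif tag not in ("in", "out") and ch.direction == "gain":
                slot["partial"].append((sym_str, tag))
            else:
                # a reversal of membership inside the clade
                slot["lost" if tag == "in" else "gained"].append(sym_str)
    rk = 0
    for branch in sorted(r_branch_gains,
                         key=lambda b: _preorder_rank(tree, b)):
        slot = r_branch_gains[branch]
        rk += 1
        label = f"R{rk}"
        carriers = set(tree.leaf_set(tree.node(branch)))
        side = _shift_side(slot, ref_assign)
        matrix.add(label, "R", f"IR boundary shift ({side})", carriers)
        events.append(MappedEvent(
            label=label, cls="R", branch=branch, direction="gain",
            classification=slot["classification"],
            detail={"gained": sorted(slot["gained"]), "lost": sorted(slot["lost"]),
                    "partial": sorted(slot["partial"]), "side": side}))

    # --- G: gene losses (Dollo) + intron losses ------------------------
    gk = 0
    loss_by_gene: dict[str, set] = {}
    status_lookup = {}
    for st in statuses:
        status_lookup[(st.taxon, str(st.symbol))] = st
        if st.status == "lost":
            loss_by_gene.setdefault(str(st.symbol), set()).add(st.taxon)
    for sym_str in sorted(loss_by_gene):
        presence = {t: ("0" if t in loss_by_gene[sym_str] else "1") for t in taxa}
        steps, changes = dollo_map(tree, presence, character_id=sym_str,
                                   ancestral_present=True)
        gk += 1
        label = f"G{gk}"
        matrix.add(label, "G", f"loss of {sym_str}", loss_by_gene[sym_str])
        for ch in changes:
            events.append(MappedEvent(
                label=label, cls="G", branch=ch.branch[1], direction="loss",
                classification=ch.classification,
                detail={"gene": sym_str, "kind": "gene-loss"}))
    intron_loss: dict[tuple, dict] = {}
    for st in intron_statuses:
        key = (str(st.symbol), st.intron_index)
        col = intron_loss.setdefault(key, {})
        col[st.taxon] = {"lost": "0", "retained": "1", "gene-absent": "?"}[st.status]
    for (sym_str, idx), col in sorted(intron_loss.items()):
        full = {t: col.get(t, "1") for t in taxa}
        if not any(v == "0" for v in full.values()):
            continue
        steps, changes = dollo_map(tree, full, character_id=f"{sym_str}:intron{idx}",
                                   ancestral_present=True)
        gk += 1
        label = f"G{gk}"
        matrix.add(label, "G", f"loss of {sym_str} intron {idx}",
                   {t for t, v in full.items() if v == "0"})
        for ch in changes:
            events.append(MappedEvent(
                label=label, cls="G", branch=ch.branch[1], direction="loss",
                classification=ch.classification,
                detail={"gene": sym_str, "intron": idx, "kind": "intron-loss"}))

    # --- T: tRNA losses (Dollo) + anticodon changes (Fitch) ------------
    tk = 0
    trna_loss: dict[str, set] = {}
    anticodon_changes: dict[tuple, set] = {}
    for taxon, reports in trna_reports.items():
        for rep in reports:
            sym_str = str(rep.locus_symbol)
            if rep.verdict == "hypothetical-loss":
                trna_loss.setdefault(sym_str, set()).add(taxon)
            elif rep.verdict == "anticodon-change":
                anticodon_changes.setdefault(
                    (sym_str, rep.anticodon_observed), set()).add(taxon)
    for sym_str in sorted(trna_loss):
        carriers = trna_loss[sym_str]
        if len(carriers) < 2:
            continue  # singleton policy applies to tRNA losses as well
        presence = {t: ("0" if t in carriers else "1") for t in taxa}
        steps, changes = dollo_map(tree, presence, character_id=sym_str,
                                   ancestral_present=True)
        tk += 1
        label = f"T{tk}"
        matrix.add(label, "T", f"loss of {sym_str}", carriers)
        for ch in changes:
            events.append(MappedEvent(
                label=label, cls="T", branch=ch.branch[1], direction="loss",
                classification=ch.classification,
                detail={"trna": sym_str, "kind": "trna-loss"}))
    for (sym_str, obs), carriers in sorted(anticodon_changes.items()):
        states = {t: ("1" if t in carriers else "0") for t in taxa}
        steps, changes = fitch_map(tree, states, resolution=config.resolution,
                                   character_id=f"{sym_str}->{obs}")
        tk += 1
        label = f"T{tk}"
        matrix.add(label, "T", f"anticodon change {sym_str} -> {obs}", carriers)
        for ch in changes:
            events.append(MappedEvent(
                label=label, cls="T", branch=ch.branch[1], direction=ch.direction,
                classification=ch.classification,
                detail={"trna": sym_str, "new_anticodon": obs,
                        "kind": "anticodon-change"}))

    # --- D: codon indels ------------------------------------------------
    matrix, autapomorphic = indels_to_characters(all_indels, taxa, matrix=matrix)
    d_chars = [(cid, desc) for cid, cls, desc in matrix.characters if cls == "D"]
    indel_by_char = {}
    kept = [i for i in sorted(all_indels, key=lambda d: (str(d.gene), d.start_col,
                                                         d.length))
            if len(i.carriers) >= 2]
    for (cid, desc), indel in zip(d_chars, kept):
        indel_by_char[cid] = indel
    # Indel characters map DELTRAN: an exact back-mutation restoring
    # deleted codons is implausible, so ambiguous placements resolve as
    # independent recurrences rather than gain-then-reversal.  A mapped
    # "loss" of the minority state is re-expressed as the complementary
    # event (majority-polarity calls are provisional; the tree decides).
    for cid, cls, desc in matrix.characters:
        if cls != "D":
            continue
        states = matrix.column(cid)
        steps, changes = fitch_map(tree, states, resolution="DELTRAN",
                                   character_id=cid)
        indel = indel_by_char[cid]
        for ch in changes:
            length = indel.length if ch.direction == "gain" else -indel.length
            events.append(MappedEvent(
                label=cid, cls="D", branch=ch.branch[1], direction="gain",
                classification=ch.classification,
                detail={"gene": str(indel.gene), "ref_position": indel.ref_position,
                        "length": length, "start_col": indel.start_col,
                        "end_col": indel.end_col,
                        "polarity_normalized": ch.direction == "loss"}))

    manifest = {
        "config": config.digest(),
        "seed": config.seed,
        "reference": config.reference,
        "n_taxa": len(taxa),
        "n_characters": len(matrix.characters),
        "n_events": len(events),
    }
    return ReportBundle(
        config=config, taxa=taxa, partitions=partitions, orders=orders,
        gene_status=statuses, trna_reports=trna_reports,
        boundary_shifts=shifts, indels=all_indels, matrix=matrix,
        events=events, manifest=manifest,
    )


def _preorder_rank(tree: Phylogeny, label: str) -> int:
    for i, n in enumerate(tree.preorder()):
        if n.plabel == label:
            return i
    return 1 << 30


def _shift_side(slot, ref_assign) -> str:
    sides = set()
    for sym_str in slot["gained"] + [p[0] for p in slot["partial"]]:
        for s, v in ref_assign.items():
            if str(s) == sym_str and v in ("LSC", "SSC"):
                sides.add(v)
    for sym_str in slot["lost"]:
        sides.add("LSC")
    return "both" if len(sides) > 1 else (sides.pop() if sides else "")
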