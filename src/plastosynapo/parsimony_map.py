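"""Parsimony mapping of binary structural characters onto a fixed tree.

Characters (inversions, boundary shifts, gene/intron/tRNA losses, codon
indels) are mapped by unweighted parsimony.  Fitch lengths are computed by
a unit-cost dynamic programme over node states, which is exact on
multifurcating trees as well; ACCTRAN/DELTRAN are realized as tie-breaking
rules in the top-down state-assignment pass.  Gene-presence characters can
instead be mapped under Dollo parsimony (a single gain, unlimited losses),
reflecting the asymmetry that plastid genes are easy to lose and hard to
regain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = [
    "Phylogeny",
    "StructuralCharacterMatrix",
    "MappedChange",
    "read_newick",
    "fitch_map",
    "dollo_map",
    "compare_topologies",
]

_INF = 1 << 30


@dataclass
class MappedChange:
    """One parsimony-placed state change on a branch (parent, child)."""

    character_id: str
    branch: tuple[str, str]
    direction: str  # gain | loss
    min_steps: int
    classification: str  # synapomorphy | autapomorphy | homoplasy


@dataclass
class StructuralCharacterMatrix:
    """taxa x binary characters (0/1/?) with V/R/G/T/D class labels."""

    taxa: list[str]
    characters: list[tuple[str, str, str]] = field(default_factory=list)  # (id, class, description)
    states: dict[str, dict[str, str]] = field(default_factory=dict)  # char id -> taxon -> "0"/"1"/"?"

    def add(self, char_id: str, char_class: str, description: str,
            carriers: set[str], missing: set[str] | None = None) -> None:
        self.characters.append((char_id, char_class, description))
        row = {}
        for t in self.taxa:
            if missing and t in missing:
                row[t] = "?"
            else:
                row[t] = "1" if t in carriers else "0"
        self.states[char_id] = row

    def column(self, char_id: str) -> dict[str, str]:
        return self.states[char_id]

    def to_frame(self):
        import pandas as pd

        data = {cid: [self.states[cid][t] for t in self.taxa]
                for cid, _, _ in self.characters}
        return pd.DataFrame(data, index=self.taxa)

    def to_nexus(self) -> str:
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.characters)};",
                 '  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";', "  MATRIX"]
        for t in self.taxa:
            row = "".join(self.states[cid][t] for cid, _, _ in self.characters)
            lines.append(f"    {t} {row}")
        lines += ["  ;", "END;"]
        return "\n".join(lines)


class Phylogeny:
    """Rooted tree wrapper around a dendropy Tree.

    Node handles are dendropy nodes; every node gets a stable ``label``:
    the taxon label for leaves, the internal-node label where the Newick
    provides one, otherwise ``nodeN`` in preorder.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        seen: set[str] = set()
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
            else:
                label = node.label
            if not label:
                label = f"node{counter}"
            counter += 1
            if node.is_leaf() and label in seen:
                raise ValueError(f"duplicate leaf label: {label}")
            seen.add(label)
            node.plabel = label

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
        tree.is_rooted = True
        return cls(tree)

    @property
    def root(self):
        return self.tree.seed_node

    def leaves(self) -> list[str]:
        return [n.plabel for n in self.tree.leaf_node_iter()]

    def node(self, label: str):
        for n in self.tree.preorder_node_iter():
            if n.plabel == label:
                return n
        raise KeyError(label)

    def leaf_set(self, node) -> frozenset:
        return frozenset(l.plabel for l in node.leaf_iter())

    def mrca(self, labels):
        labels = set(labels)
        best = None
        for n in self.tree.postorder_node_iter():
            if labels <= self.leaf_set(n):
                if best is None or len(self.leaf_set(n)) < len(self.leaf_set(best)):
                    best = n
        return best

    def preorder(self):
        return list(self.tree.preorder_node_iter())

    def postorder(self):
        return list(self.tree.postorder_node_iter())


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree, preserving internal node labels."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text)


def _leaf_costs(state: str):
    if state == "1":
        return {0: _INF, 1: 0}
    if state == "0":
        return {0: 0, 1: _INF}
    return {0: 0, 1: 0}  # '?': missing, free choice


def _sankoff_costs(tree: Phylogeny, states: dict[str, str]):
    """Bottom-up unit-cost DP.  Returns {node: {0: cost, 1: cost}}."""
    costs = {}
    for node in tree.postorder():
        if node.is_leaf():
            costs[node] = _leaf_costs(states.get(node.plabel, "?"))
        else:
            c = {0: 0, 1: 0}
            for child in node.child_nodes():
                cc = costs[child]
                for s in (0, 1):
                    c[s] += min(cc[0] + (s != 0), cc[1] + (s != 1))
            costs[node] = c
    return costs


def fitch_map(
    tree: Phylogeny,
    states: dict[str, str],
    resolution: str = "ACCTRAN",
    character_id: str = "",
):
    """Map a binary character by Fitch parsimony.

    Returns ``(min_steps, [MappedChange, ...])``.  Missing leaves ('?')
    contribute no cost.  Ambiguous placements are resolved ACCTRAN
    (changes pulled toward the root) or DELTRAN (pushed toward the tips);
    both resolutions have identical step counts.
    """
    resolution = resolution.upper()
    if resolution not in ("ACCTRAN", "DELTRAN"):
        raise ValueError("resolution must be ACCTRAN or DELTRAN")
    costs = _sankoff_costs(tree, states)
    root = tree.root
    min_steps = min(costs[root].values())
    if min_steps == 0:
        return 0, []
    # top-down assignment; root ties resolve to ancestral-absent (state 0)
    assign = {}
    root_state = 0 if costs[root][0] <= costs[root][1] else 1
    assign[root] = root_state
    changes = []
    for node in tree.preorder():
        if node is root:
            continue
        p = assign[node.parent_node]
        c = costs[node]
        keep = c[p]
        flip = c[1 - p] + 1
        if flip < keep:
            s = 1 - p
        elif keep < flip:
            s = p
        else:  # tie: ACCTRAN changes now, DELTRAN delays
            s = (1 - p) if resolution == "ACCTRAN" else p
        assign[node] = s
        if s != p:
            changes.append((node, "gain" if s == 1 else "loss"))
    mapped = []
    for node, direction in changes:
        if min_steps == 1:
            cls = "synapomorphy" if len(tree.leaf_set(node)) >= 2 else "autapomorphy"
        else:
            cls = "homoplasy"
        mapped.append(MappedChange(
            character_id=character_id,
            branch=(node.parent_node.plabel, node.plabel),
            direction=direction, min_steps=min_steps, classification=cls,
        ))
    assert len(mapped) == min_steps, "placed changes must equal the Fitch length"
    return min_steps, mapped


def dollo_map(
    tree: Phylogeny,
    states: dict[str, str],
    character_id: str = "",
    ancestral_present: bool | None = None,
):
    """Map a binary character under Dollo parsimony.

    The derived state (1) originates exactly once, at the MRCA of all
    1-leaves; every 0-leaf below that gain is explained by a loss on the
    stem of a maximal all-0 subtree.  With ``ancestral_present`` (or when
    the gain lands on the root) the state is taken as ancestrally present
    and only losses are counted.  Returns ``(steps, changes)``.
    """
    ones = [t for t, s in states.items() if s == "1"]
    if not ones:
        return 0, []
    gain_node = tree.mrca(ones)
    at_root = gain_node is tree.root
    if ancestral_present is None:
        ancestral_present = at_root
    if ancestral_present:
        gain_node = tree.root  # present at the root: only losses below it
    changes = []
    steps = 0
    if not ancestral_present and not at_root:
        cls = "synapomorphy" if len(tree.leaf_set(gain_node)) >= 2 else "autapomorphy"
        changes.append(MappedChange(
            character_id=character_id,
            branch=(gain_node.parent_node.plabel, gain_node.plabel),
            direction="gain", min_steps=0, classification=cls,
        ))
        steps += 1

    # all-0 flags (missing '?' leaves count as compatible with either state,
    # and never force a loss on their own)
    all_zero = {}
    has_zero = {}
    for node in tree.postorder():
        if node.is_leaf():
            s = states.get(node.plabel, "?")
            all_zero[node] = s != "1"
            has_zero[node] = s == "0"
        else:
            kids = node.child_nodes()
            all_zero[node] = all(all_zero[k] for k in kids)
            has_zero[node] = any(has_zero[k] for k in kids)

    def walk(node):
        nonlocal steps
        for child in node.child_nodes():
            if all_zero[child] and has_zero[child]:
                changes.append(MappedChange(
                    character_id=character_id,
                    branch=(node.plabel, child.plabel),
                    direction="loss", min_steps=0,
                    classification=("synapomorphy" if len(tree.leaf_set(child)) >= 2
                                    else "autapomorphy"),
                ))
                steps += 1
            elif not all_zero[child]:
                walk(child)

    walk(gain_node)
    for ch in changes:
        ch.min_steps = steps
    return steps, changes


def compare_topologies(states: dict[str, str], tree_a: Phylogeny, tree_b: Phylogeny):
    """Fitch lengths of one character on two trees over the same leaf set."""
    la, lb = set(tree_a.leaves()), set(tree_b.leaves())
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    sa, _ = fitch_map(tree_a, states)
    sb, _ = fitch_map(tree_b, states)
    return sa, sb
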