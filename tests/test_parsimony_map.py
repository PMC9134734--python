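"""Fitch/Dollo mapping, topology comparison, Newick handling."""

import itertools
import random

import pytest

from plastosynapo.parsimony_map import (
    Phylogeny,
    compare_topologies,
    dollo_map,
    fitch_map,
    read_newick,
)


def test_read_newick_basic(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B),C);\n")
    tree = read_newick(p)
    assert sorted(tree.leaves()) == ["A", "B", "C"]
    assert len(tree.root.child_nodes()) == 2


def test_internal_labels_preserved(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A,B)cladeX,C);\n")
    tree = read_newick(p)
    assert tree.node("cladeX") is not None
    assert tree.leaf_set(tree.node("cladeX")) == frozenset({"A", "B"})


def test_duplicate_leaves_rejected():
    with pytest.raises(Exception, match="(?i)duplicate"):
        Phylogeny.from_newick("((A,B),A);")


def test_malformed_newick_rejected():
    with pytest.raises(Exception):
        Phylogeny.from_newick("((A,B,;")


def test_sister_gain_is_synapomorphy():
    tree = Phylogeny.from_newick("((A,B)ab,(C,D)cd);")
    steps, changes = fitch_map(tree, {"A": "1", "B": "1", "C": "0", "D": "0"})
    assert steps == 1
    assert len(changes) == 1
    assert changes[0].branch[1] == "ab"
    assert changes[0].direction == "gain"
    assert changes[0].classification == "synapomorphy"


def test_constant_character_maps_nowhere():
    tree = Phylogeny.from_newick("((A,B),(C,D));")
    steps, changes = fitch_map(tree, {t: "0" for t in "ABCD"})
    assert steps == 0 and changes == []


def test_alternating_pattern_needs_two_steps():
    tree = Phylogeny.from_newick("((A,B),(C,D));")
    steps, _ = fitch_map(tree, {"A": "1", "B": "0", "C": "1", "D": "0"})
    assert steps == 2


def test_single_leaf_gain_is_autapomorphy():
    tree = Phylogeny.from_newick("((A,B),C);")
    steps, changes = fitch_map(tree, {"A": "1", "B": "0", "C": "0"})
    assert steps == 1
    assert changes[0].classification == "autapomorphy"


def _random_tree(rng, n):
    nodes = [f"L{i}" for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b})")
    return Phylogeny.from_newick(nodes[0] + ";")


def _exhaustive_min(tree, states):
    internal = [n for n in tree.postorder() if not n.is_leaf()]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        a = {id(n): s for n, s in zip(internal, assign)}
        cost = 0
        for n in tree.postorder():
            if n is tree.root:
                continue
            ps = a[id(n.parent_node)]
            if n.is_leaf():
                s = states.get(n.plabel, "?")
                if s == "?":
                    continue
                cost += int(s) != ps
            else:
                cost += a[id(n)] != ps
        if best is None or cost < best:
            best = cost
    return best


def test_fitch_equals_exhaustive_minimum_on_small_trees():
    rng = random.Random(31)
    for _ in range(60):
        n = rng.randint(3, 8)
        tree = _random_tree(rng, n)
        states = {l: rng.choice("0011?") for l in tree.leaves()}
        steps, changes = fitch_map(tree, states)
        assert steps == _exhaustive_min(tree, states)
        assert len(changes) == steps


def test_acctran_deltran_same_length_different_placement():
    rng = random.Random(7)
    for _ in range(30):
        tree = _random_tree(rng, rng.randint(4, 8))
        states = {l: rng.choice("01") for l in tree.leaves()}
        sa, _ = fitch_map(tree, states, resolution="ACCTRAN")
        sd, _ = fitch_map(tree, states, resolution="DELTRAN")
        assert sa == sd


def test_fitch_handles_polytomies():
    tree = Phylogeny.from_newick("(A,B,C,(D,E)de);")
    steps, _ = fitch_map(tree, {"A": "0", "B": "0", "C": "0", "D": "1", "E": "1"})
    assert steps == 1


def test_dollo_single_clade_gain():
    tree = Phylogeny.from_newick("((A,B)ab,(C,D));")
    steps, changes = dollo_map(tree, {"A": "1", "B": "1", "C": "0", "D": "0"})
    assert steps == 1
    assert changes[0].direction == "gain" and changes[0].branch[1] == "ab"


def test_dollo_ancestral_presence_two_losses():
    tree = Phylogeny.from_newick("((A,(B,C)bc)abc,((D,E)de,F)def);")
    states = {"A": "1", "B": "0", "C": "0", "D": "0", "E": "0", "F": "1"}
    steps, changes = dollo_map(tree, states, ancestral_present=True)
    assert steps == 2
    assert {c.branch[1] for c in changes} == {"bc", "de"}
    assert all(c.direction == "loss" for c in changes)


def test_dollo_at_least_fitch():
    rng = random.Random(13)
    for _ in range(40):
        tree = _random_tree(rng, rng.randint(3, 8))
        states = {l: rng.choice("01") for l in tree.leaves()}
        fs, _ = fitch_map(tree, states)
        ds, _ = dollo_map(tree, states)
        assert ds >= fs


def test_trnl_caa_pattern_two_independent_losses():
    """Presence everywhere except two non-sister clades maps as two
    losses under Dollo, matching the trnL-CAA distribution."""
    tree = Phylogeny.from_newick(
        "(Out,((Hym1,Hym2)hym,((Gle1,Gle2)gle,((Dip,Mat)dm,(Schiz,Core)sc)v5)gr)lepto);")
    states = {l: "1" for l in tree.leaves()}
    for l in ("Hym1", "Hym2", "Schiz", "Core"):
        states[l] = "0"
    steps, changes = dollo_map(tree, states, ancestral_present=True)
    assert steps == 2
    assert {c.branch[1] for c in changes} == {"hym", "sc"}


def test_compare_topologies_v5_style():
    a = Phylogeny.from_newick("((G,(DM,SC)x)paper,O);")
    b = Phylogeny.from_newick("(((G,DM)glei,SC)alt,O);")
    states = {"G": "0", "DM": "1", "SC": "1", "O": "0"}
    assert compare_topologies(states, a, b) == (1, 2)


def test_compare_topologies_leafset_mismatch():
    a = Phylogeny.from_newick("((A,B),C);")
    b = Phylogeny.from_newick("((A,B),D);")
    with pytest.raises(ValueError):
        compare_topologies({"A": "1", "B": "0", "C": "0"}, a, b)


def test_compare_topologies_constant_character():
    a = Phylogeny.from_newick("((A,B),C);")
    b = Phylogeny.from_newick("((A,C),B);")
    assert compare_topologies({t: "0" for t in "ABC"}, a, b) == (0, 0)
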