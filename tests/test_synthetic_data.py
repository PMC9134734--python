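"""Simulator: determinism, event application, ledger integrity."""

from collections import Counter

import pytest

from plastosynapo.parsimony_map import Phylogeny
from plastosynapo.plastome_io import GeneSymbol, extract_gene_order
from plastosynapo.ir_regions import find_inverted_repeat
from plastosynapo.synthetic_data import (
    EventSpec,
    LedgerError,
    ancestral_spec,
    build_ancestral_genome,
    evolve,
    figure2_events,
    figure2_scenario,
    figure2_tree_newick,
)


def test_ancestral_genome_is_quadripartite(ancestral_record):
    p = find_inverted_repeat(ancestral_record, 1000, 1.0)
    assert p is not None
    assert p.interval_length(p.lsc) >= p.interval_length(p.ssc)
    total = p.interval_length(p.lsc) + p.interval_length(p.ssc) + 2 * p.ir_length
    assert total == ancestral_record.length


def test_ancestral_build_deterministic():
    spec = ancestral_spec("scaled")
    a = build_ancestral_genome(spec, 5)
    b = build_ancestral_genome(spec, 5)
    assert a.sequence == b.sequence
    assert build_ancestral_genome(spec, 6).sequence != a.sequence


def test_full_preset_is_plastome_sized():
    rec = build_ancestral_genome(ancestral_spec("full"), 1)
    assert 120_000 <= rec.length <= 190_000


_TOY_TREE = "((A,B)ab,(C,D)cd)root;"


def test_no_events_means_identical_leaves():
    tree = Phylogeny.from_newick(_TOY_TREE)
    leaves, ledger = evolve(tree, events=[], sub_rate=0.0, seed=3)
    seqs = {r.sequence for r in leaves.values()}
    assert len(seqs) == 1
    assert ledger.events == []
    assert seqs.pop() == build_ancestral_genome(ancestral_spec("scaled"), 3).sequence


def test_gene_count_conserved_without_losses():
    tree = Phylogeny.from_newick(_TOY_TREE)
    events = [EventSpec("V1", "V", "ab", {"left": "psbM", "right": "ycf2"})]
    leaves, _ = evolve(tree, events=events, sub_rate=0.01, seed=4)
    counts = {t: len(r.features) for t, r in leaves.items()}
    assert len(set(counts.values())) == 1


def test_inversion_reverses_block_for_descendants_only():
    tree = Phylogeny.from_newick(_TOY_TREE)
    events = [EventSpec("V1", "V", "ab", {"left": "psbM", "right": "ycf2"})]
    leaves, ledger = evolve(tree, events=events, sub_rate=0.0, seed=5)
    anchor = GeneSymbol("ycf1")
    orders = {}
    for t, rec in leaves.items():
        p = find_inverted_repeat(rec, 1000, 1.0)
        orders[t] = [(str(s), g) for s, g in
                     extract_gene_order(rec, p, anchor).order]
    assert orders["A"] == orders["B"] != orders["C"] == orders["D"]
    assert ledger.events[0].detail["span_genes"][0] == "psbM"


def test_event_on_destroyed_target_raises_ledger_error():
    tree = Phylogeny.from_newick(_TOY_TREE)
    events = [
        EventSpec("G1", "G", "ab", {"gene": "psbM", "mode": "delete"}),
        EventSpec("V1", "V", "ab", {"left": "psbM", "right": "ycf2"}),
    ]
    with pytest.raises(LedgerError, match="V1"):
        evolve(tree, events=events, seed=1)


def test_unknown_branch_raises():
    tree = Phylogeny.from_newick(_TOY_TREE)
    with pytest.raises(LedgerError, match="nope"):
        evolve(tree, events=[EventSpec("V1", "V", "nope",
                                       {"left": "psbM", "right": "ycf2"})], seed=1)


def test_pseudogenization_drops_integrity_below_threshold():
    from plastosynapo.gene_content import assess_gene

    tree = Phylogeny.from_newick(_TOY_TREE)
    anc = build_ancestral_genome(ancestral_spec("scaled"), 8)
    ref_cds = anc.find(GeneSymbol("ycf12"))[0].extract(anc.sequence)
    events = [EventSpec("G4", "G", "ab", {"gene": "ycf12", "mode": "pseudogenize"})]
    leaves, _ = evolve(tree, events=events, sub_rate=0.0, seed=8)
    cand = leaves["A"].find(GeneSymbol("ycf12"))[0].extract(leaves["A"].sequence)
    st = assess_gene(cand, ref_cds)
    assert st.status == "lost"
    assert 0.45 <= st.integrity < 0.70


def test_anticodon_mutation_visible_in_exactly_the_right_leaves():
    from plastosynapo.gene_content import validate_trna

    tree = Phylogeny.from_newick(_TOY_TREE)
    events = [EventSpec("T5", "T", "ab", {"trna": "trnL-UAA", "mode": "anticodon",
                                          "new_anticodon": "CAA"})]
    leaves, _ = evolve(tree, events=events, sub_rate=0.0, seed=9)
    sym = GeneSymbol("trnL", "UAA")
    for t, rec in leaves.items():
        seq = rec.find(sym)[0].extract(rec.sequence)
        v = validate_trna(seq, sym)
        if t in ("A", "B"):
            assert v.verdict == "anticodon-change" and v.anticodon_observed == "CAA"
        else:
            assert v.verdict == "validated"


def test_rate_mode_draws_reproducible_events():
    tree = Phylogeny.from_newick(_TOY_TREE)
    rates = {"V": 0.8, "G": 0.5, "T": 0.5, "D": 0.8}
    l1, g1 = evolve(tree, events=None, rates=rates, sub_rate=0.0, seed=12)
    l2, g2 = evolve(tree, events=None, rates=rates, sub_rate=0.0, seed=12)
    assert {t: r.sequence for t, r in l1.items()} == {t: r.sequence for t, r in l2.items()}
    assert [e.label for e in g1.events] == [e.label for e in g2.events]


def test_figure2_ledger_class_sizes(figure2_run):
    _, leaves, ledger, _, _ = figure2_run
    labels = {c: {e.label for e in ledger.by_class(c)} for c in "VRGTD"}
    assert {c: len(v) for c, v in labels.items()} == {
        "V": 9, "R": 7, "G": 10, "T": 7, "D": 19}
    assert len(leaves) == 51


def test_figure2_replay_is_byte_identical():
    _, l1, _, _ = figure2_scenario(seed=2, sub_rate=0.01)
    _, l2, _, _ = figure2_scenario(seed=2, sub_rate=0.01)
    assert all(l1[t].sequence == l2[t].sequence for t in l1)


def test_figure2_tree_has_labeled_backbone():
    tree = Phylogeny.from_newick(figure2_tree_newick())
    for label in ("ferns", "leptosporangiates", "v5_clade", "schizo_core",
                  "core_lepto", "eupolypods"):
        assert tree.node(label) is not None


def test_figure2_event_targets_exist_in_roster():
    spec = ancestral_spec("scaled")
    names = {g.name for g in spec.roster}
    for ev in figure2_events():
        for key in ("gene", "trna", "left", "right"):
            if key in ev.params:
                base = str(ev.params[key]).split("::")[0].split("-")[0]
                assert base in names or base.startswith("trn")
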