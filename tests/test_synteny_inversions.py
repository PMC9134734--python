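"""Signed permutations, breakpoint distance and exact inversion search."""

import random

import pytest

from plastosynapo.plastome_io import GeneFeature, GeneSymbol, GenomeRecord, SignedGeneOrder
from plastosynapo.synteny_inversions import (
    SignedPermutation,
    apply_reversal,
    breakpoint_distance,
    estimate_inversion_size,
    infer_inversions,
    to_signed_permutation,
)


def _order(taxon, pairs, anchor="A"):
    return SignedGeneOrder(taxon, [(GeneSymbol(n), s) for n, s in pairs],
                           GeneSymbol(anchor))


def test_identity_permutation():
    ref = _order("r", [("A", "+"), ("B", "-"), ("C", "+")])
    smp = _order("s", [("A", "+"), ("B", "-"), ("C", "+")])
    perm = to_signed_permutation(smp, ref)
    assert perm.perm == [1, 2, 3]
    assert perm.is_identity
    assert not perm.dropped_sample and not perm.dropped_reference


def test_missing_gene_reported_and_dropped():
    ref = _order("r", [("A", "+"), ("B", "+"), ("X", "+"), ("C", "+")])
    smp = _order("s", [("A", "+"), ("B", "+"), ("C", "+")])
    perm = to_signed_permutation(smp, ref)
    assert perm.perm == [1, 2, 3]
    assert GeneSymbol("X") in perm.dropped_sample


def test_reversed_block_encoding():
    ref = _order("r", [("A", "+"), ("B", "+"), ("C", "+"), ("D", "+"), ("E", "+")])
    smp = _order("s", [("A", "+"), ("C", "-"), ("B", "-"), ("D", "+"), ("E", "+")])
    perm = to_signed_permutation(smp, ref)
    assert perm.perm == [1, -3, -2, 4, 5]


def test_no_shared_genes_raises():
    ref = _order("r", [("A", "+"), ("B", "+")])
    smp = _order("s", [("A", "+"), ("C", "+")])
    perm = to_signed_permutation(smp, ref)
    assert perm.perm == [1]  # anchor always shared
    with pytest.raises(ValueError):
        to_signed_permutation(_order("s", [("Z", "+")], anchor="Z"), ref)


@pytest.mark.parametrize("perm, expected", [
    ([1, 2, 3], 0),
    ([1, -3, -2, 4, 5], 2),
    ([-2, -1, 3], 2),
    ([3, 2, 1], 4),
])
def test_breakpoint_distance_enumerated_by_hand(perm, expected):
    assert breakpoint_distance(perm) == expected


def test_single_reversal_inferred_with_flanks():
    syms = [GeneSymbol(c) for c in "ABCDE"]
    perm = SignedPermutation("s", "r", [1, -3, -2, 4, 5], syms)
    events, status = infer_inversions(perm)
    assert status == "resolved"
    assert len(events) == 1
    assert {str(s) for s in events[0].span_genes} == {"B", "C"}


def test_identity_yields_no_events():
    syms = [GeneSymbol(c) for c in "ABC"]
    events, status = infer_inversions(SignedPermutation("s", "r", [1, 2, 3], syms))
    assert events == [] and status == "identity"


def test_ndhB_to_psbA_segment_reversal():
    """A sample with the whole ndhB..psbA block reversed against an
    Osmundaceae-like reference comes back as one event with those flanks."""
    names = ["ycf1", "psbA", "matK", "rps4", "petA", "ndhB", "rrn16"]
    ref = _order("r", [(n, "+") for n in names], anchor="ycf1")
    rev = [("ycf1", "+"), ("ndhB", "-"), ("petA", "-"), ("rps4", "-"),
           ("matK", "-"), ("psbA", "-"), ("rrn16", "+")]
    smp = _order("s", rev, anchor="ycf1")
    perm = to_signed_permutation(smp, ref)
    events, status = infer_inversions(perm)
    assert status == "resolved" and len(events) == 1
    flanks = {str(events[0].left_flank), str(events[0].right_flank)}
    assert flanks == {"psbA", "ndhB"}


def test_unresolved_when_over_event_cap():
    rng = random.Random(5)
    vals = list(range(1, 13))
    rng.shuffle(vals)
    p = [v * rng.choice([1, -1]) for v in vals]
    syms = [GeneSymbol(f"g{i}") for i in range(12)]
    events, status = infer_inversions(SignedPermutation("s", "r", p, syms),
                                      max_events=1)
    assert events == [] and status == "unresolved"


def test_event_count_within_breakpoint_bounds_and_sorts():
    rng = random.Random(99)
    for _ in range(40):
        n = rng.randint(2, 7)
        vals = list(range(1, n + 1))
        rng.shuffle(vals)
        p = [v * rng.choice([1, -1]) for v in vals]
        syms = [GeneSymbol(f"g{i}") for i in range(n)]
        events, status = infer_inversions(SignedPermutation("s", "r", p, syms),
                                          max_events=10)
        assert status in ("resolved", "identity")
        b = breakpoint_distance(p)
        assert (b + 1) // 2 <= len(events) <= b or b == 0


def test_minimality_against_exhaustive_bfs():
    """Search results equal the exhaustive BFS minimum on small cases."""
    from collections import deque

    def bfs(p):
        p = tuple(p)
        n = len(p)
        goal = tuple(range(1, n + 1))
        dist = {p: 0}
        q = deque([p])
        while q:
            s = q.popleft()
            if s == goal:
                return dist[s]
            for i in range(n):
                for j in range(i, n):
                    t = apply_reversal(s, i, j)
                    if t not in dist:
                        dist[t] = dist[s] + 1
                        q.append(t)
        return None

    rng = random.Random(4242)
    for _ in range(25):
        n = rng.randint(1, 6)
        vals = list(range(1, n + 1))
        rng.shuffle(vals)
        p = [v * rng.choice([1, -1]) for v in vals]
        syms = [GeneSymbol(f"g{i}") for i in range(n)]
        events, _ = infer_inversions(SignedPermutation("s", "r", p, syms),
                                     max_events=10)
        assert len(events) == bfs(p)


def test_estimate_inversion_size_by_construction():
    # a 4.5 kb segment between the two flanking tRNAs
    seq = "A" * 20000
    feats = [
        GeneFeature(GeneSymbol("trnT", "GGU"), "tRNA", [(1000, 1071, "+")]),
        GeneFeature(GeneSymbol("trnG", "GCC"), "tRNA", [(5429, 5500, "+")]),
    ]
    rec = GenomeRecord("sz", seq, feats)
    from plastosynapo.synteny_inversions import InversionEvent

    ev = InversionEvent(GeneSymbol("trnT", "GGU"), GeneSymbol("trnG", "GCC"),
                        [GeneSymbol("trnT", "GGU"), GeneSymbol("trnG", "GCC")])
    assert estimate_inversion_size(ev, rec) == 4501


def test_estimate_inversion_size_missing_flank_raises():
    rec = GenomeRecord("sz", "A" * 1000,
                       [GeneFeature(GeneSymbol("psbA"), "CDS", [(1, 300, "+")])])
    from plastosynapo.synteny_inversions import InversionEvent

    ev = InversionEvent(GeneSymbol("psbA"), GeneSymbol("ndhB"), [GeneSymbol("psbA")])
    with pytest.raises(ValueError, match="ndhB"):
        estimate_inversion_size(ev, rec)
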