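"""Codon-aware alignment and in-frame indel detection."""

import numpy as np
import pytest

from plastosynapo.codon_indels import (
    CodonAlignment,
    codon_align,
    detect_codon_indels,
    indels_to_characters,
)
from plastosynapo.plastome_io import GeneSymbol


def _cds(n_codons, seed=0):
    rng = np.random.default_rng(seed)
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA")]
    return "ATG" + "".join(rng.choice(sense, size=n_codons)) + "TAA"


def test_identical_cds_align_gapless():
    ref = _cds(80)
    aln = codon_align({"a": ref, "b": ref}, center="a")
    assert aln.rows[0] == aln.rows[1] == ref
    assert detect_codon_indels(aln) == []


def test_internal_deletion_appears_as_one_gap_run():
    ref = _cds(100, seed=1)
    mut = ref[:90] + ref[99:]  # 9 bp deletion
    aln = codon_align({"r": ref, "m": mut, "o": ref}, center="r")
    indels = detect_codon_indels(aln, reference="r")
    assert len(indels) == 1
    d = indels[0]
    assert d.length == -9 and d.ref_position == 91
    assert d.carriers == frozenset({"m"})
    # round trip: degapping reproduces the inputs
    assert aln.row("m").replace("-", "") == mut
    assert aln.row("r").replace("-", "") == ref


def test_insertion_gaps_the_other_rows():
    ref = _cds(100, seed=2)
    mut = ref[:60] + "AAATTT" + ref[60:]
    aln = codon_align({"r": ref, "m": mut, "o": ref}, center="r")
    indels = detect_codon_indels(aln, reference="r")
    assert len(indels) == 1
    assert indels[0].length == 6 and indels[0].carriers == frozenset({"m"})
    assert aln.row("r").count("-") == 6
    assert aln.row("m").count("-") == 0


def test_shared_deletion_merges_carriers():
    """A 15 bp deletion shared by a clade yields one indel listing all of
    its carriers (Table-2-style: matK 193-207, -15)."""
    ref = _cds(120, seed=3)
    mut = ref[:192] + ref[207:]
    cds = {"ref": ref, "o1": ref, "o2": ref, "o3": ref,
           "c1": mut, "c2": mut, "c3": mut}
    aln = codon_align(cds, center="ref")
    indels = detect_codon_indels(aln, reference="ref")
    assert len(indels) == 1
    d = indels[0]
    assert d.length == -15
    assert d.ref_position == 193
    assert d.carriers == frozenset({"c1", "c2", "c3"})


def test_majority_gap_polarity_flips_to_insertion():
    # when most rows lack the columns, the minority carries an insertion
    ref = _cds(120, seed=3)
    mut = ref[:192] + ref[207:]
    cds = {"ref": ref, "o1": ref, "c1": mut, "c2": mut, "c3": mut}
    indels = detect_codon_indels(codon_align(cds, center="ref"), reference="ref")
    assert len(indels) == 1
    assert indels[0].length == 15
    assert indels[0].carriers == frozenset({"ref", "o1"})


def test_stacked_indels_decompose_into_atoms():
    # clade deletion of 6 bp; one taxon deletes 9 bp more, adjacently
    ref = _cds(200, seed=4)
    d6 = ref[:300] + ref[306:]
    d15 = ref[:300] + ref[315:]
    cds = {"ref": ref, "o1": ref, "o2": ref, "o3": ref, "o4": ref,
           "a1": d6, "a2": d6, "b1": d15, "b2": d15}
    aln = codon_align(cds, center="ref")
    indels = detect_codon_indels(aln, reference="ref")
    got = {(d.ref_position, d.length): set(d.carriers) for d in indels}
    assert got[(301, -6)] == {"a1", "a2", "b1", "b2"}
    assert got[(307, -9)] == {"b1", "b2"}


def test_non_codon_gap_rejected():
    aln = CodonAlignment(GeneSymbol("g"), ["a", "b"],
                         ["ATGAAACCCTAA", "ATG----AATAA"], frame_valid=True)
    with pytest.raises(ValueError, match="frame"):
        detect_codon_indels(aln)


def test_translation_consistency_of_rows():
    ref = _cds(50, seed=5)
    mut = ref[:30] + ref[39:]
    aln = codon_align({"r": ref, "m": mut}, center="r")
    for row in aln.rows:
        assert len(row) % 3 == 0
        for k in range(0, len(row), 3):
            codon = row[k : k + 3]
            assert codon == "---" or "-" not in codon


def test_indels_to_characters_singleton_excluded():
    from plastosynapo.codon_indels import CodonIndel

    indels = [
        CodonIndel(GeneSymbol("rps4"), 70, 75, 6, frozenset({"a", "b", "c"})),
        CodonIndel(GeneSymbol("rps4"), 10, 12, -3, frozenset({"a"})),
        CodonIndel(GeneSymbol("matK"), 193, 207, -15, frozenset({"b", "c"})),
    ]
    matrix, auto = indels_to_characters(indels, ["a", "b", "c", "d"])
    assert len(matrix.characters) == 2
    assert len(auto) == 1 and auto[0].carriers == frozenset({"a"})
    col = matrix.column(matrix.characters[0][0])
    assert sorted(t for t, v in col.items() if v == "1") in (["a", "b", "c"], ["b", "c"])


def test_all_n_row_dropped():
    ref = _cds(30, seed=6)
    aln = codon_align({"r": ref, "n": "N" * len(ref)}, center="r")
    assert aln.taxa == ["r"]
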