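"""Gene-loss rule, tRNA cloverleaf validation, intron loss, singleton filter."""

import numpy as np
import pytest

from plastosynapo.gene_content import (
    GeneStatus,
    apply_singleton_filter,
    assess_gene,
    detect_intron_loss,
    validate_trna,
)
from plastosynapo.plastome_io import GeneFeature, GeneSymbol
from plastosynapo.synthetic_data import (
    _IR_ROSTER,
    _LSC_ROSTER,
    canonical_trna,
    scramble_trna,
)


def _cds(n_codons, seed=0):
    rng = np.random.default_rng(seed)
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
    return "ATG" + "".join(rng.choice(sense, size=n_codons)) + "TAA"


def test_identical_candidate_is_present_with_unit_metrics():
    ref = _cds(100)
    st = assess_gene(ref, ref)
    assert st.status == "present"
    assert st.integrity == 1.0 and st.similarity == 1.0


def test_internal_stop_is_a_note_not_a_loss():
    ref = _cds(100, seed=1)
    cand = ref[:150] + "TGA" + ref[153:]
    st = assess_gene(cand, ref)
    assert st.status == "present"
    assert "internal-stop" in st.notes


def test_half_length_truncation_is_lost():
    ref = _cds(120, seed=2)
    st = assess_gene(ref[: len(ref) // 2], ref)
    assert st.status == "lost"
    assert st.integrity < 0.70


def test_absent_candidate_is_lost_with_zero_integrity():
    st = assess_gene(None, _cds(50))
    assert st.status == "lost" and st.integrity == 0.0


def test_large_in_frame_internal_deletion_is_not_a_pseudogene():
    # a clean codon deletion of ~36% with intact flanks stays "present"
    ref = _cds(900, seed=3)
    cand = ref[:1500] + ref[1500 + 972 :]
    st = assess_gene(cand, ref)
    assert st.integrity < 0.70
    assert st.status == "present"
    assert "in-frame-indel" in st.notes


def test_frameshift_deletion_is_lost():
    ref = _cds(900, seed=4)
    cand = ref[:1500] + ref[1500 + 973 :]  # same deletion, frame broken
    st = assess_gene(cand, ref)
    assert st.status == "lost"


def test_truncation_monotonicity():
    ref = _cds(200, seed=5)
    last = 1.1
    for frac in (0.9, 0.7, 0.5, 0.3):
        st = assess_gene(ref[: int(len(ref) * frac)], ref)
        assert st.integrity <= last + 1e-9
        last = st.integrity


def test_bad_reference_length_rejected():
    with pytest.raises(ValueError):
        assess_gene("ATGTAA", "ATGA")


# ---------------------------------------------------------------------------
# tRNA validation

_TRNAS = [g for g in (_LSC_ROSTER + _IR_ROSTER) if g.kind == "tRNA"]


def test_roster_has_thirty_trnas():
    assert len(_TRNAS) == 30


@pytest.mark.parametrize("g", _TRNAS, ids=lambda g: f"{g.name}-{g.anticodon}")
def test_canonical_trnas_validate_and_scrambles_fail(g):
    seq, _ = canonical_trna(g.anticodon)
    v = validate_trna(seq, g.symbol)
    assert v.structure_pass
    assert v.anticodon_observed == g.anticodon
    assert v.verdict == "validated"
    vs = validate_trna(scramble_trna(seq), g.symbol)
    assert not vs.structure_pass
    assert vs.verdict == "hypothetical-loss"


def test_anticodon_change_detected():
    # locus annotated trnL-UAA but the sequence reads CAA (still leucine)
    seq, off = canonical_trna("CAA")
    v = validate_trna(seq, GeneSymbol("trnL", "UAA"))
    assert v.structure_pass and v.isotype_consistent
    assert v.anticodon_observed == "CAA"
    assert v.verdict == "anticodon-change"


def test_isotype_inconsistency_is_hypothetical_loss():
    seq, _ = canonical_trna("CAA")  # decodes Leu
    v = validate_trna(seq, GeneSymbol("trnH", "CAA"))
    assert v.verdict == "hypothetical-loss"


# ---------------------------------------------------------------------------
# Intron loss

def _feat(sym, parts):
    return GeneFeature(GeneSymbol(sym), "CDS", parts)


def test_intron_loss_detected_on_fused_exons():
    ref = _feat("rps12", [(100, 219, "+"), (400, 513, "+")])  # 120 + 114
    fused = _feat("rps12", [(100, 333, "+")])  # single 234 bp span
    statuses = detect_intron_loss(fused, ref)
    assert [s.status for s in statuses] == ["lost"]
    assert statuses[0].intron_index == 1


def test_identical_exon_structure_is_retained():
    ref = _feat("clpP", [(1, 69, "+"), (220, 513, "+"), (664, 891, "+")])
    statuses = detect_intron_loss(ref, ref)
    assert [s.status for s in statuses] == ["retained", "retained"]


def test_missing_gene_reports_gene_absent():
    ref = _feat("ndhA", [(1, 540, "+"), (721, 1260, "+")])
    statuses = detect_intron_loss(None, ref)
    assert [s.status for s in statuses] == ["gene-absent"]


# ---------------------------------------------------------------------------
# Singleton filter

def _loss(taxon, gene):
    return GeneStatus(taxon, GeneSymbol(gene), 0.2, 0.9, "lost")


def test_singleton_loss_demoted():
    calls = [_loss("t1", "rps16")] + [
        GeneStatus(t, GeneSymbol("rps16"), 1.0, 1.0, "present")
        for t in ("t2", "t3")
    ]
    out = apply_singleton_filter(calls)
    assert out[0].status == "ambiguous"


def test_shared_loss_retained():
    calls = [_loss("t1", "rps16"), _loss("t2", "rps16"),
             GeneStatus("t3", GeneSymbol("rps16"), 1.0, 1.0, "present")]
    out = apply_singleton_filter(calls)
    assert [c.status for c in out] == ["lost", "lost", "present"]


def test_no_losses_unchanged():
    calls = [GeneStatus("t1", GeneSymbol("psbA"), 1.0, 1.0, "present")]
    assert apply_singleton_filter(calls) == calls
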