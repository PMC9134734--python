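"""Gene-symbol normalization, GenBank round trips, canonical gene orders."""

import pytest
from Bio.Seq import Seq

from plastosynapo.plastome_io import (
    GeneFeature,
    GeneSymbol,
    GenomeRecord,
    extract_gene_order,
    normalize_gene_symbol,
    read_genbank,
    write_genbank,
)


@pytest.mark.parametrize(
    "raw, kind, anticodon, expected",
    [
        ("trnL", "tRNA", "CAA", "trnL-CAA"),
        (" psbA ", "CDS", None, "psbA"),
        ("trnL-UAA", "tRNA", None, "trnL-UAA"),
        ("trnK", "tRNA", "ttt", "trnK-UUU"),
        ("rrn16S", "rRNA", None, "rrn16"),
        ("PSBA", "CDS", None, "psbA"),
    ],
)
def test_normalize_gene_symbol(raw, kind, anticodon, expected):
    assert str(normalize_gene_symbol(raw, kind, anticodon)) == expected


def test_trna_without_anticodon_is_flagged_not_rejected():
    sym = normalize_gene_symbol("trnX", "tRNA", None)
    assert sym.part == "anticodon-unknown"


def test_rps12_parts_share_base_symbol():
    five = normalize_gene_symbol("rps12::5p", "CDS")
    three = normalize_gene_symbol("rps12::3p", "CDS")
    assert five != three
    assert five.base.name == three.base.name == "rps12"


def test_empty_name_rejected():
    with pytest.raises(ValueError):
        normalize_gene_symbol("   ", "CDS")


def _toy_record():
    seq = "ATG" + "A" * 60 + "TAA" + "C" * 30 + "ATG" + "G" * 27 + "TAA" + "T" * 20
    feats = [
        GeneFeature(GeneSymbol("psbA"), "CDS", [(1, 66, "+")]),
        GeneFeature(GeneSymbol("ndhB"), "CDS", [(97, 129, "-")]),
        GeneFeature(GeneSymbol("trnL", "CAA"), "tRNA", [(130, 149, "+")]),
    ]
    return GenomeRecord("toy1", seq, feats)


def test_genbank_round_trip(tmp_path):
    rec = _toy_record()
    path = tmp_path / "toy.gb"
    write_genbank(rec, path)
    back = read_genbank(path)
    assert back.sequence == rec.sequence
    assert [(str(f.symbol), f.kind, f.parts) for f in back.features] == [
        (str(f.symbol), f.kind, f.parts) for f in rec.features
    ]


def test_genbank_round_trip_ancestral(ancestral_record, tmp_path):
    path = tmp_path / "anc.gb"
    write_genbank(ancestral_record, path)
    back = read_genbank(path)
    assert back.sequence == ancestral_record.sequence
    assert len(back.features) == len(ancestral_record.features)


def test_origin_wrapping_cds_round_trip(tmp_path):
    # a CDS whose span crosses the origin of the circular record
    tail = "ATGAAACCCGGGTTTTGGCATAACCCTAA"  # 29 bp
    seq = "G" * 91 + tail  # length 120; feature wraps 100..120 + 1..21
    rec = GenomeRecord("wrap1", seq,
                       [GeneFeature(GeneSymbol("matK"), "CDS", [(100, 21, "+")])])
    extracted = rec.features[0].extract(rec.sequence)
    assert extracted == seq[99:] + seq[:21]
    assert len(extracted) % 3 == 0
    path = tmp_path / "wrap.gb"
    write_genbank(rec, path)
    back = read_genbank(path)
    assert back.features[0].parts == [(100, 21, "+")]


def test_malformed_genbank_raises(tmp_path):
    path = tmp_path / "bad.gb"
    path.write_text("this is not a genbank file\n")
    with pytest.raises(ValueError):
        read_genbank(path)


def test_extract_gene_order_linear_toy():
    rec = _toy_record()
    order = extract_gene_order(rec, anchor=GeneSymbol("psbA"))
    assert [(str(s), g) for s, g in order.order] == [
        ("psbA", "+"), ("ndhB", "-"), ("trnL-CAA", "+")]


def test_extract_gene_order_anchor_missing_lists_symbols():
    rec = _toy_record()
    with pytest.raises(ValueError, match="available symbols"):
        extract_gene_order(rec, anchor=GeneSymbol("rbcL"))


def test_gene_order_rotation_invariant():
    rec = _toy_record()
    base = extract_gene_order(rec, anchor=GeneSymbol("psbA"))
    for shift in (17, 60, 111):
        seq = rec.sequence[shift:] + rec.sequence[:shift]
        n = len(seq)
        feats = []
        for f in rec.features:
            parts = []
            for s, e, st in f.parts:
                ns = (s - 1 - shift) % n + 1
                ne = (e - 1 - shift) % n + 1
                parts.append((ns, ne, st))
            feats.append(GeneFeature(f.symbol, f.kind, parts))
        rotated = GenomeRecord("rot", seq, feats)
        order = extract_gene_order(rotated, anchor=GeneSymbol("psbA"))
        assert [(str(s), g) for s, g in order.order] == [
            (str(s), g) for s, g in base.order]


def test_gene_order_reflection_invariant():
    rec = _toy_record()
    base = extract_gene_order(rec, anchor=GeneSymbol("psbA"))
    n = rec.length
    rc_seq = str(Seq(rec.sequence).reverse_complement())
    feats = []
    for f in rec.features:
        parts = [(n - e + 1, n - s + 1, "+" if st == "-" else "-")
                 for s, e, st in f.parts]
        feats.append(GeneFeature(f.symbol, f.kind, parts))
    rc = GenomeRecord("rc", rc_seq, feats)
    order = extract_gene_order(rc, anchor=GeneSymbol("psbA"))
    assert [(str(s), g) for s, g in order.order] == [
        (str(s), g) for s, g in base.order]


def test_ir_collapse_keeps_each_duplicated_gene_once(ancestral_record):
    from plastosynapo.ir_regions import find_inverted_repeat

    part = find_inverted_repeat(ancestral_record, 1000, 1.0)
    order = extract_gene_order(ancestral_record, part, GeneSymbol("ycf1"))
    syms = [str(s) for s, _ in order.order]
    assert len(syms) == len(set(syms))
    assert "rrn16" in syms and "trnN-GUU" in syms
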