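"""GenBank parsing and translation-machinery counting."""

import random

import pytest

from ribotally import (
    SyntheticGenomeSpec,
    build_inventory,
    classify_trna,
    count_rrn_operons,
    generate_synthetic_genome,
    merge_replicons,
    parse_genbank_flatfile,
)
from ribotally.inventory import (
    _ONE_TO_THREE,
    FeatureAnnotation,
    GenBankParseError,
    InventoryWarning,
    extract_feature_sequences,
)


def _trna_feature(**quals):
    return FeatureAnnotation(
        kind="tRNA", replicon_id="X", location=((1, 76),), strand="+",
        qualifiers=quals,
    )


class TestParsing:
    def test_small_record_feature_counts(self, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        kinds = sorted(f.kind for f in asm.features)
        assert kinds == ["CDS", "CDS", "rRNA", "rRNA", "rRNA", "tRNA"]
        assert asm.species_label == "Testus exampli"
        assert asm.accessions == ["TEST01.1"]

    def test_complement_join_becomes_two_minus_segments(self, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        cds2 = asm.features_of_kind("CDS")[1]
        assert cds2.strand == "-"
        assert cds2.location == ((40, 60), (70, 90))

    def test_minus_strand_extraction_reverse_complements(self, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        seqs = dict(extract_feature_sequences(asm, "CDS"))
        # first CDS is plain forward sequence from ORIGIN
        assert seqs["CDS_1"] == "ATGGAAGAATGCTAA"
        assert len(seqs["CDS_2"]) == 42

    def test_non_genbank_input_raises(self):
        with pytest.raises(GenBankParseError):
            parse_genbank_flatfile(">fasta\nACGT\n")

    def test_ignored_feature_kinds_do_not_appear(self, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        assert all(f.kind in ("CDS", "rRNA", "tRNA") for f in asm.features)


class TestRrnCounting:
    def test_operon_count_follows_16s(self, code11):
        text, _ = generate_synthetic_genome(SyntheticGenomeSpec(n_rrn=7, seed=1))
        n_rrn, classes = count_rrn_operons(parse_genbank_flatfile(text))
        assert n_rrn == 7
        assert classes == {"16S": 7, "23S": 7, "5S": 7}

    def test_class_mismatch_warns(self):
        def rrna(product):
            return FeatureAnnotation(
                kind="rRNA", replicon_id="X", location=((1, 100),),
                strand="+", qualifiers={"product": product},
            )

        from ribotally.inventory import GenomeAssembly

        asm = GenomeAssembly(
            species_label="t", accessions=["X"], replicons={},
            features=[rrna("16S ribosomal RNA"), rrna("23S ribosomal RNA"),
                      rrna("23S ribosomal RNA")],
        )
        with pytest.warns(InventoryWarning, match="unequal"):
            n_rrn, classes = count_rrn_operons(asm)
        assert n_rrn == 1
        assert classes["23S"] == 2

    def test_unrecognised_product_warns_and_is_uncounted(self):
        from ribotally.inventory import GenomeAssembly

        asm = GenomeAssembly(
            species_label="t", accessions=["X"], replicons={},
            features=[FeatureAnnotation(
                kind="rRNA", replicon_id="X", location=((1, 100),),
                strand="+", qualifiers={"product": "mystery RNA"})],
        )
        with pytest.warns(InventoryWarning):
            n_rrn, classes = count_rrn_operons(asm)
        assert n_rrn == 0 and sum(classes.values()) == 0


class TestTrnaClassification:
    @pytest.mark.parametrize(
        "product, expected",
        [("tRNA-Leu", "L"), ("tRNA-Trp", "W"), ("tRNA-fMet", "fMet"),
         ("tRNA-Sec", "SeC"), ("tRNA-Ala", "A")],
    )
    def test_product_string(self, code11, product, expected):
        assert classify_trna(_trna_feature(product=product), code11) == expected

    def test_anticodon_decoding_all_64(self, code11):
        """Brute-force oracle: reverse-complement each anticodon by hand and
        read the resulting codon off the code table."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    anticodon = b1 + b2 + b3
                    codon = comp[b3] + comp[b2] + comp[b1]
                    aa = code11.codon_to_aa[codon]
                    expected = aa if aa != "*" else None
                    feat = _trna_feature(
                        anticodon=f"(pos:1..3,aa:Xxx,seq:{anticodon.lower()})"
                    )
                    assert classify_trna(feat, code11) == expected, anticodon

    def test_cat_anticodon_is_met(self, code11):
        feat = _trna_feature(anticodon="(pos:1..3,aa:Met,seq:cat)")
        assert classify_trna(feat, code11) == "M"

    def test_no_product_no_anticodon_is_unclassified(self, code11):
        assert classify_trna(_trna_feature(), code11) is None

    def test_non_trna_feature_rejected(self, code11):
        cds = FeatureAnnotation(
            kind="CDS", replicon_id="X", location=((1, 9),), strand="+",
        )
        with pytest.raises(ValueError):
            classify_trna(cds, code11)


class TestInventory:
    def test_counts_match_spec(self, code11):
        spec = SyntheticGenomeSpec(
            n_rrn=3, m_trna={"A": 4, "G": 12}, n_initiator_met=6, seed=5
        )
        text, _ = generate_synthetic_genome(spec)
        inv = build_inventory(parse_genbank_flatfile(text), code11)
        assert inv.m_trna == {"A": 4, "G": 12, "M": 6}
        assert inv.n_trna == 22
        assert inv.n_initiator_met == 6
        assert inv.n_rrn == 3

    def test_initiator_met_counts_inside_met(self, code11):
        spec = SyntheticGenomeSpec(
            m_trna={"M": 2}, n_initiator_met=4, seed=2
        )
        text, _ = generate_synthetic_genome(spec)
        inv = build_inventory(parse_genbank_flatfile(text), code11)
        assert inv.m_trna["M"] == 6
        assert inv.n_initiator_met == 4

    def test_pseudo_trnas_excluded_by_default(self, code11):
        spec = SyntheticGenomeSpec(m_trna={"L": 3}, n_pseudo_trna=2, seed=3)
        text, _ = generate_synthetic_genome(spec)
        asm = parse_genbank_flatfile(text)
        assert build_inventory(asm, code11).n_trna == 3
        assert build_inventory(asm, code11, exclude_pseudo=False).n_trna == 5

    def test_no_trnas_gives_empty_map(self, code11):
        text, _ = generate_synthetic_genome(SyntheticGenomeSpec(n_rrn=1, seed=4))
        inv = build_inventory(parse_genbank_flatfile(text), code11)
        assert inv.n_trna == 0 and inv.m_trna == {}

    def test_classification_identity(self, code11):
        """n_trna always equals sum(m_trna) + Sec + unclassified."""
        spec = SyntheticGenomeSpec(
            n_rrn=2, m_trna={aa: 2 for aa in "ACDEFGHIKLMNPQRSTVWY"}, seed=6
        )
        text, _ = generate_synthetic_genome(spec)
        inv = build_inventory(parse_genbank_flatfile(text), code11)
        assert inv.n_trna == sum(inv.m_trna.values()) + inv.n_sec + inv.n_unclassified

    def test_feature_order_invariance(self, code11, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        inv1 = build_inventory(asm, code11)
        rng = random.Random(0)
        shuffled = list(asm.features)
        rng.shuffle(shuffled)
        asm.features = shuffled
        inv2 = build_inventory(asm, code11)
        assert (inv1.n_rrn, inv1.n_trna, inv1.m_trna) == (
            inv2.n_rrn, inv2.n_trna, inv2.m_trna
        )


class TestMerge:
    def test_additivity(self, code11):
        spec_a = SyntheticGenomeSpec(n_rrn=2, m_trna={"L": 5}, seed=10)
        spec_b = SyntheticGenomeSpec(n_rrn=1, m_trna={"L": 2, "W": 4}, seed=11)
        a, _ = generate_synthetic_genome(spec_a)
        b, _ = generate_synthetic_genome(spec_b)
        asm_a = parse_genbank_flatfile(a)
        asm_b = parse_genbank_flatfile(b)
        # rename so replicon ids do not collide
        asm_b.replicons = {"SYNB1": asm_b.replicons.pop("SYN01.1")}
        asm_b.features = [
            FeatureAnnotation(f.kind, "SYNB1", f.location, f.strand, f.qualifiers)
            for f in asm_b.features
        ]
        asm_b.accessions = ["SYNB1"]
        merged = merge_replicons([asm_a, asm_b])
        inv = build_inventory(merged, code11)
        inv_a = build_inventory(asm_a, code11)
        inv_b = build_inventory(asm_b, code11)
        assert inv.n_rrn == inv_a.n_rrn + inv_b.n_rrn == 3
        assert inv.n_trna == inv_a.n_trna + inv_b.n_trna == 11
        assert inv.m_trna == {"L": 7, "W": 4}

    def test_merge_single_is_identity(self, code11, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        merged = merge_replicons([asm])
        assert build_inventory(merged, code11) == build_inventory(asm, code11)

    def test_duplicate_replicon_rejected(self, small_gbff_text):
        asm = parse_genbank_flatfile(small_gbff_text)
        with pytest.raises(ValueError, match="duplicate"):
            merge_replicons([asm, asm])

    def test_empty_merge_rejected(self):
        with pytest.raises(ValueError):
            merge_replicons([])


@pytest.mark.parametrize("seed", range(6))
def test_roundtrip_matches_manifest(code11, seed):
    """parse -> inventory reproduces the generator's manifest exactly."""
    rng = random.Random(seed)
    aas = rng.sample(sorted(_ONE_TO_THREE), rng.randint(1, 12))
    spec = SyntheticGenomeSpec(
        n_rrn=rng.randint(0, 8),
        m_trna={aa: rng.randint(1, 9) for aa in aas},
        n_initiator_met=rng.randint(0, 4),
        replicon_count=rng.randint(1, 3),
        seed=seed,
    )
    text, manifest = generate_synthetic_genome(spec)
    inv = build_inventory(parse_genbank_flatfile(text), code11)
    assert inv.n_rrn == manifest["n_rrn"]
    assert inv.rrna_class_counts == manifest["rrna_class_counts"]
    assert inv.n_trna == manifest["n_trna"]
    assert inv.m_trna == manifest["m_trna"]
    assert inv.n_unclassified == 0
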