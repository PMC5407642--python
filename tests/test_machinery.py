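import pytest

from plantmir.core import DomainAnnotation, ProteinRecord
from plantmir.machinery import (
    SYNTHETIC_AGO_REFERENCE,
    SYNTHETIC_RNASE3_REFERENCE,
    classify_ago,
    classify_architecture,
    classify_dcl,
    classify_rdr,
    infer_family,
    map_reference_positions,
)
from plantmir.synth import generate_protein_set


class TestMapReferencePositions:
    def test_identity_alignment(self):
        ref = SYNTHETIC_AGO_REFERENCE
        assert map_reference_positions(ref, ref, (760, 845, 986, 798)) == [
            760,
            845,
            986,
            798,
        ]

    def test_deletion_shifts_anchors(self):
        ref = SYNTHETIC_AGO_REFERENCE
        query = ProteinRecord("q", ref.seq[:700] + ref.seq[705:])
        assert map_reference_positions(query, ref, (760, 845, 986)) == [
            755,
            840,
            981,
        ]

    def test_missing_region_maps_to_gap(self):
        ref = SYNTHETIC_AGO_REFERENCE
        query = ProteinRecord("q", ref.seq[:500])
        mapped = map_reference_positions(query, ref, (760, 845, 986))
        assert mapped == [None, None, None]


class TestClassifyAgo:
    def test_reference_is_canonical(self):
        r = classify_ago(SYNTHETIC_AGO_REFERENCE)
        assert r.motif == "DDH/H"
        assert r.positions == [760, 845, 986, 798]
        assert r.evaluable

    @pytest.mark.parametrize(
        "substitutions,expected",
        [
            ({}, "DDH/H"),
            ({986: "D"}, "DDD/H"),  # the AGO2-type third aspartate
            ({798: "S"}, "DDH/S"),
            ({798: "P"}, "DDH/P"),
            ({798: "Q"}, "DDH/Q"),
            ({760: "E", 845: "N", 986: "R", 798: "R"}, "ENR/R"),
        ],
    )
    def test_motif_vocabulary(self, substitutions, expected):
        """The catalytic-triad variants observed across plant AGO paralogs."""
        seq = list(SYNTHETIC_AGO_REFERENCE.seq)
        for pos, aa in substitutions.items():
            seq[pos - 1] = aa
        assert classify_ago(ProteinRecord("q", "".join(seq))).motif == expected

    def test_invariant_to_terminal_extension(self):
        extended = ProteinRecord(
            "q", SYNTHETIC_AGO_REFERENCE.seq + "MKWLYPQRSTNVEA" * 4
        )
        r = classify_ago(extended)
        assert r.motif == "DDH/H"
        assert r.positions == [760, 845, 986, 798]

    def test_truncated_protein_not_evaluable(self):
        r = classify_ago(ProteinRecord("q", SYNTHETIC_AGO_REFERENCE.seq[:400]))
        assert not r.evaluable
        assert "?" in r.motif


def _dcl_fixture(mutations=()):
    rn = SYNTHETIC_RNASE3_REFERENCE.seq
    seq = "M" * 50 + rn + "G" * 20 + rn
    doms = [
        DomainAnnotation("d", "RIBOc", 51, 50 + len(rn)),
        DomainAnnotation("d", "RIBOc", 71 + len(rn), 70 + 2 * len(rn)),
    ]
    chars = list(seq)
    for pos, aa in mutations:
        chars[pos] = aa
    return ProteinRecord("d", "".join(chars)), doms


class TestClassifyDcl:
    def test_canonical_both_domains(self):
        prot, doms = _dcl_fixture()
        r = classify_dcl(prot, doms)
        assert r.motif == "EDDE/EDDE"
        assert r.evaluable and not r.partial

    def test_single_domain_is_partial(self):
        prot, doms = _dcl_fixture()
        r = classify_dcl(prot, doms[:1])
        assert r.motif == "EDDE"
        assert r.partial

    def test_point_mutant_read_from_alignment(self):
        # anchor 1 of domain 1 sits at protein offset 50 + 40 - 1
        prot, doms = _dcl_fixture(mutations=[(50 + 39, "Q")])
        assert classify_dcl(prot, doms).motif == "QDDE/EDDE"

    def test_no_riboc_annotation(self):
        prot, _ = _dcl_fixture()
        r = classify_dcl(prot, [])
        assert not r.evaluable


class TestClassifyRdr:
    def test_alpha_clade_csgs(self):
        p = ProteinRecord("r", "M" * 30 + "CSGS" + "AEKV" * 2 + "DLDGD" + "W" * 10)
        r = classify_rdr(p)
        assert r.clade == "alpha"
        assert r.motif == "DLDGD+CSGS"

    def test_alpha_clade_asgs(self):
        p = ProteinRecord("r", "M" * 30 + "ASGS" + "AEKV" * 2 + "DLDGD" + "W" * 10)
        assert classify_rdr(p).motif == "DLDGD+ASGS"

    def test_gamma_clade(self):
        p = ProteinRecord("r", "M" * 30 + "DFDGD" + "W" * 10)
        r = classify_rdr(p)
        assert r.clade == "gamma"
        assert r.motif == "DFDGD"

    def test_non_motif_not_evaluable(self):
        assert not classify_rdr(ProteinRecord("r", "MDMDGDAAA")).evaluable

    def test_agrees_with_substring_scan(self):
        seqs = [
            "M" * 10 + "DLDGD" + "K" * 5,
            "M" * 10 + "DFDGD" + "K" * 5 + "DLDGD",
            "CSGSAAAA" + "DLDGD",
        ]
        for s in seqs:
            r = classify_rdr(ProteinRecord("r", s))
            idx = min(s.find("DLDGD") % 10**9, s.find("DFDGD") % 10**9)
            assert r.positions == [idx + 1]

    def test_rdrp_domain_takes_precedence(self):
        s = "DLDGD" + "A" * 50 + "DFDGD" + "A" * 20
        doms = [DomainAnnotation("r", "RdRP", 40, 80)]
        r = classify_rdr(ProteinRecord("r", s), doms)
        assert r.clade == "gamma"  # the in-domain match wins over leftmost


class TestArchitecture:
    def test_complete_dcl(self):
        # layout following the full DCL domain complement
        doms = [
            DomainAnnotation("p", "DExD", 114, 266),
            DomainAnnotation("p", "Helicase-C", 503, 619),
            DomainAnnotation("p", "DUF283", 693, 784),
            DomainAnnotation("p", "PAZ", 1029, 1164),
            DomainAnnotation("p", "RIBOc", 1201, 1387),
            DomainAnnotation("p", "RIBOc", 1423, 1579),
            DomainAnnotation("p", "DSRM", 1582, 1643),
            DomainAnnotation("p", "DSRM", 1674, 1742),
        ]
        r = classify_architecture("p", doms, "DCL")
        assert r.complete and r.missing == {} and r.order_ok

    def test_truncated_dcl_missing_set(self):
        doms = [
            DomainAnnotation("p", "RIBOc", 321, 465),
            DomainAnnotation("p", "RIBOc", 506, 660),
            DomainAnnotation("p", "DSRM", 664, 723),
        ]
        r = classify_architecture("p", doms, "DCL")
        assert r.missing == {
            "DExD": 1,
            "Helicase-C": 1,
            "DUF283": 1,
            "PAZ": 1,
            "DSRM": 1,
        }
        assert not r.complete

    def test_ago_without_argomid_complete(self):
        doms = [
            DomainAnnotation("p", "ArgoN", 253, 393),
            DomainAnnotation("p", "PAZ", 458, 581),
            DomainAnnotation("p", "Piwi", 758, 1052),
        ]
        r = classify_architecture("p", doms, "AGO")
        assert r.complete
        assert "ArgoMid" in r.missing  # reported, but optional

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            classify_architecture("p", [], "XRN")


class TestSyntheticProteinTruth:
    def test_expected_reports_match_classifiers(self):
        """The generator's expected reports equal classifier output."""
        res = generate_protein_set(
            seed=3,
            families={"AGO": 3, "DCL": 2, "RDR": 3},
            corruptions={
                "synAGO2": ["H798->S"],
                "synAGO3": ["D760->E", "D845->N", "H986->R", "H798->R"],
                "synDCL2": ["RIBOc1:E1->Q"],
                "synRDR2": ["DLDGD->DFDGD"],
                "synRDR3": ["CSGS->ASGS"],
            },
        )
        by_id = {p.protein_id: p for p in res.proteins}
        for exp in res.expected:
            prot = by_id[exp.protein_id]
            if exp.family == "AGO":
                got = classify_ago(prot)
            elif exp.family == "DCL":
                got = classify_dcl(prot, res.domains)
            else:
                got = classify_rdr(prot, res.domains)
            assert got.motif == exp.motif, exp.protein_id
            if exp.family == "RDR":
                assert got.clade == exp.clade

    def test_unknown_corruption_rule(self):
        with pytest.raises(ValueError):
            generate_protein_set(seed=1, corruptions={"synAGO1": ["Z9->Q"]})


def test_infer_family_precedence():
    doms = [DomainAnnotation("x", "RIBOc", 1, 50)]
    assert infer_family("x", doms) == "DCL"
    assert infer_family("CcAGO5", []) == "AGO"
    assert infer_family("mystery", [], seq="AA" + "DLDGD") == "RDR"
    assert infer_family("mystery", [], seq="AAAA") is None
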