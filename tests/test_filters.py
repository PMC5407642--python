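import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantmir.core import (
    BaseComposition,
    GenomicInterval,
    MatureArmPlacement,
    PrecursorRecord,
    ReferenceMature,
    ThermoProfile,
)
from plantmir.filters import (
    REASON_CODES,
    FilterThresholds,
    apply_cascade,
    assign_family,
    name_precursors,
    resolve_overlaps,
)


def make_candidate(
    *,
    cid="c1",
    length=120,
    gc=45.0,
    mfe=-50.0,
    mfei=1.0,
    mature=True,
    mismatches=0,
    chrom="chr1",
    start=1000,
    strand="+",
):
    au = 100.0 - gc
    return PrecursorRecord(
        candidate_id=cid,
        seq="A" * length,
        interval=GenomicInterval(chrom, start, start + length, strand),
        thermo=ThermoProfile(mfe=mfe, amfe=mfe / length * 100, mfei=mfei),
        composition=BaseComposition(a=au / 2, u=au / 2, c=gc / 2, g=gc / 2),
        mature=MatureArmPlacement("5p", 5, 26, "U") if mature else None,
        mature_mismatches=mismatches if mature else None,
    )


class TestCascadeBoundaries:
    def test_gc_just_below_window(self):
        d = apply_cascade(make_candidate(gc=19.9))
        assert not d.accepted and d.reasons == ["GC_RANGE"]

    def test_gc_and_mfei_inclusive_boundaries(self):
        d = apply_cascade(make_candidate(gc=20.0, mfei=0.70))
        assert d.accepted and d.reasons == []
        d = apply_cascade(make_candidate(gc=65.0, mfei=0.70))
        assert d.accepted

    def test_just_outside_boundaries(self):
        assert apply_cascade(make_candidate(gc=65.1)).reasons == ["GC_RANGE"]
        assert apply_cascade(make_candidate(mfei=0.699)).reasons == ["MFEI_MIN"]

    def test_length_window_inclusive(self):
        assert apply_cascade(make_candidate(length=60)).accepted
        assert apply_cascade(make_candidate(length=338)).accepted
        assert apply_cascade(make_candidate(length=59)).reasons == ["LENGTH"]
        assert apply_cascade(make_candidate(length=339)).reasons == ["LENGTH"]

    def test_mfe_must_be_negative(self):
        assert apply_cascade(make_candidate(mfe=0.0)).reasons == ["MFE_SIGN"]

    def test_blocklist_single_nt_overlap(self):
        block = [GenomicInterval("chr1", 1119, 1500)]  # candidate is [1000,1120)
        d = apply_cascade(make_candidate(), blocklist=block)
        assert d.reasons == ["BLOCKLIST"]
        block_miss = [GenomicInterval("chr1", 1120, 1500)]
        assert apply_cascade(make_candidate(), blocklist=block_miss).accepted

    def test_all_failures_reported_in_order(self):
        d = apply_cascade(
            make_candidate(length=30, gc=10.0, mfe=1.0, mfei=0.1, mature=False),
            blocklist=[GenomicInterval("chr1", 0, 5000)],
        )
        assert d.reasons == [
            "LENGTH",
            "GC_RANGE",
            "MFE_SIGN",
            "MFEI_MIN",
            "MATURE_PLACEMENT",
            "MATURE_HOMOLOGY",
            "BLOCKLIST",
        ]
        assert set(d.reasons) <= set(REASON_CODES)

    def test_missing_descriptor_is_an_error(self):
        cand = make_candidate()
        cand.thermo = None
        with pytest.raises(ValueError, match="thermo"):
            apply_cascade(cand)

    def test_mature_homology_budget(self):
        assert apply_cascade(make_candidate(mismatches=3)).accepted
        assert apply_cascade(make_candidate(mismatches=4)).reasons == [
            "MATURE_HOMOLOGY"
        ]


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(40, 400),  # length
            st.floats(5.0, 95.0),  # GC
            st.floats(-120.0, 5.0),  # MFE
            st.floats(0.0, 3.0),  # MFEI
            st.booleans(),  # mature ok
        ),
        min_size=1,
        max_size=25,
    ),
    st.floats(0.0, 30.0),
)
def test_cascade_monotone_in_thresholds(cands, slack):
    """Relaxing any threshold never shrinks the accepted set."""
    tight = FilterThresholds()
    loose = FilterThresholds(
        gc_min=tight.gc_min - slack,
        gc_max=tight.gc_max + slack,
        mfei_min=max(0.0, tight.mfei_min - slack / 30),
        length_min=max(1, tight.length_min - int(slack)),
        length_max=tight.length_max + int(slack),
        max_mature_mismatches=tight.max_mature_mismatches + 1,
    )
    records = [
        make_candidate(cid=f"c{i}", length=l, gc=g, mfe=m, mfei=x, mature=ok)
        for i, (l, g, m, x, ok) in enumerate(cands)
    ]
    accepted_tight = {
        r.candidate_id for r in records if apply_cascade(r, tight).accepted
    }
    accepted_loose = {
        r.candidate_id for r in records if apply_cascade(r, loose).accepted
    }
    assert accepted_tight <= accepted_loose


def test_every_rejection_has_a_reason():
    for cand in (
        make_candidate(gc=10),
        make_candidate(length=10),
        make_candidate(mature=False),
    ):
        d = apply_cascade(cand)
        assert not d.accepted
        assert len(d.reasons) >= 1


class TestResolveOverlaps:
    def test_lowest_mfe_wins(self):
        a = make_candidate(cid="a", mfe=-50.0, start=1000)
        b = make_candidate(cid="b", mfe=-45.0, start=1050)
        kept = resolve_overlaps([a, b])
        assert [r.candidate_id for r in kept] == ["a"]
        assert kept[0].provenance["superseded"] == ["b"]

    def test_tie_breaks_longest(self):
        a = make_candidate(cid="a", mfe=-50.0, length=120, start=1000)
        b = make_candidate(cid="b", mfe=-50.0, length=90, start=1010)
        assert [r.candidate_id for r in resolve_overlaps([a, b])] == ["a"]

    def test_non_overlapping_both_kept(self):
        a = make_candidate(cid="a", start=1000)
        b = make_candidate(cid="b", start=5000)
        assert len(resolve_overlaps([a, b])) == 2

    def test_different_strands_not_merged(self):
        a = make_candidate(cid="a", start=1000, strand="+")
        b = make_candidate(cid="b", start=1050, strand="-")
        assert len(resolve_overlaps([a, b])) == 2


class TestAssignFamily:
    REFS = [
        ReferenceMature("ath-miR156a", "TGACAGAAGAGAGTGAGCACA"),
        ReferenceMature("ath-miR171a", "TGATTGAGCCGCGCCAATATC"),
        ReferenceMature("ath-miR170a", "TGATTGAGCCGTGTCAATATC"),
    ]

    def test_exact_match(self):
        assert assign_family("TGACAGAAGAGAGTGAGCACA", self.REFS, 3) == "MIR156"

    def test_nearest_reference_wins(self):
        # 2 mismatches to miR171, 3 to miR170
        mature = "TGATTGAGCCGCGACAATATG"
        from plantmir.filters import mismatch_count

        assert mismatch_count(mature, self.REFS[1].seq) == 2
        assert mismatch_count(mature, self.REFS[2].seq) == 3
        assert assign_family(mature, self.REFS, 3) == "MIR171"

    def test_tie_breaks_lexicographic(self):
        # equidistant from MIR170 and MIR171
        mature = "TGATTGAGCCGCGTCAATATC"
        from plantmir.filters import mismatch_count

        d1 = mismatch_count(mature, self.REFS[1].seq)
        d2 = mismatch_count(mature, self.REFS[2].seq)
        assert d1 == d2
        assert assign_family(mature, self.REFS, 3) == "MIR170"

    def test_out_of_budget_returns_none(self):
        assert assign_family("A" * 21, self.REFS, 3) is None

    def test_empty_references_error(self):
        with pytest.raises(ValueError):
            assign_family("A" * 21, [], 3)


def test_naming_by_genomic_order():
    a = make_candidate(cid="a", chrom="chr2", start=100)
    b = make_candidate(cid="b", chrom="chr1", start=900)
    c = make_candidate(cid="c", chrom="chr1", start=100)
    for r in (a, b, c):
        r.family = "MIR156"
    name_precursors([a, b, c])
    assert (c.name, b.name, a.name) == (
        "ccp-MIR156a",
        "ccp-MIR156b",
        "ccp-MIR156c",
    )
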