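"""Kovats-index computation, compound matching and peak identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromaprofiler.errors import (
    LadderError,
    LadderRangeError,
    MissingInternalStandardError,
)
from aromaprofiler.kovats import (
    AlkaneLadder,
    compute_ki,
    identify_peaks,
    ki_deviation_report,
    match_compound,
    rt_for_ki,
)
from aromaprofiler.library import (
    Peak,
    PeakTable,
    SampleMeta,
    Variety,
    WineType,
)


def brute_force_ki(anchors, rt):
    """Independent oracle: find the bracketing alkane pair, interpolate."""
    for (c1, t1), (c2, t2) in zip(anchors, anchors[1:]):
        if t1 <= rt <= t2:
            return 100 * c1 + 100 * (c2 - c1) * (rt - t1) / (t2 - t1)
    raise AssertionError("rt outside ladder")


@st.composite
def ladders(draw):
    start = draw(st.integers(min_value=5, max_value=12))
    length = draw(st.integers(min_value=2, max_value=15))
    gaps = draw(
        st.lists(st.floats(min_value=0.3, max_value=8.0), min_size=length,
                 max_size=length)
    )
    rt0 = draw(st.floats(min_value=0.5, max_value=5.0))
    rts = np.cumsum([rt0] + gaps)
    carbons = range(start, start + length + 1)
    return AlkaneLadder(anchors=tuple(zip(carbons, map(float, rts))))


class TestComputeKI:
    def test_exact_at_anchors(self, ladder):
        for carbon, rt in ladder.anchors:
            assert compute_ki(ladder, rt) == pytest.approx(100 * carbon)

    def test_midpoint_interpolation(self, ladder):
        anchors = dict(ladder.anchors)
        mid = 0.5 * (anchors[12] + anchors[13])
        assert compute_ki(ladder, mid) == pytest.approx(1250)

    def test_out_of_span_raises_with_span_in_message(self, ladder):
        lo, hi = ladder.span
        with pytest.raises(LadderRangeError, match=str(lo)):
            compute_ki(ladder, lo - 1.0)

    def test_extrapolation_opt_in(self, ladder):
        lo, _ = ladder.span
        ki = compute_ki(ladder, lo - 0.1, extrapolate=True)
        assert ki < 800

    @settings(max_examples=200, derandomize=True)
    @given(ladders(), st.floats(min_value=0.0, max_value=1.0))
    def test_matches_brute_force_oracle(self, lad, frac):
        lo, hi = lad.span
        rt = lo + frac * (hi - lo)
        assert compute_ki(lad, rt) == pytest.approx(
            brute_force_ki(lad.anchors, rt), abs=1e-9
        )

    @settings(max_examples=100, derandomize=True)
    @given(ladders(), st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_strictly_monotone(self, lad, f1, f2):
        lo, hi = lad.span
        rt1, rt2 = sorted((lo + f1 * (hi - lo), lo + f2 * (hi - lo)))
        if rt1 < rt2:
            assert compute_ki(lad, rt1) < compute_ki(lad, rt2)

    @settings(max_examples=100, derandomize=True)
    @given(ladders(), st.floats(min_value=0.0, max_value=1.0))
    def test_rt_for_ki_inverts(self, lad, frac):
        kis = 100.0 * lad.carbons
        ki = kis[0] + frac * (kis[-1] - kis[0])
        assert compute_ki(lad, rt_for_ki(lad, ki)) == pytest.approx(ki, abs=1e-6)

    def test_bad_ladders_rejected(self):
        with pytest.raises(LadderError):
            AlkaneLadder(anchors=((8, 2.0), (9, 1.5)))
        with pytest.raises(LadderError):
            AlkaneLadder(anchors=((8, 1.0), (10, 2.0)))  # gap
        AlkaneLadder(anchors=((8, 1.0), (10, 2.0)), allow_gaps=True)


class TestDefaultLadder:
    def test_library_kis_invert_within_run(self, ladder, library):
        lo, hi = ladder.span
        for rec in library:
            rt = rt_for_ki(ladder, rec.ki_calc_published)
            assert lo < rt < hi
            assert compute_ki(ladder, rt) == pytest.approx(
                rec.ki_calc_published, abs=1e-9
            )

    def test_linalool_round_trip_is_exact(self, ladder, by_id):
        rt = rt_for_ki(ladder, by_id["linalool"].ki_calc_published)
        assert compute_ki(ladder, rt) == pytest.approx(1537, abs=0.5)

    def test_synthetic_rts_preserve_elution_order(self, ladder, library):
        # the inverse mapping cannot reproduce every published rt (the
        # published KI-rt relation is not piecewise linear between alkanes)
        # but it must preserve the published elution order exactly
        ordered = sorted(library, key=lambda r: r.ki_calc_published)
        rts = [rt_for_ki(ladder, r.ki_calc_published) for r in ordered]
        assert rts == sorted(rts)
        assert all(b > a for a, b in zip(rts, rts[1:]))


class TestMatchCompound:
    def test_linalool_self_match_ranked_first(self, library):
        hits = match_compound(1537, library)
        assert hits[0][0].compound_id == "linalool"
        assert hits[0][1] == 0.0

    def test_far_ki_matches_nothing(self, library):
        assert match_compound(5000, library) == []

    def test_full_self_match_within_defaults(self, library):
        """Every record with a literature KI retrieves itself at the
        default tolerances when probed with its own calculated KI."""
        for rec in library:
            if rec.ki_lit is None:
                continue
            hits = match_compound(rec.ki_calc_published, library)
            assert rec.compound_id in {h[0].compound_id for h in hits}

    def test_sorted_by_delta_then_id(self, library):
        hits = match_compound(1520, library)
        deltas = [d for _, d in hits]
        assert deltas == sorted(deltas)
        for (r1, d1), (r2, d2) in zip(hits, hits[1:]):
            if d1 == d2:
                assert r1.compound_id < r2.compound_id


def _meta():
    return SampleMeta("toy", Variety.SERCIAL, 5, WineType.DRY, 57.0, 18.0)


def _table(peaks, is_area=1e6):
    is_peak = Peak(rt_min=4.0, area=is_area)
    return PeakTable(meta=_meta(), peaks=peaks, is_peak=is_peak)


class TestIdentifyPeaks:
    def test_resemblance_below_threshold_rejected_despite_perfect_ki(
        self, ladder, library
    ):
        rt = rt_for_ki(ladder, 1537.0)
        table = _table([Peak(rt, 1e5, candidate="linalool", resemblance_pct=79.0)])
        (result,) = identify_peaks(table, ladder, library)
        assert not result.accepted
        assert "resemblance" in result.rejection_reason

    def test_resemblance_at_threshold_accepted(self, ladder, library):
        rt = rt_for_ki(ladder, 1537.0)
        table = _table([Peak(rt, 1e5, candidate="linalool", resemblance_pct=80.0)])
        (result,) = identify_peaks(table, ladder, library)
        assert result.accepted
        assert result.compound_id == "linalool"
        assert {"MS", "RI", "Std"} == set(result.evidence_tier)

    def test_ki_disagreement_rejects_candidate(self, ladder, library):
        rt = rt_for_ki(ladder, 1800.0)  # linalool lit KI is 1537
        table = _table([Peak(rt, 1e5, candidate="linalool", resemblance_pct=95.0)])
        (result,) = identify_peaks(table, ladder, library)
        assert not result.accepted

    def test_ri_only_identification_is_lower_tier(self, ladder, library):
        rt = rt_for_ki(ladder, 1537.0)
        table = _table([Peak(rt, 1e5)])  # no spectral candidate
        (result,) = identify_peaks(table, ladder, library)
        assert result.accepted
        assert result.compound_id == "linalool"
        assert result.evidence_tier == frozenset({"RI"})

    def test_one_peak_per_compound_best_delta_then_area(self, ladder, library):
        """Exhaustive 3-peak toy: the compound goes to the smallest |dKI|,
        area breaking the tie."""
        rts = [rt_for_ki(ladder, k) for k in (1537.0, 1539.0, 1539.0)]
        table = _table([
            Peak(rts[0], 1e4, candidate="linalool", resemblance_pct=90.0),
            Peak(rts[1], 5e5, candidate="linalool", resemblance_pct=90.0),
            Peak(rts[2], 9e5, candidate="linalool", resemblance_pct=90.0),
        ])
        results = identify_peaks(table, ladder, library)
        accepted = [r for r in results if r.accepted]
        assert len(accepted) == 1
        assert accepted[0].delta_ki == pytest.approx(0.0)
        # equal-delta pair: larger area wins
        table2 = _table([
            Peak(rts[1], 5e5, candidate="linalool", resemblance_pct=90.0),
            Peak(rts[2], 9e5, candidate="linalool", resemblance_pct=90.0),
        ])
        accepted2 = [r for r in identify_peaks(table2, ladder, library) if r.accepted]
        assert len(accepted2) == 1
        assert accepted2[0].area == 9e5

    def test_missing_internal_standard_is_hard_error(self, ladder, library):
        table = _table([Peak(10.0, 1e5)], is_area=0.0)
        with pytest.raises(MissingInternalStandardError):
            identify_peaks(table, ladder, library)

    def test_deterministic_ordering(self, ladder, library, noiseless_study):
        tables, _, lad = noiseless_study
        first = identify_peaks(tables[0], lad, library)
        second = identify_peaks(tables[0], lad, library)
        assert first == second


class TestDeviationReport:
    def test_bounds(self, library):
        report = ki_deviation_report(library)
        assert report["min_abs"] == 0
        assert report["max_abs"] <= 35
        assert report["max_rel_pct"] <= 5
        assert report["n"] == 81  # one compound lacks a literature KI

    def test_sorted_descending(self, library):
        rows = ki_deviation_report(library)["per_compound"]
        deltas = [r["delta"] for r in rows]
        assert deltas == sorted(deltas, reverse=True)

    def test_empty_library(self):
        report = ki_deviation_report([])
        assert report["n"] == 0 and report["max_abs"] is None
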