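"""LSV stratification, binary reduction, event geometry, pA-read counting."""

import numpy as np
import pytest

from psmorph import splice
from psmorph import synthetic as syn
from psmorph.splice import Junction, LSVRecord


def lsv(dpsis, prob=0.9, juncs=None, kinds=None, lsv_id="l", orient="source"):
    n = len(dpsis)
    if juncs is None:
        juncs = [(100 + 50 * i, 500 + 50 * i) for i in range(n)]
    if kinds is None:
        kinds = ["junction"] * n
    return LSVRecord("g", lsv_id, orient,
                     [Junction(s, e, k) for (s, e), k in zip(juncs, kinds)],
                     list(dpsis), prob)


class TestClassifyRegulated:
    @pytest.mark.parametrize("dpsis,prob,expected", [
        ((10.0, -10.0), 0.9, "regulated"),
        ((1.0, -1.0), 0.0, "non_regulated"),
        ((10.0, -10.0), 0.3, "ambiguous"),       # strong dPSI, weak prob
        ((3.0, -3.0), 0.9, "ambiguous"),         # the 2-5% gap
        ((1.0, -1.0), 0.2, "ambiguous"),         # small dPSI, nonzero prob
        ((5.0, -5.0), 0.9, "ambiguous"),         # boundary: >5 is strict
        ((-6.0, 6.0), 0.51, "regulated"),        # sign-free threshold
    ])
    def test_rule(self, dpsis, prob, expected):
        assert splice.classify_regulated(lsv(dpsis, prob)) == expected


def binarize_oracle(dpsis):
    """Independent rule application via explicit sorting."""
    order = list(np.argsort([-abs(d) for d in dpsis], kind="stable"))
    d1, d2 = dpsis[order[0]], dpsis[order[1]]
    if abs(d2) < 0.5 * abs(d1) or d1 * d2 > 0:
        return None
    return order[0], order[1]


class TestBinarize:
    @pytest.mark.parametrize("dpsis,retained,mains", [
        ((10.0, -8.0, -2.0), True, (10.0, -8.0)),
        ((10.0, -4.0, -3.0, -3.0), False, None),
        ((10.0, -10.0), True, (10.0, -10.0)),
        ((10.0, 8.0, -3.0), False, None),        # same-sign second junction
    ])
    def test_examples(self, dpsis, retained, mains):
        out = splice.binarize_lsv(lsv(dpsis))
        if retained:
            assert out is not None
            assert (out.main_dpsi, out.second_dpsi) == mains
        else:
            assert out is None

    def test_single_junction_rejected(self):
        with pytest.raises(ValueError):
            splice.binarize_lsv(lsv([10.0]))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 6))
            dpsis = list(np.round(rng.uniform(-20, 20, n), 3))
            got = splice.binarize_lsv(lsv(dpsis))
            want = binarize_oracle(dpsis)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.main_dpsi == dpsis[want[0]]
                assert got.second_dpsi == dpsis[want[1]]


def event_pair(kind, dpsi=12.0, prob=0.9, base=10_000):
    rows = syn.make_event_lsvs(kind, "g", "e", base, dpsi, prob)
    return tuple(splice.lsv_from_row(r) for r in rows)


class TestClassifyEvent:
    @pytest.mark.parametrize("kind", list(syn.EVENT_KINDS))
    def test_constructed_events_recovered(self, kind):
        src, tgt = event_pair(kind)
        assert splice.classify_event(src, tgt).event_type == kind

    def test_cassette_reports_middle_exon(self):
        src, tgt = event_pair("cassette", base=50_000)
        call = splice.classify_event(src, tgt)
        assert call.middle_exon == (50_500, 50_600)

    def test_unregulated_input_rejected(self):
        src, tgt = event_pair("cassette", dpsi=1.0, prob=0.0)
        with pytest.raises(ValueError):
            splice.classify_event(src, tgt)

    def test_twelve_event_fixture(self):
        """Hand-constructed mixture: every call matches its construction."""
        fixture = [("cassette", 10_000), ("alt_3ss", 20_000),
                   ("alt_5ss", 30_000), ("intron_retention", 40_000)] * 3
        calls = []
        for i, (kind, base) in enumerate(fixture):
            src, tgt = event_pair(kind, dpsi=8.0 + i, base=base + i * 2000)
            calls.append(splice.classify_event(src, tgt).event_type)
        assert calls == [k for k, _ in fixture]


class TestSubclassifyCassette:
    def exons_with_middle(self, call, where):
        lo, hi = call.middle_exon
        internal = [(lo - 5000, lo - 4800), (lo, hi), (hi + 4800, hi + 5000)]
        if where == "internal":
            return internal
        if where == "first":
            return [(lo, hi), (hi + 4800, hi + 5000), (hi + 9000, hi + 9200)]
        return [(lo - 9200, lo - 9000), (lo - 5000, lo - 4800), (lo, hi)]

    @pytest.mark.parametrize("where,expected", [
        ("internal", "simple"), ("first", "alt_first_exon"),
        ("last", "alt_last_exon")])
    def test_terminal_exon_calls(self, where, expected):
        src, tgt = event_pair("cassette")
        call = splice.classify_event(src, tgt)
        assert splice.subclassify_cassette(
            call, self.exons_with_middle(call, where)) == expected

    def test_multiple_patterns_are_complex(self):
        # two alternative middle exons supported by extra junctions
        d1, a3 = 200, 1500
        src = lsv([10.0, -10.0, 4.0],
                  juncs=[(d1, 500), (d1, a3), (d1, 800)], lsv_id="s")
        tgt = lsv([10.0, -10.0, 4.0],
                  juncs=[(600, a3), (d1, a3), (900, a3)],
                  lsv_id="t", orient="target")
        call = splice.classify_event(src, tgt)
        assert call.event_type == "cassette"
        assert len(call.junction_pairs) > 1
        assert splice.subclassify_cassette(call) == "complex"

    def test_missing_model_falls_back_to_simple(self):
        src, tgt = event_pair("cassette")
        call = splice.classify_event(src, tgt)
        assert splice.subclassify_cassette(call, None) == "simple"

    def test_non_cassette_rejected(self):
        src, tgt = event_pair("alt_3ss")
        call = splice.classify_event(src, tgt)
        with pytest.raises(ValueError):
            splice.subclassify_cassette(call)


REGION = ("chr11", 65_422_000, 65_424_000)


class TestCountPAReads:
    def test_constructed_mixture(self):
        _, recs = syn.simulate_reads(REGION, 5, 7, tail_len=8, seed=4)
        res = splice.count_pa_reads(recs, REGION)
        assert res.n_pa_reads == 5
        assert res.n_total_reads == 12

    def test_counts_invariant_under_shuffling(self, rng):
        _, recs = syn.simulate_reads(REGION, 6, 9, tail_len=10, seed=5)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert splice.count_pa_reads(shuffled, REGION).n_pa_reads == 6

    def test_reverse_strand_t_clip_counted(self):
        header, _ = syn.simulate_reads(REGION, 0, 0, seed=0)
        import pysam
        a = pysam.AlignedSegment(header)
        a.query_name = "rev"
        a.query_sequence = "T" * 8 + "ACGTACGTACGT"
        a.cigarstring = "8S12M"
        a.reference_id = 0
        a.reference_start = REGION[1] + 100
        a.is_reverse = True
        a.mapping_quality = 60
        assert splice.count_pa_reads([a], REGION).n_pa_reads == 1

    def test_templated_a_run_is_not_evidence(self):
        # aligned (template-encoded) A-run without soft clip must not count
        header, _ = syn.simulate_reads(REGION, 0, 0, seed=0)
        import pysam
        a = pysam.AlignedSegment(header)
        a.query_name = "decoy"
        a.query_sequence = "ACGT" + "A" * 16
        a.cigarstring = "20M"
        a.reference_id = 0
        a.reference_start = REGION[1] + 100
        a.mapping_quality = 60
        res = splice.count_pa_reads([a], REGION)
        assert res.n_total_reads == 1 and res.n_pa_reads == 0

    def test_short_or_impure_tails_rejected(self):
        header, _ = syn.simulate_reads(REGION, 0, 0, seed=0)
        import pysam

        def read(seq, cigar):
            a = pysam.AlignedSegment(header)
            a.query_name = "x"
            a.query_sequence = seq
            a.cigarstring = cigar
            a.reference_id = 0
            a.reference_start = REGION[1] + 10
            a.mapping_quality = 60
            return a

        short = read("ACGTACGTACGT" + "AAAA", "12M4S")        # tail < 6
        impure = read("ACGTACGTACGT" + "ACGTACGT", "12M8S")   # A-frac < 0.8
        res = splice.count_pa_reads([short, impure], REGION)
        assert res.n_pa_reads == 0 and res.n_total_reads == 2

    def test_log2_fold_change(self):
        _, recs = syn.simulate_reads(REGION, 8, 0, tail_len=8, seed=6)
        res = splice.count_pa_reads(recs, REGION, reference_count=8)
        assert res.log2_fold_change == pytest.approx(0.0)
        res2 = splice.count_pa_reads(recs, REGION, reference_count=17)
        assert res2.log2_fold_change == pytest.approx(-1.0)

    def test_three_prime_end_outside_region_not_counted(self):
        _, recs = syn.simulate_reads(REGION, 3, 0, tail_len=8, seed=7)
        shifted = ("chr11", REGION[2] + 10_000, REGION[2] + 12_000)
        res = splice.count_pa_reads(recs, shifted)
        assert res.n_total_reads == 0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            splice.count_pa_reads([], ("chr1", 100, 100))
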