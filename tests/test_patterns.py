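"""Site discovery, pattern assembly, epiallele counting, conversion QC."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from amplimeth import (
    MethCall,
    QCReport,
    SiteIndex,
    assemble_patterns,
    build_site_index,
    compute_qc,
    count_patterns,
)
from conftest import (
    brute_force_count,
    calls_for_patterns,
    make_amplicon,
    make_read_patterns,
)


def cpg(read_id, pos, meth, chrom="chr1"):
    return MethCall(read_id, chrom, pos, "CpG", meth)


class TestSiteIndex:
    def test_dedupe_and_sort(self, amplicon):
        calls = [cpg("r1", 110, True), cpg("r2", 110, False),
                 cpg("r1", 150, True), cpg("r3", 130, True)]
        assert build_site_index(calls, amplicon).sites == (110, 130, 150)

    def test_positions_outside_trimmed_interval_excluded(self):
        a = make_amplicon(start=90, end=200, fwd=10, rev=40)  # trimmed [100,160)
        calls = [cpg("r1", 95, True), cpg("r1", 110, True), cpg("r1", 160, True)]
        assert build_site_index(calls, a).sites == (110,)

    def test_other_chrom_and_noncpg_ignored(self, amplicon):
        calls = [cpg("r1", 110, True, chrom="chr9"),
                 MethCall("r1", "chr1", 120, "CHH", False)]
        assert build_site_index(calls, amplicon).sites == ()

    def test_no_cpg_control_yields_empty_sites(self, amplicon):
        chh_only = [MethCall(f"r{i}", "chr1", 110 + i, "CHH", False)
                    for i in range(20)]
        assert build_site_index(chh_only, amplicon).sites == ()


class TestAssemble:
    def test_full_coverage_encoding(self, site_index):
        calls = [cpg("r1", 110, True), cpg("r1", 130, False), cpg("r1", 150, True)]
        (p,) = assemble_patterns(calls, site_index)
        assert p.pattern == "101"

    def test_partial_coverage_uses_missing_char(self, site_index):
        (p,) = assemble_patterns([cpg("r1", 130, True)], site_index)
        assert p.pattern == "-1-"
        assert p.coverage_fraction == pytest.approx(1 / 3)

    def test_five_read_fixture_gives_three_distinct_patterns(self, site_index):
        strings = ["111", "111", "000", "000", "1--"]
        patterns = assemble_patterns(
            calls_for_patterns(strings, [110, 130, 150]), site_index
        )
        assert sorted(p.pattern for p in patterns) == sorted(strings)
        assert len({p.pattern for p in patterns}) == 3

    def test_duplicate_call_first_seen_wins_and_conflict_counted(self, site_index):
        qc = QCReport("s")
        calls = [cpg("r1", 110, True), cpg("r1", 110, False),  # disagreement
                 cpg("r1", 130, True), cpg("r1", 130, True)]   # agreement
        (p,) = assemble_patterns(calls, site_index, conflict_counter=qc)
        assert p.pattern == "11-"
        assert qc.call_conflicts == 1

    def test_reads_without_on_site_calls_excluded(self, site_index):
        calls = [cpg("r1", 110, True), cpg("r2", 145, True)]  # 145 not a site
        patterns = assemble_patterns(calls, site_index)
        assert [p.read_id for p in patterns] == ["r1"]


class TestCount:
    def test_direct_count_and_site_fractions(self, site_index):
        idx = SiteIndex(site_index.amplicon, (110, 130))
        s = count_patterns(make_read_patterns(["11", "11", "10"]), idx,
                           min_coverage_fraction=0.0)
        assert [(r.pattern, r.count) for r in s.rows] == [("11", 2), ("10", 1)]
        assert [r.fraction for r in s.rows] == [pytest.approx(2 / 3), pytest.approx(1 / 3)]
        assert s.site_meth_fraction == (1.0, 2 / 3)
        assert s.total_reads == 3 and s.dropped_reads == 0

    def test_coverage_filter_drops_partial_reads(self, site_index):
        idx = SiteIndex(site_index.amplicon, (110, 130))
        s = count_patterns(make_read_patterns(["1-", "11"]), idx,
                           min_coverage_fraction=1.0)
        assert [(r.pattern, r.count) for r in s.rows] == [("11", 1)]
        assert s.dropped_reads == 1

    def test_tie_break_is_lexicographic(self, site_index):
        idx = SiteIndex(site_index.amplicon, (110, 130))
        s = count_patterns(make_read_patterns(["10", "01", "11", "00"]), idx)
        assert [r.pattern for r in s.rows] == ["00", "01", "10", "11"]

    def test_empty_input_is_not_an_error(self, site_index):
        s = count_patterns([], site_index)
        assert s.total_reads == 0 and s.rows == ()
        assert s.site_meth_fraction == (None, None, None)

    def test_fully_methylated_sample_single_row(self, site_index):
        s = count_patterns(make_read_patterns(["111"] * 40), site_index)
        assert len(s.rows) == 1 and s.rows[0].count == 40
        assert all(f == 1.0 for f in s.site_meth_fraction)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed, site_index):
        rng = random.Random(seed)
        n_sites = rng.randint(1, 8)
        idx = SiteIndex(site_index.amplicon, tuple(110 + 3 * i for i in range(n_sites)))
        strings = []
        for _ in range(rng.randint(1, 50)):
            while True:
                s = "".join(rng.choice("01-") for _ in range(n_sites))
                if s.count("-") < n_sites:
                    break
            strings.append(s)
        threshold = rng.choice([0.0, rng.random(), 1.0])
        got = count_patterns(make_read_patterns(strings), idx,
                             min_coverage_fraction=threshold)
        rows, dropped, fractions = brute_force_count(strings, threshold)
        assert [(r.pattern, r.count) for r in got.rows] == rows
        assert got.dropped_reads == dropped
        assert list(got.site_meth_fraction) == fractions

    @given(
        strings=st.lists(
            st.text(alphabet="01-", min_size=3, max_size=3), min_size=1,
            max_size=40).filter(lambda xs: all(x.count("-") < 3 for x in xs)),
        rnd=st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, strings, rnd):
        idx = SiteIndex(make_amplicon(), (110, 130, 150))
        shuffled = list(strings)
        rnd.shuffle(shuffled)
        a = count_patterns(make_read_patterns(strings), idx,
                           min_coverage_fraction=0.5)
        b = count_patterns(make_read_patterns(shuffled), idx,
                           min_coverage_fraction=0.5)
        assert a == b

    @given(
        strings=st.lists(
            st.text(alphabet="01-", min_size=4, max_size=4), min_size=0,
            max_size=60).filter(lambda xs: all(x.count("-") < 4 for x in xs)),
        threshold=st.floats(0.0, 1.0),
    )
    def test_conservation(self, strings, threshold):
        idx = SiteIndex(make_amplicon(), (110, 120, 130, 140))
        s = count_patterns(make_read_patterns(strings), idx,
                           min_coverage_fraction=threshold)
        assert sum(r.count for r in s.rows) == s.total_reads
        assert s.total_reads + s.dropped_reads == len(strings)
        if s.rows:
            assert sum(r.fraction for r in s.rows) == pytest.approx(1.0, abs=1e-9)


class TestQC:
    def test_conversion_ratio(self):
        calls = [MethCall(f"r{i}", "chr1", i, "CHH", False) for i in range(98)]
        calls += [MethCall(f"m{i}", "chr1", i, "CHH", True) for i in range(2)]
        qc = compute_qc(calls)
        assert qc.conversion_rate == pytest.approx(0.98)

    def test_fully_converted_sample(self):
        calls = [MethCall("r", "chr1", i, ctx, False)
                 for i, ctx in enumerate(["CHH", "CHG"] * 10)]
        assert compute_qc(calls).conversion_rate == 1.0

    def test_no_noncpg_calls_flagged_undefined(self):
        calls = [MethCall("r", "chr1", 5, "CpG", True)]
        qc = compute_qc(calls)
        assert qc.conversion_rate is None and not qc.conversion_defined

    def test_context_breakdown(self):
        calls = [MethCall("r", "chr1", 1, "CHG", True),
                 MethCall("r", "chr1", 2, "CHG", False),
                 MethCall("r", "chr1", 3, "CHH", False),
                 MethCall("r", "chr1", 4, "CpG", True),
                 MethCall("r", "chr1", 5, "unknown", True)]  # excluded
        qc = compute_qc(calls)
        assert qc.context_counts["CHG"] == {"methylated": 1, "unmethylated": 1}
        assert qc.context_counts["CHH"] == {"methylated": 0, "unmethylated": 1}
        assert qc.conversion_rate == pytest.approx(2 / 3)
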