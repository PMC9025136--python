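"""Two-point phase inference, rate MLEs and the rate-equality LR test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import xlogy

from xopop import corate, tagselect
from xopop.corate import COUPLING, REPULSION, TwoPointCounts
from xopop.genotypes import AA_X_AB, AB_X_AA, HET, HOM, MISSING, GenotypeDataset

counts4 = st.tuples(*[st.integers(min_value=0, max_value=300)] * 4).filter(
    lambda c: sum(c) > 0
)


def _grid_mle(counts: TwoPointCounts, step=1e-4):
    """Independent oracle: maximize the coupling likelihood on a grid."""
    rs = np.arange(0.0, 0.5 + step, step)
    ll = xlogy(counts.parental, (1 - rs) / 2) + xlogy(counts.recombinant, rs / 2)
    return rs[np.argmax(ll)]


class TestPhase:
    def test_recombinant_minority_is_coupling(self):
        phased = corate.infer_phase(TwoPointCounts(48, 2, 3, 47))
        assert phased.phase == COUPLING
        assert phased.counts == TwoPointCounts(48, 2, 3, 47)

    def test_repulsion_relabelled_to_canonical(self):
        phased = corate.infer_phase(TwoPointCounts(2, 48, 47, 3))
        assert phased.phase == REPULSION
        assert phased.counts == TwoPointCounts(48, 2, 3, 47)

    def test_tie_breaks_to_coupling_and_flags_unlinked(self):
        phased = corate.infer_phase(TwoPointCounts(25, 25, 25, 25))
        assert phased.phase == COUPLING
        assert phased.unlinked
        assert corate.estimate_rate(phased.counts) == 0.5

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            corate.infer_phase(TwoPointCounts(0, 0, 0, 0))


class TestRateMLE:
    @pytest.mark.parametrize(
        "counts, expected",
        [((48, 2, 3, 47), 0.05), ((50, 0, 0, 50), 0.0), ((40, 10, 10, 40), 0.2)],
    )
    def test_closed_form_examples(self, counts, expected):
        assert corate.estimate_rate(TwoPointCounts(*counts)) == pytest.approx(expected)

    @settings(max_examples=150, deadline=None)
    @given(counts4)
    def test_closed_form_matches_grid_maximization(self, raw):
        phased = corate.infer_phase(TwoPointCounts(*raw))
        r_hat = corate.estimate_rate(phased.counts)
        assert abs(r_hat - _grid_mle(phased.counts)) <= 1e-4
        assert 0.0 <= r_hat <= 0.5


class TestEqualRatesLR:
    def test_identical_tables_give_zero(self):
        c = TwoPointCounts(48, 2, 3, 47)
        lr, p = corate.lr_equal_rates(c, c)
        assert lr == 0.0
        assert p == 1.0

    def test_frozen_example(self):
        # oracle: numeric maximization of the full and pooled likelihoods
        lr, p = corate.lr_equal_rates(TwoPointCounts(90, 5, 5, 100), TwoPointCounts(80, 20, 20, 80))
        assert lr == pytest.approx(21.849062, abs=1e-4)
        assert p == pytest.approx(2.9496e-06, rel=1e-3)

    def test_boundary_zero_recombinants(self):
        c = TwoPointCounts(50, 0, 0, 50)
        lr, p = corate.lr_equal_rates(c, c)
        assert lr == 0.0

    @settings(max_examples=100, deadline=None)
    @given(counts4, counts4)
    def test_nonnegative_and_zero_iff_equal_rates(self, a, b):
        ca = corate.infer_phase(TwoPointCounts(*a)).counts
        cb = corate.infer_phase(TwoPointCounts(*b)).counts
        lr, p = corate.lr_equal_rates(ca, cb)
        assert lr >= 0.0
        if corate.estimate_rate(ca) == corate.estimate_rate(cb):
            assert lr == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(counts4, counts4, st.integers(min_value=2, max_value=7))
    def test_lr_scales_linearly_with_counts(self, a, b, k):
        ca = corate.infer_phase(TwoPointCounts(*a)).counts
        cb = corate.infer_phase(TwoPointCounts(*b)).counts
        lr1, _ = corate.lr_equal_rates(ca, cb)
        lrk, _ = corate.lr_equal_rates(
            TwoPointCounts(*(k * x for x in ca.as_tuple())),
            TwoPointCounts(*(k * x for x in cb.as_tuple())),
        )
        assert lrk == pytest.approx(k * lr1, rel=1e-9, abs=1e-9)


def _two_tag_dataset(calls_by_marker, n_progeny):
    markers = pd.DataFrame(
        {
            "chrom": ["c1"] * 4,
            "pos": [100_000, 100_400, 300_000, 300_400],
            "seg_type": [AB_X_AA, AA_X_AB, AB_X_AA, AA_X_AB],
        }
    )
    ds = GenotypeDataset(markers, np.array(calls_by_marker, dtype=np.int8),
                         [f"p{i}" for i in range(n_progeny)])
    tags = tagselect.select_spaced_tags(tagselect.pair_snps_into_tags(ds))
    return ds, tagselect.build_intervals(tags)


class TestScan:
    def test_pairwise_missing_handling_and_counts(self):
        n = 6
        f1 = [HET, HET, HOM, HOM, MISSING, HET]
        f2 = [HET, HET, HOM, HOM, HET, MISSING]
        m1 = [HET, HOM, HET, HOM, HET, HOM]
        m2 = [HET, HOM, HET, HOM, HET, HOM]
        ds, intervals = _two_tag_dataset([f1, m1, f2, m2], n)
        res = corate.scan_intervals(ds, intervals)
        assert len(res) == 1
        row = res.iloc[0]
        assert row.n_f == 4  # two progeny dropped pairwise
        assert row.n_m == 6
        assert row.low_n  # below the default informative threshold
        assert row.tested

    def test_all_missing_pair_flagged_untested(self):
        n = 4
        f1 = [HET, HET, HOM, HOM]
        f2 = [HET, HET, HOM, HOM]
        m1 = [MISSING] * n
        m2 = [HET, HOM, HET, HOM]
        ds, intervals = _two_tag_dataset([f1, m1, f2, m2], n)
        res = corate.scan_intervals(ds, intervals)
        assert not res.iloc[0].tested
        assert np.isnan(res.iloc[0].p)

    def test_recovers_interval_rates_on_simulation(self, small_population):
        ds, truth = small_population
        tags = tagselect.select_spaced_tags(tagselect.pair_snps_into_tags(ds))
        res = corate.scan_intervals(ds, tagselect.build_intervals(tags))
        assert res["tested"].all()
        truth_f = truth.interval_rates.query("parent == 'female'")["rate"].mean()
        assert res["r_f"].mean() == pytest.approx(truth_f, abs=0.01)


def _brute_force_regions(pvalues, alpha):
    """Oracle: scan runs of consecutive significant entries by enumeration."""
    sig = [p < alpha for p in pvalues]
    runs, i = [], 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    regions = [(a, b) for a, b in runs if b > a]
    singles = [(a, b) for a, b in runs if b == a]
    return regions, singles


def _results_frame(pvalues):
    k = len(pvalues)
    return pd.DataFrame(
        {
            "chrom": ["c1"] * k,
            "left_pos": np.arange(k) * 100.0,
            "right_pos": np.arange(1, k + 1) * 100.0,
            "p": pvalues,
            "tested": True,
        }
    )


class TestRegions:
    def test_run_grouping_example(self):
        regions, singles = corate.find_significant_regions(
            _results_frame([0.04, 0.03, 0.20, 0.01]), alpha=0.05
        )
        assert len(regions) == 1 and regions.iloc[0].n_intervals == 2
        assert len(singles) == 1 and singles.iloc[0].start == 300.0

    def test_no_significance_no_regions(self):
        regions, singles = corate.find_significant_regions(
            _results_frame([0.5, 0.9, 0.06]), alpha=0.05
        )
        assert regions.empty and singles.empty

    def test_three_consecutive_form_one_region(self):
        regions, _ = corate.find_significant_regions(
            _results_frame([0.01, 0.01, 0.01]), alpha=0.05
        )
        assert len(regions) == 1
        assert regions.iloc[0].n_intervals == 3

    def test_gap_in_positions_breaks_region(self):
        frame = _results_frame([0.01, 0.01])
        frame.loc[1, "left_pos"] = 150.0  # no shared boundary tag
        regions, singles = corate.find_significant_regions(frame, alpha=0.05)
        assert regions.empty and len(singles) == 2

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_scanner(self, pvalues):
        regions, singles = corate.find_significant_regions(_results_frame(pvalues), alpha=0.05)
        exp_regions, exp_singles = _brute_force_regions(pvalues, 0.05)
        assert len(regions) == len(exp_regions)
        assert len(singles) == len(exp_singles)
        for row, (a, b) in zip(regions.itertuples(), exp_regions):
            assert row.n_intervals == b - a + 1


class TestPairedTest:
    def _frame(self, rf, rm):
        k = len(rf)
        return pd.DataFrame(
            {
                "chrom": [f"c{i}" for i in range(k)],
                "r_f": rf,
                "r_m": rm,
                "p": [0.5] * k,
                "tested": True,
            }
        )

    def test_identical_means_give_p_one(self):
        frame = self._frame([0.05, 0.06, 0.07], [0.05, 0.06, 0.07])
        with pytest.warns(UserWarning):
            _, res = corate.chromosome_summary_and_paired_test(frame)
        assert res.pvalue == 1.0

    def test_nineteen_one_sided_pairs_exact_p(self):
        rf = [0.05 + 0.001 * (i + 1) for i in range(19)]
        rm = [0.05] * 19
        _, res = corate.chromosome_summary_and_paired_test(self._frame(rf, rm))
        assert res.n_pairs == 19
        assert res.pvalue == pytest.approx(2 / 2**19, rel=1e-9)

    def test_interval_unit_uses_all_rows(self):
        frame = self._frame([0.05, 0.06, 0.07, 0.08], [0.04, 0.05, 0.06, 0.07])
        frame["chrom"] = "c1"
        _, res = corate.chromosome_summary_and_paired_test(frame, unit="interval")
        assert res.n_pairs == 4
        assert res.unit == "interval"

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            corate.chromosome_summary_and_paired_test(self._frame([0.05], [0.04]))
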