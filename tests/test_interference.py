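"""Coefficient-of-coincidence MLEs, the interference LR test, phase cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.special import xlogy

from xopop import interference, simdata
from xopop.interference import ThreePointCounts
from xopop.simdata import PHASE_CASE_PERMUTATION

counts8 = st.tuples(*[st.integers(min_value=0, max_value=200)] * 8).filter(
    lambda c: sum(c) > 0
)


def _numeric_mle(counts: ThreePointCounts):
    """Independent oracle: 3-parameter maximization of the class likelihood."""
    a, b, c, d = counts.parental, counts.co_second, counts.co_first, counts.double

    def nll(x):
        r1, r2, coc = x
        p11 = r1 * r2 * coc
        probs = [1 - r1 - r2 + p11, r2 - p11, r1 - p11, p11]
        if min(probs) < 0 or r1 < 0 or r2 < 0 or coc < 0:
            return 1e9
        return -(xlogy(a, probs[0]) + xlogy(b, probs[1]) + xlogy(c, probs[2]) + xlogy(d, probs[3]))

    best = None
    for c0 in (0.25, 1.0, 3.0):
        res = optimize.minimize(
            nll, x0=[0.2, 0.2, c0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestCocMLE:
    @pytest.mark.parametrize(
        "counts, r1, r2, coc",
        [
            ((36, 4, 1, 9, 9, 1, 4, 36), 0.20, 0.10, 1.0),
            ((30, 2, 4, 10, 8, 4, 2, 40), 0.26, 0.12, 2.5641026),
            ((40, 6, 0, 12, 12, 0, 6, 24), 0.24, 0.12, 0.0),
        ],
    )
    def test_closed_form_examples(self, counts, r1, r2, coc):
        r1h, r2h, ch = interference.estimate_coc(ThreePointCounts(counts))
        assert r1h == pytest.approx(r1)
        assert r2h == pytest.approx(r2)
        assert ch == pytest.approx(coc, abs=1e-6)

    def test_zero_marginal_rate_gives_undefined_coc(self):
        r1, r2, coc = interference.estimate_coc(ThreePointCounts((50, 0, 0, 0, 0, 0, 0, 50)))
        assert r1 == 0.0 and np.isnan(coc)

    @settings(max_examples=100, deadline=None)
    @given(counts8)
    def test_closed_form_matches_numeric_maximization(self, raw):
        counts = ThreePointCounts(raw)
        r1, r2, coc = interference.estimate_coc(counts)
        if not np.isfinite(coc) or counts.double == 0:
            return  # boundary: oracle cannot pin C against a flat likelihood
        n1, n2, nc = _numeric_mle(counts)
        assert r1 == pytest.approx(n1, abs=1e-5)
        assert r2 == pytest.approx(n2, abs=1e-5)
        assert coc == pytest.approx(nc, abs=1e-4, rel=1e-4)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=0.45),
        st.floats(min_value=0.01, max_value=0.45),
        st.floats(min_value=0.0, max_value=2.0),
    )
    def test_class_probabilities_sum_to_one(self, r1, r2, coc):
        try:
            probs = simdata.three_point_class_probs(r1, r2, coc)
        except ValueError:
            return  # invalid (r1, r2, C) combination
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs >= 0)


class TestInterferenceLR:
    def test_exact_independence_gives_zero(self):
        lr, p, direction = interference.lr_interference(ThreePointCounts((36, 4, 1, 9, 9, 1, 4, 36)))
        assert lr == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert direction == "none"

    def test_frozen_negative_interference_example(self):
        lr, p, direction = interference.lr_interference(ThreePointCounts((30, 2, 4, 10, 8, 4, 2, 40)))
        assert lr == pytest.approx(10.166481, abs=1e-4)
        assert p == pytest.approx(1.4302e-3, rel=1e-3)
        assert direction == "negative"

    def test_zero_doubles_positive_direction(self):
        lr, p, direction = interference.lr_interference(ThreePointCounts((40, 6, 0, 12, 12, 0, 6, 24)))
        assert lr > 0
        assert direction == "positive"

    def test_undefined_coc_raises(self):
        with pytest.raises(ValueError):
            interference.lr_interference(ThreePointCounts((50, 0, 0, 0, 0, 0, 0, 50)))

    @settings(max_examples=100, deadline=None)
    @given(counts8)
    def test_nonnegative_zero_iff_coc_one(self, raw):
        counts = ThreePointCounts(raw)
        _, _, coc = interference.estimate_coc(counts)
        if not np.isfinite(coc):
            return
        lr, _, _ = interference.lr_interference(counts)
        assert lr >= 0.0
        if coc == 1.0:
            assert lr == pytest.approx(0.0, abs=1e-9)
        if lr == 0.0:
            assert coc == pytest.approx(1.0)


class TestPhaseCases:
    # a strongly linked canonical table (r1=0.1, r2=0.15, C=1, n=400 expected)
    CANONICAL = ThreePointCounts((302, 50, 6, 34, 34, 6, 50, 302))

    @pytest.mark.parametrize("case", [1, 2, 3, 4])
    def test_each_case_detected_and_canonicalized(self, case):
        permuted = self.CANONICAL.permute(PHASE_CASE_PERMUTATION[case])
        detected, canonical, informative = interference.resolve_phase_case(permuted)
        assert detected == case
        assert informative
        assert canonical.n == self.CANONICAL.n

    def test_case_permutations_match_marker_flips(self):
        # repulsion/coupling flips het/hom at marker 1 only; double repulsion
        # flips at marker 2 — the index maps frozen from first principles
        assert PHASE_CASE_PERMUTATION[3].tolist() == [4, 5, 6, 7, 0, 1, 2, 3]
        assert PHASE_CASE_PERMUTATION[4].tolist() == [2, 3, 0, 1, 6, 7, 4, 5]

    @settings(max_examples=100, deadline=None)
    @given(counts8, st.integers(min_value=0, max_value=7))
    def test_estimates_invariant_under_marker_relabeling(self, raw, flips):
        """Any het/hom relabeling of single markers leaves r1, r2, C, LR identical."""
        base = ThreePointCounts(raw)
        perm = np.arange(8)
        for bit, flip in ((4, 0b100), (2, 0b010), (1, 0b001)):
            if flips & flip:
                perm = perm ^ bit
        relabeled = ThreePointCounts(tuple(np.asarray(base.n)[perm]))
        _, canon_a, ok_a = interference.resolve_phase_case(base)
        _, canon_b, ok_b = interference.resolve_phase_case(relabeled)
        if not (ok_a and ok_b):
            return
        r1a, r2a, ca = interference.estimate_coc(canon_a)
        r1b, r2b, cb = interference.estimate_coc(canon_b)
        assert (r1a, r2a) == (r1b, r2b)  # bit-identical
        if np.isfinite(ca) or np.isfinite(cb):
            assert ca == cb
            assert interference.lr_interference(canon_a) == interference.lr_interference(canon_b)

    def test_uninformative_subpair_flagged(self):
        flat = ThreePointCounts((25, 25, 25, 25, 25, 25, 25, 25))
        _, _, informative = interference.resolve_phase_case(flat)
        assert not informative


class TestMilScan:
    def test_greedy_triple_chain(self):
        pos = np.array([0, 300_000, 600_000, 1_200_000, 1_800_000])
        triples = interference.select_mil_triples(pos, 500_000)
        assert triples == [(0, 2, 3), (2, 3, 4)]

    def test_too_few_markers_no_triples(self):
        assert interference.select_mil_triples(np.array([0, 600_000]), 500_000) == []

    def test_mil_larger_than_chromosome_no_triples(self):
        pos = np.array([0, 300_000, 600_000])
        assert interference.select_mil_triples(pos, 5_000_000) == []

    def test_empty_dataset_zero_summary(self, small_population):
        ds, _ = small_population
        empty = ds.subset(np.zeros(ds.n_markers, dtype=bool))
        summary, details = interference.mil_scan(
            empty, {"Chr01": 10_000_000, "Chr02": 8_000_000}, mils_bp=(500_000,)
        )
        assert (summary["n_pairs"] == 0).all()
        assert (summary["coverage"] == 0.0).all()

    def test_scan_runs_on_simulated_population(self, small_population):
        ds, _ = small_population
        table = interference.scan_triples(ds, "female", 500_000)
        assert len(table) > 0
        tested = table[table["tested"] == True]  # noqa: E712
        assert len(tested) > 0
        # the MLE triple always implies valid class frequencies
        for row in tested.itertuples():
            probs = simdata.three_point_class_probs(row.r1, row.r2, row.coc)
            assert probs.sum() == pytest.approx(1.0)
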