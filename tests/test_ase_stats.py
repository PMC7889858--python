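"""Binomial tests, Fisher's method, BH adjustment, and both ASE models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asedetect.ase_stats import (
    bh_adjust,
    binomial_test,
    binomial_test_many,
    fisher_combine,
    run_mdfdr,
    run_meta_analysis,
    sample_tests,
)

from .conftest import make_informative


def brute_force_binomial_p(ref: int, alt: int) -> float:
    """Independent oracle: exact enumeration of Binomial(n, 0.5) via integers."""
    n = ref + alt
    k = max(ref, alt)
    tail = sum(math.comb(n, j) for j in range(k, n + 1))
    return min(1.0, 2 * tail / 2**n)


class TestBinomialTest:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (10, 10, 1.0),
            (15, 5, 2 * 21700 / 2**20),  # 0.0413895
            (20, 0, 2 / 2**20),  # 1.9073e-6
            (0, 20, 2 / 2**20),  # symmetric in the labels
            (1, 0, 1.0),  # one read cannot deviate from 50:50
        ],
    )
    def test_frozen_enumeration_values(self, ref, alt, expected):
        assert binomial_test(ref, alt) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_small_grid(self):
        for n in range(1, 31):
            for ref in range(n + 1):
                got = binomial_test(ref, n - ref)
                assert got == pytest.approx(brute_force_binomial_p(ref, n - ref), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_test(-1, 5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            binomial_test(0, 0)

    def test_vectorised_equals_scalar(self, rng):
        ref = rng.integers(0, 60, size=200)
        alt = rng.integers(0, 60, size=200)
        keep = (ref + alt) >= 1
        ref, alt = ref[keep], alt[keep]
        many = binomial_test_many(ref, alt)
        for r, a, p in zip(ref, alt, many):
            assert p == binomial_test(int(r), int(a))


class TestFisherCombine:
    def test_single_pvalue_is_identity(self):
        for p in (0.001, 0.05, 0.5, 1.0):
            _, combined = fisher_combine([p])
            assert combined == pytest.approx(p, abs=1e-12)

    def test_two_half_pvalues_closed_form(self):
        x, combined = fisher_combine([0.5, 0.5])
        assert x == pytest.approx(-2 * (math.log(0.5) + math.log(0.5)), abs=1e-12)
        # chi-square survival with 4 df has closed form e^{-x/2}(1 + x/2)
        assert combined == pytest.approx(math.exp(-x / 2) * (1 + x / 2), abs=1e-12)
        assert combined == pytest.approx(0.59657, abs=5e-6)

    def test_all_ones_give_unit_pvalue(self):
        x, combined = fisher_combine([1.0, 1.0, 1.0])
        assert x == 0.0
        assert combined == 1.0

    def test_zero_input_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            x, combined = fisher_combine([0.0, 0.5])
        assert math.isfinite(x) and 0.0 <= combined <= 1.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_statistic_is_permutation_invariant(self, pvals):
        x1, p1 = fisher_combine(pvals)
        x2, p2 = fisher_combine(list(reversed(pvals)))
        assert x1 == pytest.approx(x2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


def bh_reference(pvals):
    """Quadratic-time reference: adj_i = min over thresholds t >= p_i of m*t/#{p<=t}."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    counts = (p[None, :] <= p[:, None]).sum(axis=1)  # #{q <= p_j} per threshold
    ratio = np.minimum(1.0, m * p / counts)
    return np.array([ratio[p >= pi].min() for pi in p])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.05, 0.01], [0.05, 0.02]),  # order restored to input order
        ],
    )
    def test_hand_worked_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-12)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_quadratic_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        p = rng.uniform(size=n)
        assert bh_adjust(p) == pytest.approx(bh_reference(p), abs=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 150)))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            assert bh_adjust(p) == pytest.approx(adj, abs=1e-12)


class TestMetaAnalysis:
    def test_balanced_single_sample_not_ase(self):
        results = run_meta_analysis([make_informative([(10, 10)])])
        r = results[0]
        assert r.combined_p == 1.0 and not r.is_ase

    def test_extreme_single_sample_flagged(self):
        # m = 1 so BH is the identity; k = 1 so Fisher is the identity
        results = run_meta_analysis([make_informative([(20, 0)])])
        r = results[0]
        assert r.adj_p == pytest.approx(2 / 2**20, rel=1e-9)
        assert r.is_ase

    def test_bh_spans_all_informative_snps(self):
        snps = [make_informative([(20, 0)], pos=1000 * i) for i in range(1, 11)]
        snps.append(make_informative([(25, 25)], pos=99000))
        results = run_meta_analysis(snps)
        raw = [r.combined_p for r in results]
        assert [r.adj_p for r in results] == pytest.approx(list(bh_adjust(raw)), abs=1e-15)

    def test_power_monotone_in_depth_and_skew(self, rng):
        def power(depth, skew):
            from asedetect.simulate import simulate_informative

            snps = simulate_informative(300, 5, depth, skew, np.random.default_rng(11))
            res = run_meta_analysis(snps)
            return np.mean([r.is_ase for r in res])

        assert power(100, 0.7) >= power(30, 0.7)
        assert power(60, 0.8) >= power(60, 0.65)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_meta_analysis([])


class TestMdfdr:
    def test_single_variant_single_sample_thresholds_collapse_to_alpha(self):
        # p = 0.0414 (15 vs 5 at depth 20) < alpha -> selected and significant
        res = run_mdfdr([make_informative([(15, 5)])], alpha=0.05)[0]
        assert res.selected
        assert res.n_significant == 1
        assert res.directions[0] == "ref_higher"

    def test_single_variant_above_alpha_not_selected(self):
        # p = 0.0639 (14 vs 5 at depth 19) > alpha
        res = run_mdfdr([make_informative([(14, 5)])], alpha=0.05)[0]
        assert binomial_test(14, 5) > 0.05
        assert not res.selected and res.n_significant == 0

    def test_significant_samples_only_in_selected_variants(self, rng):
        from asedetect.simulate import simulate_informative

        snps = simulate_informative(100, 8, 50, 0.5, rng) + simulate_informative(
            20, 8, 80, 0.8, np.random.default_rng(5)
        )
        for res in run_mdfdr(snps):
            if not res.selected:
                assert res.n_significant == 0

    def test_discovery_count_monotone_in_alpha(self, rng):
        from asedetect.simulate import simulate_informative

        snps = simulate_informative(150, 8, 60, 0.65, rng)
        loose = run_mdfdr(snps, alpha=0.05)
        tight = run_mdfdr(snps, alpha=0.01)
        assert sum(r.n_significant for r in tight) <= sum(r.n_significant for r in loose)
        tight_sel = {r.key() for r in tight if r.selected}
        loose_sel = {r.key() for r in loose if r.selected}
        assert tight_sel <= loose_sel

    def test_both_models_subset_of_informative(self, rng):
        from asedetect.simulate import simulate_informative

        snps = simulate_informative(100, 6, 50, 0.6, rng)
        keys = {s.key() for s in snps}
        meta = {r.key() for r in run_meta_analysis(snps) if r.is_ase}
        mdfdr = {r.key() for r in run_mdfdr(snps) if r.selected}
        assert meta <= keys and mdfdr <= keys

    def test_fisher_screening_variant_runs(self):
        res = run_mdfdr([make_informative([(15, 5)])], screening="fisher")[0]
        assert res.selected

    def test_sample_tests_align_with_counts(self):
        snp = make_informative([(30, 10), (10, 30), (20, 20)])
        tests = sample_tests(snp)
        assert [t.direction for t in tests] == ["ref_higher", "alt_higher", "tie"]
        assert tests[2].p == 1.0
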