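"""Exact tests, FDR control, residuals and spectra against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, hypergeom, multivariate_hypergeom
from statsmodels.stats.multitest import multipletests

from popdiff import (
    GenotypeCounts,
    ValidationError,
    VariantKey,
    adjusted_residuals,
    allele_frequency_spectrum,
    benjamini_hochberg,
    expected_counts,
    fisher_exact_2x2,
    fisher_exact_2xk,
    independence_expected,
)
from popdiff.integration import MergedVariant


def oracle_2x2(table, eps=1e-7):
    """Direct hypergeometric enumeration of the probability-mass p-value."""
    t = np.asarray(table)
    r1 = t[0].sum()
    c1, c2 = t.sum(axis=0)
    n = t.sum()
    if min(r1, t[1].sum(), c1, c2) == 0:
        return 1.0
    support = np.arange(max(0, r1 - c2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[t[0, 0] - support[0]]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + eps)].sum()))


def oracle_2x3(table, eps=1e-7):
    """Brute-force enumeration over the first row's free cells."""
    t = np.asarray(table)
    cols = t.sum(axis=0)
    n1 = int(t[0].sum())
    if n1 == 0 or t[1].sum() == 0:
        return 1.0
    p_obs = multivariate_hypergeom.pmf(t[0], cols, n1)
    total = 0.0
    for a in range(min(n1, cols[0]) + 1):
        for b in range(min(n1 - a, cols[1]) + 1):
            c = n1 - a - b
            if c > cols[2]:
                continue
            p = multivariate_hypergeom.pmf([a, b, c], cols, n1)
            if p <= p_obs * (1 + eps):
                total += p
    return float(min(1.0, total))


class TestExpectedCounts:
    @pytest.mark.parametrize(
        "focal,others,expected",
        [
            ((298, 44), (61000, 24500), (244.0, 98.0)),
            ((100, 0), (50, 50), (50.0, 50.0)),
            ((0, 0), (10, 10), (0.0, 0.0)),
        ],
    )
    def test_examples(self, focal, others, expected):
        np.testing.assert_allclose(expected_counts(focal, others), expected)

    def test_all_zero_others_raises(self):
        with pytest.raises(ValidationError, match="no reference population"):
            expected_counts((10, 5), (0, 0))

    @given(
        focal=st.lists(st.integers(0, 10_000), min_size=2, max_size=3),
        others=st.lists(st.integers(0, 10_000), min_size=2, max_size=3),
    )
    def test_conservation(self, focal, others):
        if sum(others) == 0 or len(focal) != len(others):
            return
        exp = expected_counts(focal, others)
        assert abs(exp.sum() - sum(focal)) < 1e-9 * max(1, sum(focal))


class TestFisher2x2:
    def test_enumeration_example(self):
        # margins (4,4)/(4,4): point probs (1,16,36,16,1)/70, observed 16/70
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-12)

    def test_modal_table_gives_one(self):
        assert fisher_exact_2x2([[10, 10], [10, 10]]) == 1.0

    def test_degenerate_column_margin(self):
        assert fisher_exact_2x2([[5, 0], [7, 0]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_large_margins_supported(self):
        # pooled rows at real-catalogue scale stay finite and in [0, 1]
        p = fisher_exact_2x2([[298, 44], [610_000, 245_000]])
        assert 0.0 < p < 1e-6

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            t = rng.integers(0, 60, size=(2, 2))
            assert fisher_exact_2x2(t) == pytest.approx(oracle_2x2(t), rel=1e-9, abs=1e-12)

    def test_p_monotone_in_point_probability(self):
        """For fixed margins, a less probable observed table never has the
        larger p-value (the ordering the mass method is built on)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            r1 = int(rng.integers(1, 20))
            c1 = int(rng.integers(1, 30))
            c2 = int(rng.integers(1, 30))
            n = c1 + c2
            if r1 > n:
                continue
            support = np.arange(max(0, r1 - c2), min(r1, c1) + 1)
            pmf = hypergeom.pmf(support, n, c1, r1)
            pvals = np.array(
                [
                    fisher_exact_2x2([[a, r1 - a], [c1 - a, c2 - (r1 - a)]])
                    for a in support
                ]
            )
            order = np.argsort(pmf)
            assert (np.diff(pvals[order]) >= -1e-12).all()


class TestFisher2xK:
    def test_symmetric_modal_table(self):
        assert fisher_exact_2xk([[1, 1, 1], [1, 1, 1]]) == 1.0

    def test_zero_row_degenerate(self):
        assert fisher_exact_2xk([[0, 0, 0], [4, 5, 6]]) == 1.0

    def test_disjoint_support_example(self):
        t = [[5, 0, 0], [0, 5, 5]]
        assert fisher_exact_2xk(t) == pytest.approx(oracle_2x3(t), rel=1e-9)

    def test_reduces_to_2x2(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 50, size=(2, 2))
            assert fisher_exact_2xk(t) == pytest.approx(
                fisher_exact_2x2(t), rel=1e-12, abs=1e-15
            )

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            t = np.vstack([rng.integers(0, 8, size=3), rng.integers(0, 300, size=3)])
            if t.sum() == 0:
                continue
            assert fisher_exact_2xk(t) == pytest.approx(oracle_2x3(t), rel=1e-9, abs=1e-12)


class TestBenjaminiHochberg:
    def test_all_ones_rejected_nothing(self):
        assert benjamini_hochberg([1.0] * 10) == [False] * 10

    def test_empty(self):
        assert benjamini_hochberg([]) == []

    def test_ties_share_a_fate(self):
        flags = benjamini_hochberg([0.01, 0.01, 0.8, 0.9], q=0.05)
        assert flags[:2] == [True, True]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(size=rng.integers(1, 40))
            ours = benjamini_hochberg(p, q=0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert ours == list(theirs)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.floats(0.01, 0.2))
    def test_contains_bonferroni_rejections(self, pvals, q):
        """The BH rejection set always contains the Bonferroni one."""
        flags = benjamini_hochberg(pvals, q=q)
        m = len(pvals)
        for p, flag in zip(pvals, flags):
            if p <= q / m:
                assert flag


class TestAdjustedResiduals:
    def test_zero_when_observed_equals_expected(self):
        o = np.array([[20, 20], [20, 20]])
        np.testing.assert_allclose(adjusted_residuals(o), np.zeros((2, 2)), atol=1e-12)

    def test_squared_residual_equals_chi2_on_2x2(self):
        o = np.array([[30, 10], [10, 30]])
        r = adjusted_residuals(o, independence_expected(o))
        chi2 = ((o - independence_expected(o)) ** 2 / independence_expected(o)).sum()
        assert chi2 == pytest.approx(20.0)
        np.testing.assert_allclose(r**2, chi2, rtol=1e-12)
        assert abs(r[0, 0]) == pytest.approx(np.sqrt(20), rel=1e-12)

    def test_chi2_identity_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            o = rng.integers(1, 80, size=(2, 2))
            chi2 = chi2_contingency(o, correction=False)[0]
            r = adjusted_residuals(o)
            np.testing.assert_allclose(r**2, chi2, rtol=1e-9)

    def test_risk_allele_direction(self):
        # focal REF excess / ALT deficit relative to the pooled row
        o = np.array([[298, 44], [61000, 24500]])
        r = adjusted_residuals(o)
        assert r[0, 0] > 0 and r[0, 1] < 0

    def test_zero_expected_cell_is_nan(self):
        o = np.array([[5, 0], [7, 0]])
        r = adjusted_residuals(o)
        assert np.isnan(r[:, 1]).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_residuals(np.ones((2, 2)), np.ones((2, 3)))


def _variant(pos, counts):
    return MergedVariant(
        key=VariantKey("1", pos, "C", "T"),
        counts=counts,
        source={label: "table" for label in counts},
    )


class TestSpectrum:
    def test_bin_placement_last_bin_closed(self):
        v = _variant(1, {"x": GenotypeCounts(1, 0, 1)})  # AF exactly 0.5
        hist = allele_frequency_spectrum([v], ["x"], n_bins=2)
        assert hist.counts["x"].tolist() == [0, 1]
        v2 = _variant(2, {"x": GenotypeCounts(0, 0, 5)})  # AF 1.0 -> last closed bin
        hist2 = allele_frequency_spectrum([v2], ["x"], n_bins=2)
        assert hist2.counts["x"].tolist() == [0, 1]

    def test_no_variants(self):
        hist = allele_frequency_spectrum([], ["x"], n_bins=4)
        assert hist.counts["x"].tolist() == [0, 0, 0, 0]

    def test_matches_direct_binning_of_beta_frequencies(self):
        rng = np.random.default_rng(21)
        afs = rng.beta(0.2, 2.0, size=1000)
        variants = []
        for i, p in enumerate(afs):
            n = 100
            draw = rng.multinomial(n, [(1 - p) ** 2, 2 * p * (1 - p), p**2])
            variants.append(_variant(i + 1, {"x": GenotypeCounts(*map(int, draw))}))
        hist = allele_frequency_spectrum(variants, ["x"], n_bins=50)
        empirical = [v.counts["x"].alt_frequency for v in variants]
        expected, _ = np.histogram(empirical, bins=np.linspace(0, 1, 51))
        assert hist.counts["x"].tolist() == expected.tolist()
        # rare-heavy Beta(0.2, 2): most mass in the lowest bins
        assert hist.counts["x"][:5].sum() > 0.5 * len(variants)

    def test_counts_sum_to_non_absent_variants(self):
        variants = [
            _variant(1, {"x": GenotypeCounts(5, 1, 0), "y": None}),
            _variant(2, {"x": None, "y": GenotypeCounts(5, 0, 0)}),
        ]
        hist = allele_frequency_spectrum(variants, ["x", "y"], n_bins=10)
        assert hist.counts["x"].sum() == 1
        assert hist.counts["y"].sum() == 1

    def test_focal_vs_others_pooling(self):
        variants = [
            _variant(
                1,
                {
                    "focal": GenotypeCounts(1, 0, 0),
                    "a": GenotypeCounts(1, 1, 0),
                    "b": GenotypeCounts(0, 1, 1),
                },
            )
        ]
        hist = allele_frequency_spectrum(
            variants, ["focal", "a", "b"], n_bins=10, focal="focal"
        )
        # pooled others: (1,2,1) -> AF 0.5
        assert hist.counts["Others"].tolist()[5] == 1
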