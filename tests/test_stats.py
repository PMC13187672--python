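import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from darkinhib.stats import (
    DegenerateDataError,
    compact_letter_display,
    dunn_posthoc,
    holm_adjust,
    kruskal_wallis,
)


class TestKruskalWallis:
    def test_rank_sum_formula_oracle(self):
        # direct evaluation, no ties: ranks 1,2 | 3,4
        # H = 12/(4*5) * (3^2/2 + 7^2/2) - 3*5 = 2.4
        h, df, p = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)
        assert df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [np.round(rng.normal(0, 2, rng.integers(4, 10))) for _ in range(3)]
        h, df, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[5, 5], [5, 5]])

    def test_type_i_error_calibration(self):
        # two groups from the same distribution: rejection rate ~ alpha
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 1, 15)
            _, _, p = kruskal_wallis([a, b])
            rejections += p < 0.05
        assert 0.03 < rejections / n_rep < 0.07

    def test_invariant_under_wholesale_group_swap(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 6.0, 7.0]
        h1, _, _ = kruskal_wallis([a, b])
        h2, _, _ = kruskal_wallis([b, a])
        assert h1 == pytest.approx(h2)


class TestHolm:
    def test_step_down_oracle(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, ps):
        adj = holm_adjust(ps)
        assert all(0.0 <= a <= 1.0 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))
        # order-preserving: sorting by raw p sorts adjusted p
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.array(adj)[order]) >= -1e-12)


class TestDunn:
    def test_two_groups_equal_normal_approximation(self):
        groups = {"a": [1.0, 2.0, 5.0], "b": [3.0, 4.0, 6.0]}
        (res,) = dunn_posthoc(groups)
        # direct z from the Dunn formula with no ties
        pooled = np.concatenate([groups["a"], groups["b"]])
        n = pooled.size
        ranks = sps.rankdata(pooled)
        z_expected = (ranks[:3].mean() - ranks[3:].mean()) / np.sqrt(
            n * (n + 1) / 12 * (1 / 3 + 1 / 3)
        )
        assert res.z == pytest.approx(z_expected)
        assert res.p_raw == pytest.approx(2 * sps.norm.sf(abs(z_expected)))
        # Holm with a single pair is the identity
        assert res.p_adjusted == pytest.approx(res.p_raw)

    def test_three_separated_groups_direct_formula(self):
        # ranks are 1..9 regardless of the magnitude gaps; direct evaluation
        # of the Dunn formula gives z = -6/sqrt(7.5*(2/3)) for the outer pair
        # (p = 0.0073) and z = -3/sqrt(7.5*(2/3)) for adjacent pairs (p = 0.18)
        groups = {"a": [1, 2, 3], "b": [11, 12, 13], "c": [101, 102, 103]}
        results = dunn_posthoc(groups)
        assert len(results) == 3
        se = np.sqrt(9 * 10 / 12 * (2 / 3))
        ac = next(r for r in results if set(r.pair) == {"a", "c"})
        ab = next(r for r in results if set(r.pair) == {"a", "b"})
        assert abs(ac.z) == pytest.approx(6 / se)
        assert abs(ab.z) == pytest.approx(3 / se)
        assert ac.p_raw < 0.05 < ab.p_raw

    def test_tie_correction_enters_variance(self):
        # heavy ties shrink the variance term relative to the no-tie case
        tied = {"a": [1, 1, 1, 2], "b": [2, 2, 3, 3]}
        (res_tied,) = dunn_posthoc(tied)
        assert np.isfinite(res_tied.z)

    def test_larger_rank_gap_gives_larger_z_at_equal_sizes(self, rng):
        base = list(rng.normal(0, 1, 6))
        near = {"a": base, "b": [v + 0.5 for v in base]}
        far = {"a": base, "b": [v + 5.0 for v in base]}
        (z_near,) = dunn_posthoc(near)
        (z_far,) = dunn_posthoc(far)
        assert abs(z_far.z) > abs(z_near.z)


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        groups = ["g1", "g2", "g3"]
        sig = {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        letters = compact_letter_display(groups, sig)
        assert len(set(letters.values())) == 3
        assert all(len(v) == 1 for v in letters.values())

    def test_chain_case_shares_middle(self):
        letters = compact_letter_display(["A", "B", "C"], {("A", "C")})
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])

    @pytest.mark.parametrize("seed", range(8))
    def test_letter_partition_encodes_exactly_the_ns_pairs(self, seed):
        # brute-force property: share a letter  <=>  pair not significant
        rng = np.random.default_rng(seed)
        names = [f"g{i}" for i in range(rng.integers(2, 7))]
        sig = set()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if rng.random() < 0.4:
                    sig.add((a, b))
        letters = compact_letter_display(names, sig)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                shares = bool(set(letters[a]) & set(letters[b]))
                assert shares == ((a, b) not in sig)
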