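from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from darkinhib.core import (
    aggregate_species,
    covariate_screen,
    dark_inhibition,
    dl_meta_regression,
    filter_by_method,
    method_concordance,
)
from darkinhib.types import ActivityObservation, AssayMethod, Dataset, Taxonomy


def obs(species="Pisum sativum", light=100.0, dark=50.0,
        method=AssayMethod.RADIOLABEL_CO2, source="s1", **kw):
    return ActivityObservation(
        source_id=source,
        taxonomy=Taxonomy(order_code="Fab", species=species),
        light_activity=light,
        dark_activity=dark,
        method=method,
        **kw,
    )


class TestDarkInhibition:
    @pytest.mark.parametrize(
        "light, dark, percent",
        [(12.0, 12.0, 0.0), (100.0, 107.0, -7.0), (50.0, 0.0, 100.0)],
    )
    def test_ratio_and_sign_convention(self, light, dark, percent):
        di = dark_inhibition(light, dark)
        assert di.percent == pytest.approx(percent)
        assert di.percent == pytest.approx(100.0 * di.ratio)

    def test_nonpositive_light_rejected(self):
        with pytest.raises(ValueError):
            dark_inhibition(0.0, 1.0)

    @given(
        light=st.floats(0.1, 1e6),
        dark=st.floats(0.0, 1e6),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, light, dark, scale):
        a = dark_inhibition(light, dark).ratio
        b = dark_inhibition(scale * light, scale * dark).ratio
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


class TestAggregateSpecies:
    def test_two_point_mean_and_sample_sd(self):
        ds = Dataset(observations=[obs(dark=20.0), obs(dark=8.0)])  # 80%, 92%
        (summary,) = aggregate_species(ds)
        assert summary.mean_di_percent == pytest.approx(86.0)
        assert summary.sd_di_percent == pytest.approx(np.std([80, 92], ddof=1))
        assert summary.n_datapoints == 2

    def test_single_observation_has_no_sd(self):
        ds = Dataset(observations=[obs(dark=83.0)])
        (summary,) = aggregate_species(ds)
        assert summary.mean_di_percent == pytest.approx(17.0)
        assert summary.sd_di_percent is None

    def test_monte_carlo_mean_recovery(self, rng):
        # species true mean 50, noise sd 5, n=20: direct-averaging oracle
        percents = 50.0 + rng.normal(0, 5, 20)
        ds = Dataset(
            observations=[obs(dark=100.0 - p) for p in percents]
        )
        (summary,) = aggregate_species(ds)
        assert summary.mean_di_percent == pytest.approx(percents.mean(), abs=1e-9)
        assert abs(summary.mean_di_percent - 50.0) < 3.0


class TestFilterByMethod:
    def test_counts_and_report(self):
        ds = Dataset(
            observations=[obs() for _ in range(5)]
            + [obs(method=AssayMethod.COUPLED_3PGA_NADH) for _ in range(2)]
        )
        kept, report = filter_by_method(ds, AssayMethod.RADIOLABEL_CO2)
        assert len(kept.observations) == 5
        assert report.removed_per_method == {"coupled_3PGA_NADH": 2}
        assert set(kept.observations) <= set(ds.observations)

    def test_absent_method_leaves_empty_list(self):
        ds = Dataset(observations=[obs()])
        kept, report = filter_by_method(ds, AssayMethod.RADIOLABEL_CA1P)
        assert kept.observations == [] and report.n_kept == 0

    def test_mixed_method_species_partially_retained(self):
        ds = Dataset(
            observations=[obs(dark=10), obs(dark=20, method=AssayMethod.RADIOLABEL_CA1P)]
        )
        kept, _ = filter_by_method(ds, AssayMethod.RADIOLABEL_CO2)
        assert [o.dark_activity for o in kept.observations] == [10]


def _exact_permutation_p(a, b):
    """Exact permutation null of the Kruskal-Wallis H for two small groups."""
    from darkinhib.stats import kruskal_wallis

    pooled = list(a) + list(b)
    h_obs, _, _ = kruskal_wallis([a, b])
    n = len(a)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        h, _, _ = kruskal_wallis([ga, gb])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


class TestMethodConcordance:
    def _ds(self, a, b):
        return Dataset(
            observations=[obs(dark=100 - v) for v in a]
            + [obs(dark=100 - v, method=AssayMethod.COUPLED_3PGA_NADH) for v in b]
        )

    def test_identical_methods_not_flagged(self):
        res = method_concordance(self._ds([10, 12, 11], [10, 12, 11]), "Pisum sativum")
        assert not res.flagged and res.p_value > 0.5

    def test_separated_methods_flagged_matches_exact_permutation(self):
        a, b = [10.0, 12.0, 11.0], [60.0, 62.0, 61.0]
        res = method_concordance(self._ds(a, b), "Pisum sativum")
        assert res.flagged
        # chi-square approximation should agree in direction with the exact
        # permutation test over all 20 assignments
        assert _exact_permutation_p(a, b) == pytest.approx(0.1, abs=1e-9)
        assert res.p_value < 0.05

    def test_single_method_insufficient(self):
        ds = Dataset(observations=[obs(dark=10), obs(dark=20)])
        res = method_concordance(ds, "Pisum sativum")
        assert res.insufficient and res.p_value is None


class TestDLMetaRegression:
    def test_hand_computed_four_source_oracle(self):
        # direct evaluation of the DL formulas for a fixed 4-study table
        y = np.array([10.0, 20.0, 30.0, 42.0])
        v = np.array([4.0, 4.0, 9.0, 9.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), x])
        w = 1 / v
        beta_fe = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        resid = y - X @ beta_fe
        q_e = (w * resid**2).sum()
        p = 2
        trace_corr = np.trace(
            np.linalg.inv(X.T @ (X * w[:, None])) @ (X.T * w**2) @ X
        )
        tau2_expected = max(0.0, (q_e - (4 - p)) / (w.sum() - trace_corr))
        w_re = 1 / (v + tau2_expected)
        beta_expected = np.linalg.solve(
            X.T @ (X * w_re[:, None]), X.T @ (w_re * y)
        )

        coef, se, z, tau2 = dl_meta_regression(y, v, x)
        assert tau2 == pytest.approx(tau2_expected)
        assert coef == pytest.approx(beta_expected[1])

    def test_zero_heterogeneity_collapses_to_weighted_ols(self):
        # residuals small enough that Q_E <= k - p  =>  tau2 = 0
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 5.0 + 2.0 * x
        v = np.full(4, 4.0)
        coef, se, z, tau2 = dl_meta_regression(y, v, x)
        assert tau2 == 0.0
        assert coef == pytest.approx(2.0)


class TestCovariateScreen:
    def test_null_covariate_type_i_error(self, rng):
        # independent covariate: the trend test should flag ~alpha of the time
        flags = 0
        n_rep = 200
        for _ in range(n_rep):
            covs = rng.normal(5, 2, 40)
            ds = Dataset(
                observations=[
                    obs(dark=100 - p, assay_pH=c, source=f"s{i % 8}")
                    for i, (p, c) in enumerate(zip(rng.normal(40, 10, 40), covs))
                ]
            )
            res = covariate_screen(ds, "assay_pH", alpha=0.05)[0]
            flags += res.flagged
        assert flags / n_rep < 0.10

    def test_few_distinct_values_insufficient(self):
        ds = Dataset(observations=[obs(dark=10, assay_pH=8.0), obs(dark=20, assay_pH=8.0)])
        res = covariate_screen(ds, "assay_pH")[0]
        assert res.insufficient

    def test_strong_covariate_flagged_by_both_tests(self, rng):
        covs = np.repeat([0.0, 5.0, 10.0, 20.0], 10)
        ds = Dataset(
            observations=[
                obs(dark=100 - (10 + 3 * c + rng.normal(0, 2)), edta_mM=c,
                    source=f"s{int(c)}")
                for c in covs
            ]
        )
        trend, meta = covariate_screen(ds, "edta_mM", alpha=0.05)
        assert trend.flagged
        assert meta.flagged
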