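import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from darkinhib.classify import (
    assign_level,
    classification_concordance,
    compare_groups,
    level_counts,
)
from darkinhib.modality import PAPER_DEFAULT, ThresholdSet
from darkinhib.types import Level


class TestAssignLevel:
    @pytest.mark.parametrize(
        "percent, expected",
        [
            (86.0, Level.VERY_HIGH),
            (48.0, Level.HIGH),
            (-7.0, Level.LOW),
            (44.0, Level.HIGH),  # boundary: left-closed upper category
            (18.0, Level.MODERATE),
            (77.0, Level.VERY_HIGH),
            (17.999, Level.LOW),
        ],
    )
    def test_published_thresholds(self, percent, expected):
        assert assign_level(percent, PAPER_DEFAULT) is expected

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=100, derandomize=True)
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert (
            assign_level(lo, PAPER_DEFAULT).rank
            <= assign_level(hi, PAPER_DEFAULT).rank
        )


class TestLevelCounts:
    def test_fixture_printed_totals(self, fixture_dataset):
        table = level_counts(fixture_dataset.summaries)
        assert table["count"].tolist() == [57, 45, 45, 10]
        assert table["count"].sum() == 157
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_fixture_by_order(self, fixture_dataset):
        table = level_counts(fixture_dataset.summaries, by="order")
        assert table.loc["Fab", "total"] == 94
        assert table.loc["Poa", "total"] == 21
        assert table["total"].sum() == 157

    def test_empty_input(self):
        assert level_counts([]).empty

    def test_assigned_labels_match_printed_when_thresholds_published(self, fixture_dataset):
        printed = level_counts(fixture_dataset.summaries)
        assigned = level_counts(
            fixture_dataset.summaries, use_printed_labels=False, thresholds=PAPER_DEFAULT
        )
        # one known disagreement moves one species from moderate to high
        assert assigned.loc["moderate", "count"] == printed.loc["moderate", "count"] - 1
        assert assigned.loc["high", "count"] == printed.loc["high", "count"] + 1


class TestConcordance:
    def test_fixture_unique_disagreement(self, fixture_dataset):
        report = classification_concordance(fixture_dataset.summaries, PAPER_DEFAULT)
        assert report.n_total == 157
        assert report.n_agree == 156
        ((species, mean, printed, assigned),) = report.disagreements
        assert species == "Melilotus albus"
        assert mean == 46.0 and printed == "moderate" and assigned == "high"

    def test_round_trip_labels_fully_agree(self, fixture_dataset):
        from dataclasses import replace

        relabelled = [
            replace(s, level_label=assign_level(s.mean_di_percent, PAPER_DEFAULT))
            for s in fixture_dataset.summaries
        ]
        report = classification_concordance(relabelled, PAPER_DEFAULT)
        assert report.n_agree == report.n_total

    def test_shifted_thresholds_break_very_high(self, fixture_dataset):
        shifted = ThresholdSet(cutpoints=(118.0, 144.0, 177.0), provenance="derived")
        report = classification_concordance(fixture_dataset.summaries, shifted)
        broken = {d[0] for d in report.disagreements}
        vh = {
            s.taxonomy.species
            for s in fixture_dataset.summaries
            if s.level_label is Level.VERY_HIGH
        }
        assert vh <= broken


class TestCompareGroups:
    def test_fixture_orders_surviving_min_n(self, fixture_dataset, fixture_means):
        labels = [s.taxonomy.order_code for s in fixture_dataset.summaries]
        comp = compare_groups(fixture_means, labels, grouping="order", min_group_n=5)
        assert set(comp.group_sizes) == {"Fab", "Poa", "Sol", "Car", "Ast"}
        assert "Nym" in comp.dropped_groups
        assert comp.H is not None and comp.p_value < 0.05

    def test_shifted_tribe_gets_unshared_letter(self, rng):
        values = list(rng.normal(10, 3, 30)) + list(rng.normal(60, 3, 10))
        labels = (
            ["t1"] * 10 + ["t2"] * 10 + ["t3"] * 10 + ["shifted"] * 10
        )
        comp = compare_groups(np.array(values), labels, min_group_n=5)
        shifted_letters = set(comp.letters["shifted"])
        for other in ("t1", "t2", "t3"):
            assert not shifted_letters & set(comp.letters[other])

    def test_all_groups_below_min_is_insufficient(self, rng):
        comp = compare_groups(
            rng.normal(0, 1, 8), ["a"] * 4 + ["b"] * 4, min_group_n=5
        )
        assert comp.insufficient
        assert comp.H is None and comp.letters == {}

    def test_holm_ordering_in_pairwise(self, fixture_dataset, fixture_means):
        labels = [s.taxonomy.order_code for s in fixture_dataset.summaries]
        comp = compare_groups(fixture_means, labels, grouping="order")
        for pr in comp.pairwise:
            assert pr.p_adjusted >= pr.p_raw - 1e-12

    def test_conservation_of_counts(self, fixture_dataset):
        table = level_counts(fixture_dataset.summaries, by="order")
        assert table["total"].sum() == len(fixture_dataset.summaries)
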