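"""Percentile scoring, combined score, ranking and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchrank import (
    MetricDistribution,
    build_ranking,
    combined_score,
    correlation_report,
    rank_cut_nodes,
)
from patchrank import reference as ref
from patchrank.scoring import EmptyPopulationError


class TestPercentileScore:
    def test_component_count_reference_histogram(self):
        """The published C_A percentile column reproduces to 5 decimals."""
        d = MetricDistribution.from_histogram("C_A", ref.COMPONENT_COUNT_HISTOGRAM)
        printed = {
            1: 0.0, 2: 65.37786, 3: 84.35852, 4: 92.26714, 5: 95.43058,
            6: 97.18805, 7: 98.24253, 8: 98.59402, 9: 98.94552,
            11: 99.29701, 12: 99.47276, 17: 99.64851, 35: 99.82425,
        }
        for x, expected in printed.items():
            assert d.percentile(x) == pytest.approx(expected, abs=5e-6)

    def test_second_size_reference_prefix(self):
        d = MetricDistribution.from_histogram(
            "C_S",
            ref.SECOND_SIZE_HISTOGRAM_PREFIX,
            size=ref.N_CUT_NODES,
            complete_below=ref.SECOND_SIZE_COMPLETE_BELOW,
        )
        printed = {
            1: 0.0, 2: 59.40246, 3: 68.18981, 4: 71.17750, 5: 73.81371,
            6: 75.39543, 7: 77.15290, 8: 78.91037, 9: 79.78910,
            10: 80.66784, 11: 81.72232, 12: 82.24956,
        }
        for x, expected in printed.items():
            assert d.percentile(x) == pytest.approx(expected, abs=5e-6)

    def test_truncated_tail_refuses(self):
        d = MetricDistribution.from_histogram(
            "C_S", {1: 3, 2: 1, 9: 1}, size=10, complete_below=3
        )
        with pytest.raises(ValueError, match="truncated"):
            d.percentile(9)  # counts between 2 and 9 were elided
        assert d.percentile(2) == 30.0

    def test_all_identical_scores_zero(self):
        d = MetricDistribution.from_values("m", [4, 4, 4, 4])
        assert d.percentile(4) == 0.0

    def test_empty_population(self):
        with pytest.raises(EmptyPopulationError):
            MetricDistribution("m", {}, 0).percentile(1)

    def test_non_member_rejected(self):
        with pytest.raises(ValueError):
            MetricDistribution.from_values("m", [1, 2]).percentile(1.5)

    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_monotone_never_100_min_zero(self, values):
        d = MetricDistribution.from_values("m", values)
        uniq = sorted(set(values))
        scores = [d.percentile(x) for x in uniq]
        assert scores[0] == 0.0
        assert all(a < b for a, b in zip(scores, scores[1:]))
        assert all(0 <= s < 100 for s in scores)
        mult_max = values.count(max(values))
        assert scores[-1] == pytest.approx(
            100.0 * (len(values) - mult_max) / len(values)
        )


class TestCombinedScore:
    def test_worked_row_top(self):
        """Percentile addends of the top worked row sum to 202.11 at 2 dp."""
        p = {"C_A": 95.43058, "C_S": 85.06, "D": 21.62}
        assert round(combined_score(p), 2) == 202.11

    def test_worked_row_second(self):
        p = {"C_A": 84.36, "C_S": 0.0, "D": 45.17}
        assert round(combined_score(p), 2) == 129.53

    def test_all_minimum_row_is_zero(self):
        assert combined_score({"C_A": 0.0, "C_S": 0.0, "D": 0.0}) == 0.0

    def test_two_metric_subset(self):
        assert combined_score({"a": 0.0, "b": 50.0}, ("a", "b")) == 50.0

    def test_missing_metric_named(self):
        with pytest.raises(KeyError, match="D"):
            combined_score({"C_A": 1.0, "C_S": 2.0}, ("C_A", "C_S", "D"))

    def test_order_invariant(self):
        p = {"a": 10.0, "b": 20.0, "c": 30.0}
        assert combined_score(p, ("a", "b", "c")) == combined_score(p, ("c", "a", "b"))


class TestRanking:
    def test_descending_order(self):
        df = pd.DataFrame(
            {"node_id": ["a", "b", "c"], "combined": [202.11, 129.53, 0.0]}
        )
        out = rank_cut_nodes(df.sample(frac=1, random_state=0))
        assert list(out["node_id"]) == ["a", "b", "c"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_all_equal_share_rank_one(self):
        df = pd.DataFrame({"node_id": [3, 1, 2], "combined": [5.0, 5.0, 5.0]})
        out = rank_cut_nodes(df)
        assert list(out["node_id"]) == [1, 2, 3]  # id order within ties
        assert list(out["rank"]) == [1, 1, 1]

    def test_tie_broken_by_betweenness_then_id(self):
        df = pd.DataFrame(
            {
                "node_id": [1, 2, 3],
                "combined": [5.0, 5.0, 5.0],
                "C_B_norm": [0.1, 0.9, 0.9],
            }
        )
        out = rank_cut_nodes(df)
        assert list(out["node_id"]) == [2, 3, 1]
        assert list(out["rank"]) == [1, 1, 1]

    def test_matches_sort_oracle(self, rng):
        scores = rng.random(50).round(3)
        df = pd.DataFrame({"node_id": range(50), "combined": scores})
        out = rank_cut_nodes(df)
        assert list(out["combined"]) == sorted(scores, reverse=True)


class TestBuildRanking:
    def _metrics(self):
        return pd.DataFrame(
            {
                "node_id": [1, 2, 3, 4],
                "C_A": [5, 1, 1, 2],
                "C_S": [21, 1, 1, 3],
                "C_B_norm": [0.9, 0.1, 0.2, 0.5],
            }
        )

    def test_percentiles_and_combined(self):
        out = build_ranking(self._metrics(), ("C_A", "C_S"))
        top = out.iloc[0]
        assert top["node_id"] == 1
        assert top["C_A_pctl"] == 75.0
        assert top["C_S_pctl"] == 75.0
        assert top["combined"] == 150.0
        assert list(out["rank"]) == [1, 2, 3, 3]

    def test_noise_filter_drops_second_size_one(self):
        out = build_ranking(self._metrics(), ("C_A", "C_S"), noise_filter=True)
        assert set(out["node_id"]) == {1, 4}

    def test_missing_metric_column(self):
        with pytest.raises(KeyError, match="D"):
            build_ranking(self._metrics(), ("C_A", "C_S", "D"))


class TestCorrelationReport:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r = correlation_report(x, 2 * x + 1)
        assert r.pearson == pytest.approx(1.0)
        assert r.spearman == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.arange(10.0)
        r = correlation_report(x, -x)
        assert r.pearson == pytest.approx(-1.0)
        assert r.spearman == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.random(50), rng.random(50)
        r = correlation_report(x, y)
        # direct product-moment formula
        xm, ym = x - x.mean(), y - y.mean()
        pearson = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r.pearson == pytest.approx(pearson, abs=1e-12)
        # Spearman = Pearson on mid-ranks
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        rxm, rym = rx - rx.mean(), ry - ry.mean()
        spearman = (rxm * rym).sum() / np.sqrt((rxm**2).sum() * (rym**2).sum())
        assert r.spearman == pytest.approx(spearman, abs=1e-12)

    def test_zero_variance_flagged(self):
        r = correlation_report([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.degenerate
        assert np.isnan(r.pearson)
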