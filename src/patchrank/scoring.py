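"""Strictly-less percentile scores, combined score, ranking and correlation.

Fragmentation metrics (C_A, C_S), site distance and betweenness live on
incomparable scales, so a raw sum would let one metric dominate.  Each
metric is instead converted to a percentile score: the percentage of
population values *strictly less* than the measure.  The minimum value of
a metric scores exactly 0 (contributing nothing to priorities) and the
maximum never reaches 100; equal raw values always get equal scores.  The
combined score of a cut node is the sum of its (unrounded) percentile
scores over a configurable metric set; rounding is applied only when
reports are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import _node_key

__all__ = [
    "MetricDistribution",
    "percentile_score",
    "combined_score",
    "rank_cut_nodes",
    "correlation_report",
    "CorrelationReport",
    "build_ranking",
    "DEFAULT_METRICS",
]

DEFAULT_METRICS: tuple[str, ...] = ("C_A", "C_S", "D")


class EmptyPopulationError(ValueError):
    """Percentile scores are undefined over an empty population."""


@dataclass(frozen=True)
class MetricDistribution:
    """Multiset of metric values over the scoring population (all cut nodes).

    ``counts`` maps value -> occurrences.  ``size`` is the population size;
    it may exceed the histogram total when the histogram is a truncated
    excerpt.  A truncated distribution must declare ``complete_below``, the
    threshold under which the histogram is known to be complete; scores are
    then computable only for values below it (all strictly-smaller values
    are present), and anything else raises.
    """

    name: str
    counts: Mapping[float, int]
    size: int
    complete_below: float | None = None

    @classmethod
    def from_values(cls, name: str, values: Iterable[float]) -> "MetricDistribution":
        vals = list(values)
        counts: dict[float, int] = {}
        for x in vals:
            counts[x] = counts.get(x, 0) + 1
        return cls(name=name, counts=dict(sorted(counts.items())), size=len(vals))

    @classmethod
    def from_histogram(
        cls,
        name: str,
        counts: Mapping[float, int],
        size: int | None = None,
        complete_below: float | None = None,
    ) -> "MetricDistribution":
        total = sum(counts.values())
        if size is None:
            size = total
        elif size < total:
            raise ValueError(f"declared size {size} < histogram total {total}")
        if size > total and complete_below is None:
            raise ValueError(
                "a truncated histogram must declare complete_below"
            )
        return cls(
            name=name,
            counts=dict(sorted(counts.items())),
            size=size,
            complete_below=complete_below,
        )

    def percentile(self, x: float) -> float:
        """Strictly-less percentile score of a population member ``x``."""
        if self.size == 0:
            raise EmptyPopulationError(f"metric {self.name!r} has an empty population")
        if x not in self.counts:
            raise ValueError(
                f"{x!r} is not a member of the {self.name!r} population"
            )
        if self.complete_below is not None and x >= self.complete_below:
            raise ValueError(
                f"{self.name!r} histogram is truncated; scores are defined "
                f"only below {self.complete_below}"
            )
        below = sum(c for v, c in self.counts.items() if v < x)
        return 100.0 * below / self.size

    def table(self) -> pd.DataFrame:
        """Histogram with percentile column (value, occurrences, percentile).

        For truncated distributions, percentiles beyond the complete range
        are left missing.
        """
        rows = []
        for v, c in sorted(self.counts.items()):
            computable = self.complete_below is None or v < self.complete_below
            rows.append(
                {
                    "value": v,
                    "occurrences": c,
                    "percentile": self.percentile(v) if computable else None,
                }
            )
        return pd.DataFrame(rows, columns=["value", "occurrences", "percentile"])


def percentile_score(dist: MetricDistribution, x: float) -> float:
    """Percentage of population values strictly below ``x``."""
    return dist.percentile(x)


def combined_score(
    percentiles: Mapping[str, float], metric_set: Sequence[str] = DEFAULT_METRICS
) -> float:
    """Sum of the percentile scores over ``metric_set`` (unrounded)."""
    missing = [m for m in metric_set if m not in percentiles]
    if missing:
        raise KeyError(f"missing percentile score(s) for metric(s): {missing}")
    return float(sum(percentiles[m] for m in metric_set))


def rank_cut_nodes(records: pd.DataFrame) -> pd.DataFrame:
    """Order ranking records by descending combined score.

    Ties on the combined score are ordered by higher normalized betweenness
    (column ``C_B_norm``, optional), then by smaller node id, so the
    priority list is a total order.  Rank positions are 1-based and ties on
    the combined score share the better position (competition ranking).
    """
    df = records.copy()
    cb = df["C_B_norm"] if "C_B_norm" in df else pd.Series(0.0, index=df.index)
    order = sorted(
        df.index,
        key=lambda i: (-df.at[i, "combined"], -cb[i], _node_key(df.at[i, "node_id"])),
    )
    df = df.loc[order].reset_index(drop=True)
    ranks, last_score, last_rank = [], None, 0
    for pos, score in enumerate(df["combined"], start=1):
        if score != last_score:
            last_rank, last_score = pos, score
        ranks.append(last_rank)
    df["rank"] = ranks
    return df


@dataclass(frozen=True)
class CorrelationReport:
    pearson: float
    spearman: float
    n: int
    degenerate: bool  # zero variance in either variable

    def as_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "spearman": self.spearman,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def correlation_report(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationReport:
    """Pearson and Spearman correlation between paired score vectors.

    Spearman uses mid-ranks for ties.  Zero variance in either variable is
    reported with a ``degenerate`` flag and NaN coefficients rather than an
    exception.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired (same length)")
    n = len(xa)
    if n < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationReport(float("nan"), float("nan"), n, degenerate=True)
    pearson = stats.pearsonr(xa, ya).statistic
    spearman = stats.spearmanr(xa, ya).statistic
    return CorrelationReport(float(pearson), float(spearman), n, degenerate=False)


def build_ranking(
    metrics: pd.DataFrame,
    metric_set: Sequence[str] = DEFAULT_METRICS,
    noise_filter: bool = False,
) -> pd.DataFrame:
    """Score and rank a cut-node metrics table.

    Parameters
    ----------
    metrics
        One row per cut node with column ``node_id``, one column per metric
        in ``metric_set`` (e.g. ``C_A``, ``C_S``, ``D``), and optionally
        ``C_B_norm`` kept as a comparison column.
    metric_set
        Metrics entering the combined score.  Percentile populations are
        global: all cut nodes across all components.
    noise_filter
        Drop rows with ``C_S == 1`` (likely enclave noise) before scoring.

    Returns
    -------
    DataFrame ordered by descending combined score with, per metric m,
    columns ``m`` (raw) and ``m_pctl``, plus ``combined`` and ``rank``.
    """
    df = metrics.copy()
    missing = [m for m in metric_set if m not in df.columns]
    if missing:
        raise KeyError(f"metrics table lacks column(s): {missing}")
    if noise_filter and "C_S" in df.columns:
        df = df[df["C_S"] != 1].reset_index(drop=True)
    if len(df) == 0:
        cols = ["node_id"]
        for m in metric_set:
            cols += [m, f"{m}_pctl"]
        return pd.DataFrame(columns=cols + ["combined", "rank"])
    for m in metric_set:
        dist = MetricDistribution.from_values(m, df[m])
        df[f"{m}_pctl"] = [dist.percentile(x) for x in df[m]]
    df["combined"] = sum(df[f"{m}_pctl"] for m in metric_set)
    return rank_cut_nodes(df)
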