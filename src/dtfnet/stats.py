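"""Group-level statistics: one-way ANOVA and Newman-Keuls post-hoc ranking.

Group differences per day are tested with the classical between/within
sums-of-squares decomposition; pairwise structure is resolved with the
step-down studentized-range (Newman-Keuls) procedure — ordered group means
are compared at the critical value q(r, df_within, alpha) for the span r of
each stretch, and a non-significant stretch is never subdivided further.

``experiment_report`` drives the full pipeline over a labelled epoch set
and emits tidy tables of group means +/- SEM, F statistics and post-hoc
pair calls per metric x band x day.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import EpochSet
from .pipeline import METRIC_NAMES, PipelineConfig, metrics_table

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairwiseDecision",
    "one_way_anova",
    "newman_keuls",
    "ExperimentReport",
    "experiment_report",
]


@dataclass
class GroupSummary:
    """Per-group value vectors for one metric on one day (one band)."""

    metric_name: str
    band_label: str
    day: int
    values_by_group: dict
    aggregation_level: str = "section"

    def validate(self) -> None:
        if len(self.values_by_group) < 2:
            raise ValueError("need at least 2 groups")
        for g, v in self.values_by_group.items():
            v = np.asarray(v, dtype=float)
            if v.size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 values")
            if not np.isfinite(v).all():
                raise ValueError(f"group {g!r} contains non-finite values")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass
class PairwiseDecision:
    group_low: str   # smaller mean
    group_high: str  # larger mean
    mean_diff: float
    span_r: int
    q_statistic: float
    q_critical: float
    p_value: float
    significant: bool


def one_way_anova(summary: GroupSummary) -> AnovaResult:
    """Classical one-way ANOVA across the summary's groups."""
    summary.validate()
    groups = [np.asarray(v, dtype=float) for v in summary.values_by_group.values()]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    ms_within = ss_within / df_within
    if ss_within == 0.0 and ss_between == 0.0:
        warnings.warn("all values identical; F defined as 0")
        return AnovaResult(0.0, df_between, df_within, 1.0, 0.0)
    if ms_within == 0.0:
        return AnovaResult(np.inf, df_between, df_within, 0.0, 0.0)
    f_stat = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), df_between, df_within, p, float(ms_within))


def newman_keuls(summary: GroupSummary, alpha: float = 0.05) -> list[PairwiseDecision]:
    """Step-down studentized-range procedure on the summary's group means.

    Groups are ordered by mean; the stretch spanning r means is tested at
    q(r, df_within, alpha); a stretch that fails is declared homogeneous and
    none of its sub-stretches are tested.  Unbalanced groups use the
    harmonic-mean sample size.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    anova = one_way_anova(summary)
    names = list(summary.values_by_group)
    means = np.array([np.mean(summary.values_by_group[g]) for g in names])
    sizes = np.array([len(summary.values_by_group[g]) for g in names], dtype=float)
    order = np.argsort(means, kind="stable")
    names = [names[i] for i in order]
    means = means[order]
    n_h = len(sizes) / np.sum(1.0 / sizes)
    if anova.ms_within == 0.0:
        # degenerate: no within-group variance; every distinct pair separates
        se = 0.0
    else:
        se = float(np.sqrt(anova.ms_within / n_h))

    k = len(names)
    decisions: dict[tuple[int, int], PairwiseDecision] = {}
    homogeneous: list[tuple[int, int]] = []

    def test(i: int, j: int) -> None:
        if j - i < 1 or (i, j) in decisions:
            return
        if any(bi <= i and j <= bj for bi, bj in homogeneous):
            return
        r = j - i + 1
        diff = means[j] - means[i]
        q_crit = float(sps.studentized_range.isf(alpha, r, anova.df_within))
        if se == 0.0:
            q_stat = np.inf if diff > 0 else 0.0
            p = 0.0 if diff > 0 else 1.0
        else:
            q_stat = diff / se
            p = float(sps.studentized_range.sf(q_stat, r, anova.df_within))
        if q_stat > q_crit:
            decisions[(i, j)] = PairwiseDecision(
                names[i], names[j], float(diff), r, float(q_stat), q_crit, p, True
            )
            test(i, j - 1)
            test(i + 1, j)
        else:
            homogeneous.append((i, j))
            decisions[(i, j)] = PairwiseDecision(
                names[i], names[j], float(diff), r, float(q_stat), q_crit, p, False
            )

    test(0, k - 1)
    results = []
    for i, j in itertools.combinations(range(k), 2):
        if (i, j) in decisions:
            results.append(decisions[(i, j)])
        else:
            # untested because it sits inside a homogeneous stretch
            r = j - i + 1
            diff = means[j] - means[i]
            q_crit = float(sps.studentized_range.isf(alpha, r, anova.df_within))
            q_stat = diff / se if se > 0 else 0.0
            results.append(
                PairwiseDecision(
                    names[i], names[j], float(diff), r, float(q_stat), q_crit, 1.0, False
                )
            )
    return results


# ---------------------------------------------------------------------------
# Full experiment report
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """Outputs of the full pipeline on one labelled epoch set."""

    order_p: int
    thresholds: dict
    metrics: pd.DataFrame      # per epoch (or per subject) x band metric values
    group_stats: pd.DataFrame  # long: metric, band, day, group, mean, sem, n
    anova: pd.DataFrame        # metric, band, day, F, dfs, p, sig_pairs
    alpha: float = 0.05
    aggregation_level: str = "section"

    def is_pair_significant(
        self, metric: str, band: str, day: int, group_a: str, group_b: str
    ) -> bool:
        row = self.anova[
            (self.anova["metric"] == metric)
            & (self.anova["band"] == band)
            & (self.anova["day"] == day)
        ]
        if row.empty:
            raise KeyError(f"no ANOVA row for {metric}/{band}/day {day}")
        pairs = row.iloc[0]["sig_pairs"]
        return any({group_a, group_b} == {p[0], p[1]} for p in pairs)

    def group_mean(self, metric: str, band: str, day: int, group: str) -> float:
        row = self.group_stats[
            (self.group_stats["metric"] == metric)
            & (self.group_stats["band"] == band)
            & (self.group_stats["day"] == day)
            & (self.group_stats["group"] == group)
        ]
        return float(row.iloc[0]["mean"])


def _check_cells(labels: pd.DataFrame) -> tuple[list, list]:
    groups = sorted(str(g) for g in labels["group"].unique())
    days = sorted(int(d) for d in labels["day"].unique())
    present = {
        (str(g), int(d))
        for g, d in labels[["group", "day"]].drop_duplicates().itertuples(index=False)
    }
    missing = [(g, d) for g in groups for d in days if (g, d) not in present]
    if missing:
        raise ValueError(f"missing group x day cells: {missing}")
    return groups, days


def experiment_report(epochs: EpochSet, config: PipelineConfig | None = None) -> ExperimentReport:
    """Run preprocessed epochs through MVAR/DTF/network metrics and compare
    the groups per day with one-way ANOVA + Newman-Keuls.

    ``config.aggregation_level`` chooses the unit of analysis: "section"
    (every epoch is an observation, the published df) or "subject" (sections
    are averaged within subject first, the valid unit when subjects carry
    their own coupling variability).
    """
    config = config or PipelineConfig()
    groups, days = _check_cells(epochs.labels)
    per_epoch, thresholds, order = metrics_table(epochs, config)

    if config.aggregation_level == "subject":
        agg = (
            per_epoch.groupby(["group", "day", "subject", "band"], as_index=False)[
                list(METRIC_NAMES)
            ].mean()
        )
    elif config.aggregation_level == "section":
        agg = per_epoch
    else:
        raise ValueError(f"unknown aggregation_level {config.aggregation_level!r}")

    stat_rows, anova_rows = [], []
    for metric in METRIC_NAMES:
        for band in config.bands:
            for day in days:
                sub = agg[(agg["band"] == band) & (agg["day"] == day)]
                values = {
                    g: sub.loc[sub["group"] == g, metric].to_numpy() for g in groups
                }
                summary = GroupSummary(metric, band, day, values, config.aggregation_level)
                res = one_way_anova(summary)
                pairs = newman_keuls(summary, config.alpha)
                sig = [
                    (p.group_low, p.group_high)
                    for p in pairs
                    if p.significant and res.p_value < config.alpha
                ]
                for g in groups:
                    v = values[g]
                    stat_rows.append(
                        (metric, band, day, g, v.mean(), v.std(ddof=1) / np.sqrt(v.size), v.size)
                    )
                anova_rows.append(
                    (metric, band, day, res.F, res.df_between, res.df_within, res.p_value, sig)
                )

    group_stats = pd.DataFrame(
        stat_rows, columns=["metric", "band", "day", "group", "mean", "sem", "n"]
    )
    anova_df = pd.DataFrame(
        anova_rows,
        columns=["metric", "band", "day", "F", "df_between", "df_within", "p", "sig_pairs"],
    )
    return ExperimentReport(
        order_p=order,
        thresholds=thresholds,
        metrics=agg,
        group_stats=group_stats,
        anova=anova_df,
        alpha=config.alpha,
        aggregation_level=config.aggregation_level,
    )
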