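import numpy as np
import pytest
from scipy import stats as sps

from dtfnet.pipeline import PipelineConfig
from dtfnet.stats import (
    GroupSummary,
    experiment_report,
    newman_keuls,
    one_way_anova,
)
from dtfnet.synth import ExperimentDesign, default_base_spec, simulate_experiment


def summary(**groups):
    return GroupSummary("metric", "band", 1, groups)


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        with pytest.warns(UserWarning, match="identical"):
            res = one_way_anova(summary(a=[2.0, 2.0], b=[2.0, 2.0], c=[2.0, 2.0]))
        assert res.F == 0.0
        assert res.p_value == 1.0

    def test_equal_group_means_give_zero_f(self):
        res = one_way_anova(summary(a=[1, 2, 3], b=[1, 2, 3], c=[1, 2, 3]))
        assert res.F == pytest.approx(0.0)

    def test_textbook_sums_of_squares_oracle(self):
        g1, g2, g3 = [6, 8, 4, 5, 3, 4], [8, 12, 9, 11, 6, 8], [13, 9, 11, 8, 7, 12]
        res = one_way_anova(summary(a=g1, b=g2, c=g3))
        allv = np.array(g1 + g2 + g3, dtype=float)
        ss_b = sum(6 * (np.mean(g) - allv.mean()) ** 2 for g in (g1, g2, g3))
        ss_w = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in (g1, g2, g3))
        assert res.F == pytest.approx((ss_b / 2) / (ss_w / 15), rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = {
                f"g{k}": rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(3, 30))
                for k in range(3)
            }
            res = one_way_anova(GroupSummary("m", "b", 1, groups))
            ref = sps.f_oneway(*groups.values())
            assert res.F == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova(GroupSummary("m", "b", 1, {"a": [1, 2]}))
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova(summary(a=[1.0], b=[1, 2]))
        with pytest.raises(ValueError, match="finite"):
            one_way_anova(summary(a=[1.0, np.nan], b=[1, 2]))


class TestNewmanKeuls:
    def test_identical_groups_yield_no_significant_pairs(self):
        decisions = newman_keuls(summary(a=[1, 2, 3], b=[1, 2, 3], c=[1, 2, 3]))
        assert not any(d.significant for d in decisions)

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(1)
        decisions = newman_keuls(
            summary(
                a=rng.normal(0.0, 0.01, 50),
                b=rng.normal(5.0, 0.01, 50),
                c=rng.normal(10.0, 0.01, 50),
            )
        )
        assert all(d.significant for d in decisions)
        assert len(decisions) == 3

    def test_decisions_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            groups = {
                f"g{k}": rng.normal(rng.uniform(-0.8, 0.8), 1.0, 12) for k in range(4)
            }
            s = GroupSummary("m", "b", 1, groups)
            sig_strict = {
                (d.group_low, d.group_high)
                for d in newman_keuls(s, alpha=0.01)
                if d.significant
            }
            sig_loose = {
                (d.group_low, d.group_high)
                for d in newman_keuls(s, alpha=0.05)
                if d.significant
            }
            assert sig_strict <= sig_loose

    def test_never_significant_when_t_test_p_above_half(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            groups = {
                f"g{k}": rng.normal(rng.uniform(-0.5, 0.5), 1.0, 15) for k in range(3)
            }
            s = GroupSummary("m", "b", 1, groups)
            for d in newman_keuls(s, alpha=0.05):
                if d.significant:
                    t_p = sps.ttest_ind(groups[d.group_low], groups[d.group_high]).pvalue
                    assert t_p <= 0.5

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            newman_keuls(summary(a=[1, 2], b=[3, 4]), alpha=1.5)


def test_anova_null_rejection_rate_is_calibrated():
    """Under a common generator, the 5 % level rejects ~5 % of the time."""
    rng = np.random.default_rng(4)
    rejections = 0
    n_sims = 1000
    for _ in range(n_sims):
        s = GroupSummary(
            "m", "b", 1, {g: rng.standard_normal(20) for g in ("x", "y", "z")}
        )
        rejections += one_way_anova(s).p_value < 0.05
    assert 0.03 <= rejections / n_sims <= 0.07


@pytest.fixture(scope="module")
def tiny_report():
    base = default_base_spec(4)
    design = ExperimentDesign(
        days=(1,), subjects_per_group=2, sections_per_day=2,
        epoch_length_s=1.5, seed=3,
    )
    epochs = simulate_experiment(design, base)
    config = PipelineConfig(order=4, grid="bands")
    return experiment_report(epochs, config), epochs, config


class TestExperimentReport:
    def test_report_row_counts(self, tiny_report):
        report, _, config = tiny_report
        n_metrics, n_bands, n_days = 4, len(config.bands), 1
        assert len(report.anova) == n_metrics * n_bands * n_days
        assert len(report.group_stats) == n_metrics * n_bands * n_days * 3

    def test_report_is_deterministic(self, tiny_report):
        report, epochs, config = tiny_report
        again = experiment_report(epochs, config)
        assert report.anova.drop(columns="sig_pairs").equals(
            again.anova.drop(columns="sig_pairs")
        )
        assert report.group_stats.equals(again.group_stats)

    def test_missing_cells_are_reported(self):
        base = default_base_spec(4)
        design = ExperimentDesign(
            days=(1, 2), subjects_per_group=1, sections_per_day=1,
            epoch_length_s=1.0, seed=8,
        )
        epochs = simulate_experiment(design, base)
        keep = ~((epochs.labels["group"] == "PRO") & (epochs.labels["day"] == 1))
        broken = type(epochs)(
            epochs.data[keep.to_numpy()],
            epochs.sampling_rate_hz,
            epochs.labels.loc[keep].reset_index(drop=True),
            epochs.event_index,
        )
        with pytest.raises(ValueError, match=r"\('PRO', 1\)"):
            experiment_report(broken, PipelineConfig(order=4, grid="bands"))

    def test_subject_aggregation_reduces_observations(self, tiny_report):
        _, epochs, _ = tiny_report
        config = PipelineConfig(order=4, grid="bands", aggregation_level="subject")
        report = experiment_report(epochs, config)
        # 2 subjects per group -> n = 2 per group in the summaries
        assert (report.group_stats["n"] == 2).all()
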