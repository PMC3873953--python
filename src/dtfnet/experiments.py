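"""Canonical synthetic-study runs used by the analysis scripts and tests.

The study emulates the in-vivo design: three dose groups (control, low-dose
"pro", high-dose "PRO"), six subjects per group, event-aligned 3 s epochs at
2 kHz from 16 prefrontal electrodes, analysed on recording days 1-3 after
anesthesia.  Ten sections per subject per day give 60 sections per group per
day — the same per-day group sample the published F statistics' (2, 177)
degrees of freedom imply.  The high-dose group's directed coupling is
attenuated to 0.3x on day 1 and 0.6x on day 2 and fully recovered on day 3;
the other groups are never attenuated.

Group comparisons aggregate sections within subject before testing
(n = 6 per group): subjects carry persistent coupling jitter, so sections
from one subject are not independent observations and section-level tests
would be pseudoreplicated.  Section-level aggregation remains available via
``PipelineConfig`` for single-subject analyses.
"""

from __future__ import annotations

from .pipeline import METRIC_NAMES, PipelineConfig
from .stats import ExperimentReport, experiment_report
from .synth import (
    CouplingSpec,
    ExperimentDesign,
    default_attenuation,
    default_base_spec,
    simulate_experiment,
)

__all__ = [
    "STUDY_DAYS",
    "study_design",
    "run_study",
    "pro_control_decrease_significant",
    "any_pro_control_significant",
    "headline_pattern_holds",
]

STUDY_DAYS = (1, 2, 3)


def study_design(
    seed: int,
    attenuated: bool = True,
    days: tuple = STUDY_DAYS,
    subjects_per_group: int = 6,
    sections_per_day: int = 10,
    subject_jitter: float = 0.1,
) -> ExperimentDesign:
    """The study's group x day x subject x section layout for one master seed."""
    attenuation = default_attenuation if attenuated else (lambda group, day: 1.0)
    return ExperimentDesign(
        days=days,
        subjects_per_group=subjects_per_group,
        sections_per_day=sections_per_day,
        attenuation=attenuation,
        seed=seed,
        subject_jitter=subject_jitter,
    )


def run_study(
    seed: int,
    n_channels: int = 16,
    attenuated: bool = True,
    aggregation_level: str = "subject",
    base_spec: CouplingSpec | None = None,
    **design_kwargs,
) -> ExperimentReport:
    """Simulate one full study and push it through the connectivity pipeline.

    The MVAR order is BIC-selected on the first epoch (candidates 1..8) and
    shared across epochs so all models are comparable.
    """
    base = base_spec if base_spec is not None else default_base_spec(n_channels)
    design = study_design(seed, attenuated=attenuated, **design_kwargs)
    epochs = simulate_experiment(design, base)
    config = PipelineConfig(
        order="auto", p_max=8, grid="bands", aggregation_level=aggregation_level
    )
    return experiment_report(epochs, config)


def pro_control_decrease_significant(
    report: ExperimentReport, metric: str, band: str, day: int
) -> bool:
    """True iff the high-dose group sits significantly *below* control:
    ANOVA p < alpha and the Newman-Keuls PRO-vs-control pair separates."""
    return report.is_pair_significant(metric, band, day, "PRO", "control") and (
        report.group_mean(metric, band, day, "PRO")
        < report.group_mean(metric, band, day, "control")
    )


def any_pro_control_significant(report: ExperimentReport, band: str, day: int) -> bool:
    """Any of the four connectivity metrics separating PRO from control."""
    return any(
        report.is_pair_significant(metric, band, day, "PRO", "control")
        for metric in METRIC_NAMES
    )


def headline_pattern_holds(report: ExperimentReport, band: str = "gamma") -> bool:
    """The published qualitative result: every connectivity metric shows a
    significant PRO-vs-control decrease on days 1 and 2 and no
    PRO-vs-control difference on day 3 (recovery)."""
    for day in (1, 2):
        if not all(
            pro_control_decrease_significant(report, metric, band, day)
            for metric in METRIC_NAMES
        ):
            return False
    return not any_pro_control_significant(report, band, 3)
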