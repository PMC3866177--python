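"""Parameter estimation from summary statistics and individual-level records.

Progression rates come from longitudinal incidence (incidence fraction over a
follow-up horizon), transition times from the weight (adults, kg) or BMI
(children, kg/m^2) change needed relative to the change behavioral treatment
delivers per year, and weight-loss-engagement proportions from survey-style
individual records: a person counts as engaging in weight-loss behaviors only
if they report being on a weight-loss/low-calorie diet AND accumulate at least
250 minutes per week of moderate plus vigorous recreational activity.

A seeded synthetic-record generator emulates the survey records so the
estimation pipeline runs without any external data files.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

WEEKS_PER_YEAR = 52.0
WEEKS_PER_MONTH = 4.333
#: Weekly moderate+vigorous activity minutes required to count as engaging in
#: physical activity for weight loss.
ACTIVITY_THRESHOLD_MIN_PER_WEEK = 250.0
#: Expected adult weight loss (kg) per year of behavioral treatment.
DEFAULT_EXPECTED_LOSS_KG_PER_YEAR = 5.5
#: Expected child BMI decrease per year of behavioral treatment.
DEFAULT_EXPECTED_BMI_DECREASE_PER_YEAR = 1.7

GROUPS = ("ow_adult", "ob_adult", "ow_child", "ob_child")


@dataclass(frozen=True)
class IndividualRecord:
    """One survey-style respondent.

    Activity fields follow the questionnaire convention: typical days per week
    and minutes on a typical day, separately for moderate and vigorous
    recreational activity.
    """

    group: str
    on_weight_loss_diet: bool
    moderate_days_per_week: int
    moderate_minutes_per_day: float
    vigorous_days_per_week: int
    vigorous_minutes_per_day: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("moderate_days_per_week", "vigorous_days_per_week"):
            d = getattr(self, name)
            if not 0 <= d <= 7:
                raise ValueError(f"{name} must be in [0, 7], got {d}")
        for name in ("moderate_minutes_per_day", "vigorous_minutes_per_day"):
            m = getattr(self, name)
            if m < 0:
                raise ValueError(f"{name} must be >= 0, got {m}")

    @property
    def weekly_activity_minutes(self) -> float:
        """Days/week times minutes/day, summed over moderate and vigorous."""
        return (
            self.moderate_days_per_week * self.moderate_minutes_per_day
            + self.vigorous_days_per_week * self.vigorous_minutes_per_day
        )

    @property
    def engages_in_weight_loss(self) -> bool:
        """Dieting AND at least 250 active minutes per week."""
        return (
            self.on_weight_loss_diet
            and self.weekly_activity_minutes >= ACTIVITY_THRESHOLD_MIN_PER_WEEK
        )


@dataclass(frozen=True)
class EstimationSummaries:
    """Published summary inputs for rate and transition-time estimation."""

    incidence_fraction: float = 0.0
    incidence_horizon: float = 1.0
    mean_excess_weight_kg: float = 0.0
    expected_loss_kg_per_year: float = DEFAULT_EXPECTED_LOSS_KG_PER_YEAR
    mean_bmi_decrease_needed: float = 0.0
    expected_bmi_decrease_per_year: float = DEFAULT_EXPECTED_BMI_DECREASE_PER_YEAR


def progression_rate(incidence_fraction: float, horizon_weeks: float) -> float:
    """Per-week progression rate from a cohort incidence over a horizon.

    E.g. a 16% four-year adult obesity incidence gives
    0.16 / (4 * 52) = 0.000769 week^-1; a 4.3% 28-month child incidence gives
    0.043 / (28 * 4.333) = 0.000354 week^-1.
    """
    if not (0 <= incidence_fraction < 1):
        raise ValueError(f"incidence_fraction must be in [0, 1), got {incidence_fraction}")
    if horizon_weeks <= 0:
        raise ValueError(f"horizon_weeks must be > 0, got {horizon_weeks}")
    return incidence_fraction / horizon_weeks


def adult_transition_time(
    mean_excess_weight_kg: float,
    expected_loss_kg_per_year: float = DEFAULT_EXPECTED_LOSS_KG_PER_YEAR,
) -> float:
    """Average weeks for an engaged adult to drop one weight category.

    Scales the one-year treatment horizon by the ratio of weight to lose to
    the expected yearly loss.
    """
    if mean_excess_weight_kg <= 0:
        raise ValueError(f"mean_excess_weight_kg must be > 0, got {mean_excess_weight_kg}")
    if expected_loss_kg_per_year <= 0:
        raise ValueError(
            f"expected_loss_kg_per_year must be > 0, got {expected_loss_kg_per_year}"
        )
    return mean_excess_weight_kg / expected_loss_kg_per_year * WEEKS_PER_YEAR


def child_transition_time(
    mean_bmi_decrease_needed: float,
    expected_bmi_decrease_per_year: float = DEFAULT_EXPECTED_BMI_DECREASE_PER_YEAR,
) -> float:
    """Average weeks for an engaged child to drop one BMI-percentile category.

    Consumes an already growth-chart-adjusted summary BMI decrease.
    """
    if mean_bmi_decrease_needed <= 0:
        raise ValueError(
            f"mean_bmi_decrease_needed must be > 0, got {mean_bmi_decrease_needed}"
        )
    if expected_bmi_decrease_per_year <= 0:
        raise ValueError(
            f"expected_bmi_decrease_per_year must be > 0, got {expected_bmi_decrease_per_year}"
        )
    return mean_bmi_decrease_needed / expected_bmi_decrease_per_year * WEEKS_PER_YEAR


def weight_loss_engagement(records: Iterable[IndividualRecord], group: str) -> float:
    """Fraction of the group's records engaging in weight-loss behaviors."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    in_group = [r for r in records if r.group == group]
    if not in_group:
        raise ValueError(f"no records for group {group!r}; proportion undefined")
    return sum(r.engages_in_weight_loss for r in in_group) / len(in_group)


def synthesize_records(
    n_per_group: int,
    engagement_target: float,
    seed: int,
    groups: Sequence[str] = GROUPS,
) -> List[IndividualRecord]:
    """Generate survey-like records with a known engagement proportion.

    Per group, exactly floor(engagement_target * n_per_group) records qualify
    (diet plus >= 250 weekly active minutes); the remainder fail at least one
    criterion. Deterministic for a given seed.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if not 0 <= engagement_target <= 1:
        raise ValueError(f"engagement_target must be in [0, 1], got {engagement_target}")
    rng = np.random.default_rng(seed)
    records: List[IndividualRecord] = []
    for group in groups:
        n_engaged = int(math.floor(engagement_target * n_per_group + 1e-9))
        for i in range(n_per_group):
            engaged = i < n_engaged
            if engaged:
                # Moderate activity alone clears 250 min/week (>= 4*70) with
                # diet on; vigorous minutes only add headroom.
                mod_days = int(rng.integers(4, 8))
                mod_min = float(rng.integers(70, 121))
                vig_days = int(rng.integers(0, 4))
                vig_min = float(rng.integers(20, 61))
                diet = True
            else:
                # Fail the diet criterion, the activity criterion, or both.
                mode = rng.integers(0, 3)
                diet = mode == 1
                mod_days = int(rng.integers(0, 4))
                mod_min = float(rng.integers(0, 40))
                vig_days = int(rng.integers(0, 2))
                vig_min = float(rng.integers(0, 40))
                if diet and mod_days * mod_min + vig_days * vig_min >= ACTIVITY_THRESHOLD_MIN_PER_WEEK:
                    mod_min = 0.0
                    vig_min = 0.0
            rec = IndividualRecord(
                group=group,
                on_weight_loss_diet=bool(diet),
                moderate_days_per_week=mod_days,
                moderate_minutes_per_day=mod_min,
                vigorous_days_per_week=vig_days,
                vigorous_minutes_per_day=vig_min,
            )
            if engaged and not rec.engages_in_weight_loss:
                raise AssertionError("generator produced a non-qualifying engaged record")
            records.append(rec)
        rng.shuffle(records[-n_per_group:])  # order carries no information
    return records


def records_to_dataframe(records: Iterable[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def records_from_csv(path: Union[str, Path]) -> List[IndividualRecord]:
    """Read records from CSV with the IndividualRecord column schema."""
    df = pd.read_csv(path)
    expected = [f.name for f in fields(IndividualRecord)]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return [
        IndividualRecord(
            group=str(row.group),
            on_weight_loss_diet=bool(row.on_weight_loss_diet),
            moderate_days_per_week=int(row.moderate_days_per_week),
            moderate_minutes_per_day=float(row.moderate_minutes_per_day),
            vigorous_days_per_week=int(row.vigorous_days_per_week),
            vigorous_minutes_per_day=float(row.vigorous_minutes_per_day),
        )
        for row in df.itertuples(index=False)
    ]


def estimate_engagement_params(records: Iterable[IndividualRecord]) -> Dict[str, float]:
    """Engagement proportions per stock, as a model-config params fragment."""
    records = list(records)
    return {
        "rho_awl": weight_loss_engagement(records, "ow_adult"),
        "eps_awl": weight_loss_engagement(records, "ob_adult"),
        "rho_cwl": weight_loss_engagement(records, "ow_child"),
        "eps_cwl": weight_loss_engagement(records, "ob_child"),
    }
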