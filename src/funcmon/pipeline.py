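"""End-to-end monitoring pipeline: events + IMU + assessments -> monthly reports.

Glues the three components together over the assessment calendar:

1. validate the event stream against the layout and segment it into days;
2. component 1: predict per-window TUG category / SPPB from the IMU,
   majority-aggregate per period, fall back to the assessment records
   where IMU data is missing, and flag qualifier changes;
3. component 2: daily meal-preparation minutes from kitchen sensors,
   compared per period against a 3-month lookback reference (the
   component's stated capability is catching a 5% weight change within
   3 months, which a strictly month-over-month comparison would miss);
4. component 3: day-by-day probability-map classification against the
   adaptive 7-day baseline plus the transition-graph activity trend,
   combined into f_env per period;
5. fuse available component flags into one alarm per period pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import environment as env
from .activities import (
    AmplitudeThresholdPredictor,
    PeriodScores,
    ScorePredictor,
    aggregate_interval,
    extract_features,
    detect_change_c1,
)
from .core import (
    AssessmentRecord,
    ComponentOutput,
    HouseholdLayout,
    ImuWindow,
    SensorKind,
    segment_days,
    validate_events,
)
from .fusion import AvailabilityMask, MonthlyReport, build_report
from .icf import IcfLinkTable, tug_seconds_to_category
from .meals import MealPrepParams, build_meal_profile, detect_change_c2, meal_prep_time_daily


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and per-resident settings."""

    participant: str = "participant"
    group: Optional[str] = None  # control | intervention | None
    prepares_meals: bool = True
    seed: int = 0
    alpha: float = 0.05
    n_resamples: int = 1000
    env_threshold: float = env.DEFAULT_ENV_THRESHOLD
    max_gap_s: float = 300.0
    pir_debounce_s: float = 2.0
    lookback_months: int = 3
    slope_min_days: int = 30
    meal_params: MealPrepParams = field(default_factory=MealPrepParams)
    link_table: IcfLinkTable = field(default_factory=IcfLinkTable)
    normalization: str = "per_map"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "meal_params" in d:
            d["meal_params"] = MealPrepParams(**d["meal_params"])
        if "link_table" in d:
            d["link_table"] = IcfLinkTable.from_dict(d["link_table"])
        return cls(**d)


@dataclass
class PipelineResult:
    reports: "list[MonthlyReport]"
    diagnostics: dict


def _periods_from_assessments(
    assessments: Sequence[AssessmentRecord],
) -> "list[tuple[date, date]]":
    """Half-open [start, end) day ranges between consecutive visits."""
    if len(assessments) < 2:
        raise ValueError("need at least two assessment visits to define periods")
    dates = [a.date for a in sorted(assessments, key=lambda a: a.time_point)]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("assessment dates must be strictly increasing")
    return list(zip(dates, dates[1:]))


def _c1_period_scores(
    windows: Sequence[ImuWindow],
    assessment: AssessmentRecord,
    predictor: ScorePredictor,
    link: IcfLinkTable,
) -> PeriodScores:
    """Aggregate IMU predictions for one period, assessment as fallback."""
    if windows:
        feats = [extract_features(w) for w in windows]
        tug_preds = list(predictor.predict_tug_category(feats))
        sppb_preds = list(predictor.predict_sppb(feats))
        tug = aggregate_interval(tug_preds, len(tug_preds), worse=max)[0]
        sppb = aggregate_interval(sppb_preds, len(sppb_preds), worse=min)[0]
        return PeriodScores(sppb=sppb, tug_category=tug)
    tug = (
        tug_seconds_to_category(assessment.tug_seconds, link.tug_bands)
        if assessment.tug_seconds is not None
        else None
    )
    return PeriodScores(sppb=assessment.sppb, tug_category=tug)


def run_pipeline(
    events: pd.DataFrame,
    imu_windows: Sequence[ImuWindow],
    assessments: Sequence[AssessmentRecord],
    layout: HouseholdLayout,
    config: Optional[RunConfig] = None,
    predictor: Optional[ScorePredictor] = None,
) -> PipelineResult:
    config = config or RunConfig()
    predictor = predictor or AmplitudeThresholdPredictor()
    rng = np.random.default_rng(config.seed)
    link = config.link_table

    clean, report = validate_events(
        events, layout, pir_debounce_s=config.pir_debounce_s
    )
    days = segment_days(clean)
    day_dates = sorted(days)
    periods = _periods_from_assessments(assessments)
    n_periods = len(periods)

    def period_of(d: date) -> Optional[int]:
        for k, (start, end) in enumerate(periods):
            if start <= d < end:
                return k
        return None

    # ----- component 1 -----
    windows_by_period: "list[list[ImuWindow]]" = [[] for _ in range(n_periods)]
    for w in imu_windows:
        k = period_of(w.start.date())
        if k is not None:
            windows_by_period[k].append(w)
    ordered = sorted(assessments, key=lambda a: a.time_point)
    scores = [
        _c1_period_scores(windows_by_period[k], ordered[k], predictor, link)
        for k in range(n_periods)
    ]
    c1_outputs = [
        detect_change_c1(scores[k], scores[k + 1], link, period=(k, k + 1))
        for k in range(n_periods - 1)
    ]

    # ----- component 2 -----
    kitchen = [
        sid
        for sid in layout.sensors_in_room("kitchen")
        if layout.sensors[sid].kind in (SensorKind.POWER, SensorKind.PIR, SensorKind.DOOR_CONTACT)
    ]
    c2_outputs: "list[ComponentOutput]" = []
    if config.prepares_meals and kitchen:
        daily_min = {
            d: meal_prep_time_daily(days[d], kitchen, config.meal_params)
            for d in day_dates
        }
        period_of_day = {d: period_of(d) for d in day_dates if period_of(d) is not None}
        profile = build_meal_profile(
            {d: m for d, m in daily_min.items() if d in period_of_day}, period_of_day
        )
        for k in range(n_periods - 1):
            ref = max(0, k + 1 - config.lookback_months)
            out = detect_change_c2(profile, (ref, k + 1), config.meal_params)
            c2_outputs.append(
                ComponentOutput(
                    component=2,
                    flag=out.flag,
                    icf_items=out.icf_items,
                    direction=out.direction,
                    period=(k, k + 1),
                    available=out.available,
                )
            )
    else:
        c2_outputs = [
            ComponentOutput(component=2, flag=0, period=(k, k + 1), available=False)
            for k in range(n_periods - 1)
        ]

    # ----- component 3 -----
    maps = {
        d: env.build_probability_map(days[d], layout.sensor_ids, config.normalization)
        for d in day_dates
    }
    graphs = {
        d: env.build_transition_graph(days[d], layout, config.max_gap_s) for d in day_dates
    }
    activity = {d: env.total_activity(graphs[d]) for d in day_dates}

    init_days = day_dates[: env.BASELINE_WINDOW]
    classifications: dict = {}
    if len(init_days) >= env.BASELINE_WINDOW:
        baseline = env.BaselineMap.from_days([maps[d] for d in init_days])
        for d in day_dates[env.BASELINE_WINDOW :]:
            cls = env.classify_day(
                maps[d], baseline, config.alpha, config.n_resamples, rng
            )
            classifications[d] = cls
            baseline = env.update_baseline(baseline, maps[d], cls)

    baseline_activity = float(np.mean([activity[d] for d in init_days])) if init_days else 0.0
    start0 = periods[0][0]
    diff_x: "list[float]" = []
    diffs: "list[float]" = []
    if baseline_activity > 0:
        for d in day_dates:
            diff_x.append((d - start0).days)
            diffs.append(env.percent_difference(activity[d], baseline_activity))

    c3_outputs = []
    for k in range(n_periods - 1):
        start, end = periods[k + 1]
        p = (end - start).days
        c = sum(
            1
            for d, cls in classifications.items()
            if start <= d < end and cls.is_abnormal
        )
        upto = [(x, y) for x, y in zip(diff_x, diffs) if x < (end - start0).days]
        s = env.slope_for_period(
            [x for x, _ in upto],
            [y for _, y in upto],
            group=config.group,
            min_days=config.slope_min_days,
        )
        trend = env.EnvTrend(
            slope=s,
            abnormal_days=c,
            period_days=p,
            threshold=config.env_threshold,
            percent_diffs=tuple(y for _, y in upto),
            x_days=tuple(x for x, _ in upto),
        )
        c3_outputs.append(env.detect_change_c3(trend, period=(k, k + 1)))

    mask = AvailabilityMask(
        components=frozenset({1, 3} | ({2} if config.prepares_meals and kitchen else set()))
    )
    outputs_by_period = [
        {1: c1_outputs[k], 2: c2_outputs[k], 3: c3_outputs[k]}
        for k in range(n_periods - 1)
    ]
    reports = build_report(outputs_by_period, mask, participant=config.participant)
    diagnostics = {
        "validation": {
            "n_input": report.n_input,
            "n_kept": report.n_kept,
            "n_rejected": report.n_rejected,
            "n_deduplicated": report.n_deduplicated,
            "reasons": dict(report.reasons),
        },
        "n_days": len(day_dates),
        "n_abnormal_days": sum(c.is_abnormal for c in classifications.values()),
        "baseline_activity": baseline_activity,
        "period_scores": [(s.sppb, s.tug_category) for s in scores],
    }
    return PipelineResult(reports=reports, diagnostics=diagnostics)
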