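"""Cohort processing pipeline and the statistical analysis model.

Two layers live here:

* the *processing* layer turns raw trials into per-participant scalar
  variables — calibrate from the standing trial, track and decompose joint
  angles per walking trial, time-normalise, average the trials, detect
  events, extract the six dynamic variables, measure the subtalar-neutral
  standing angle and run the pass-through comparison;
* the *analysis* layer is a statsmodels-style pair: :class:`CohortAnalysis`
  is built from a variables table plus deformity profiles, and its
  :meth:`~CohortAnalysis.fit` returns :class:`CohortResults` carrying the
  full comparison/correlation grid, cohort summaries and a ``summary()``
  table.

The comparison grid mirrors the study design: ankle equinus vs none (three
rearfoot variables), limited vs free hallux dorsiflexion (two variables),
first-ray three-group (two variables), forefoot three-group (mid-stance
rearfoot eversion), and the rearfoot-varus comparison which is reported as
skipped whenever the comparator group is too small — with ~97 % prevalence
it essentially always is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deformity import (ClassificationThresholds, DeformityProfile, StnResult,
                        StnSummary, classify_deformities, cohort_stn_summary,
                        deformity_count_histogram, deformity_prevalence,
                        stn_passthrough)
from .errors import ContractError, UndefinedCorrelationError
from .events import (GaitEvents, GaitVariables, detect_heel_lift, detect_stance,
                     extract_variables)
from .io_formats import (ManifestEntry, StaticAssessment, read_cohort_manifest,
                         read_marker_trial, write_json_report)
from .kinematics import (InterSegmentAngleSeries, SegmentCalibration,
                         calibrate_segments, compute_joint_angles,
                         mean_across_trials)
from .stats import (ComparisonResult, CorrelationResult, GroupSummary,
                    StatsConfig, compare_three_groups, compare_two_groups,
                    correlate)
from .synthetic import SyntheticParticipant

log = logging.getLogger(__name__)

STATIC_COLUMNS = ("ncsp_deg", "rcsp_deg", "ankle_dorsiflexion_deg",
                  "first_mpj_dorsiflexion_deg", "fpi")

#: (comparison name, grouping, dynamic variables compared across its groups)
COMPARISON_GRID: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("rearfoot_varus", "two:rearfoot_varus",
     ("peak_rearfoot_eversion_midstance",)),
    ("ankle_equinus", "two:ankle_equinus",
     ("peak_rearfoot_dorsiflexion_midstance",
      "peak_rearfoot_eversion_midstance",
      "rearfoot_sagittal_at_heel_lift")),
    ("hallux_limited", "two:hallux_limited",
     ("peak_hallux_dorsiflexion_propulsion",
      "peak_rearfoot_eversion_propulsion")),
    ("first_ray", "three:first_ray",
     ("peak_rearfoot_eversion_midstance",
      "peak_hallux_dorsiflexion_propulsion")),
    ("forefoot", "three:forefoot",
     ("peak_rearfoot_eversion_midstance",)),
)

#: (static variable, dynamic variable) pairs for the correlation analysis.
CORRELATION_GRID: tuple[tuple[str, str], ...] = (
    ("ncsp_deg", "peak_rearfoot_eversion_midstance"),
    ("ankle_dorsiflexion_deg", "peak_rearfoot_dorsiflexion_midstance"),
    ("ankle_dorsiflexion_deg", "peak_rearfoot_eversion_midstance"),
    ("ankle_dorsiflexion_deg", "rearfoot_sagittal_range_midstance"),
    ("first_mpj_dorsiflexion_deg", "peak_hallux_dorsiflexion_propulsion"),
    ("first_mpj_dorsiflexion_deg", "peak_rearfoot_eversion_propulsion"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Processing conventions; all defaults documented in the methods note."""

    filter_cutoff_hz: float | None = 6.0
    filter_order: int = 4
    force_threshold_n: float = 20.0
    min_stance_s: float = 0.2
    assumed_stance_fraction: float = 0.62  # cycle = stance / this
    midstance_start_pct: float = 15.0      # foot-flat proxy, % of stance
    heel_lift_search_start_pct: float = 40.0
    heel_lift_sustain_pct: float = 5.0
    heel_lift_fallback_pct: float = 60.0
    stn_window: str = "stance"
    stn_tolerance_deg: float = 1e-9


@dataclass
class ProcessedTrial:
    cycle: InterSegmentAngleSeries
    stance: InterSegmentAngleSeries
    stance_duration_s: float


@dataclass
class ParticipantResult:
    participant_id: str
    static: StaticAssessment
    profile: DeformityProfile
    variables: GaitVariables
    events: GaitEvents
    stn_angle_deg: float
    stn: StnResult
    mean_cycle: InterSegmentAngleSeries
    mean_stance: InterSegmentAngleSeries
    n_trials: int


def process_walking_trial(trial, calibration: SegmentCalibration,
                          config: PipelineConfig = PipelineConfig()
                          ) -> ProcessedTrial:
    """One walking trial -> cycle- and stance-normalised angle curves."""
    if trial.force is None:
        raise ContractError(f"trial {trial.trial_id!r} has no force data")
    hs, to = detect_stance(trial.force, trial.force_rate_hz,
                           config.force_threshold_n, config.min_stance_s)
    series = compute_joint_angles(trial, calibration,
                                  cutoff_hz=config.filter_cutoff_hz,
                                  filter_order=config.filter_order)
    cycle_s = (to - hs) / config.assumed_stance_fraction
    cycle = series.normalized(hs, hs + cycle_s, basis="cycle")
    stance = series.normalized(hs, to, basis="stance")
    return ProcessedTrial(cycle=cycle, stance=stance, stance_duration_s=to - hs)


def stn_neutral_angle(stn_trial, calibration: SegmentCalibration,
                      config: PipelineConfig = PipelineConfig()) -> float:
    """Frontal rearfoot angle (deg) of the subtalar-neutral standing trial."""
    series = compute_joint_angles(stn_trial, calibration,
                                  cutoff_hz=config.filter_cutoff_hz,
                                  filter_order=config.filter_order)
    return float(np.nanmean(series.curve("rearfoot", "frontal")))


def process_participant(
    participant_id: str,
    static: StaticAssessment,
    standing, stn_trial, walking_trials: Sequence,
    config: PipelineConfig = PipelineConfig(),
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ParticipantResult:
    """Full per-participant pipeline: trials -> variables, STN, profile.

    The per-trial curves are averaged pointwise on the normalised bases
    (the study convention: the mean of the walking trials is derived before
    variables are read off), events are detected on the mean stance curve,
    and the six dynamic variables extracted from it.
    """
    calibration = calibrate_segments(standing)
    processed = [process_walking_trial(t, calibration, config)
                 for t in walking_trials]
    mean_cycle = mean_across_trials([p.cycle for p in processed])
    mean_stance = mean_across_trials([p.stance for p in processed])
    stance_s = float(np.mean([p.stance_duration_s for p in processed]))

    hl_pct, fallback = detect_heel_lift(
        mean_stance.curve("rearfoot", "sagittal"),
        search_start_pct=config.heel_lift_search_start_pct,
        sustain_pct=config.heel_lift_sustain_pct,
        fallback_pct=config.heel_lift_fallback_pct)
    events = GaitEvents(heel_strike_s=0.0, toe_off_s=stance_s,
                        heel_lift_pct_stance=hl_pct,
                        midstance_start_pct=config.midstance_start_pct,
                        heel_lift_fallback_used=fallback)
    variables = extract_variables(mean_stance, events)

    neutral = stn_neutral_angle(stn_trial, calibration, config)
    stn = stn_passthrough(neutral, mean_cycle.curve("rearfoot", "frontal"),
                          window=config.stn_window,
                          stance_fraction=config.assumed_stance_fraction,
                          tolerance_deg=config.stn_tolerance_deg)
    return ParticipantResult(
        participant_id=participant_id, static=static,
        profile=classify_deformities(static, thresholds),
        variables=variables, events=events,
        stn_angle_deg=neutral, stn=stn,
        mean_cycle=mean_cycle, mean_stance=mean_stance,
        n_trials=len(processed))


def process_cohort_from_manifest(
    manifest_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> list[ParticipantResult]:
    results = []
    for entry in read_cohort_manifest(manifest_path):
        standing = read_marker_trial(entry.standing_trial,
                                     kind="standing_reference")
        stn_trial = read_marker_trial(entry.stn_trial, kind="stn_standing")
        walking = [read_marker_trial(p, kind="walking")
                   for p in entry.walking_trials]
        results.append(process_participant(
            entry.participant_id, entry.static, standing, stn_trial, walking,
            config, thresholds))
    return results


def process_synthetic_cohort(
    participants: Sequence[SyntheticParticipant],
    config: PipelineConfig = PipelineConfig(),
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> list[ParticipantResult]:
    """Run the measurement pipeline on in-memory synthetic participants."""
    results = []
    for p in participants:
        if p.trials is None:
            raise ContractError(
                f"participant {p.participant_id} has no marker trials")
        results.append(process_participant(
            p.participant_id, p.static, p.standing, p.stn_trial, p.trials,
            config, thresholds))
    return results


# ---------------------------------------------------------------------------
# variables tables
# ---------------------------------------------------------------------------

def variables_frame(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """One row per participant: statics, categories and dynamic variables."""
    rows = []
    for r in results:
        row = {"participant_id": r.participant_id,
               "n_trials": r.n_trials,
               "first_ray": r.static.first_ray,
               "forefoot": r.static.forefoot}
        for col in STATIC_COLUMNS:
            row[col] = getattr(r.static, col)
        row.update(r.variables.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def truth_frame(participants: Sequence[SyntheticParticipant],
                thresholds: ClassificationThresholds = ClassificationThresholds(),
                ) -> tuple[pd.DataFrame, list[DeformityProfile], list[StnResult]]:
    """Analysis inputs straight from synthetic ground truth (no markers).

    Fast path for statistical simulations: the dynamic variables are the
    generator's true values, profiles are classified from the statics, and
    STN results come from the true curve scan.
    """
    rows, profiles, stn_results = [], [], []
    for p in participants:
        row = {"participant_id": p.participant_id,
               "n_trials": 0,
               "first_ray": p.static.first_ray,
               "forefoot": p.static.forefoot}
        for col in STATIC_COLUMNS:
            row[col] = getattr(p.static, col)
        row.update(p.true_variables.as_dict())
        rows.append(row)
        profiles.append(classify_deformities(p.static, thresholds))
        if p.true_stn_passed_stance:
            stn_results.append(StnResult(
                passed=True, crossing_time_pct=p.true_stn_timing_pct,
                closest_time_pct=p.true_stn_timing_pct))
        else:
            stn_results.append(StnResult(
                passed=False, min_difference_deg=0.0,
                closest_time_pct=p.true_stn_timing_pct))
    return pd.DataFrame(rows), profiles, stn_results


# ---------------------------------------------------------------------------
# the analysis model
# ---------------------------------------------------------------------------

@dataclass
class CohortResults:
    """Fitted cohort analysis: grids, summaries and a printable report."""

    comparisons: list[ComparisonResult]
    correlations: list[CorrelationResult]
    cohort_summary: pd.DataFrame
    deformity_counts: dict[int, int]
    prevalence: dict[str, float]
    stn_summary: StnSummary | None
    n: int

    def comparison(self, name: str, variable: str) -> ComparisonResult:
        for c in self.comparisons:
            if c.family == name and c.variable == variable:
                return c
        raise KeyError((name, variable))

    def correlation(self, static: str, dynamic: str) -> CorrelationResult:
        for c in self.correlations:
            if c.pair == (static, dynamic):
                return c
        raise KeyError((static, dynamic))

    def summary(self) -> str:
        lines = [f"Cohort analysis of {self.n} feet",
                 "=" * 34, "",
                 "Cohort summary (mean, 95% CI):"]
        for name, row in self.cohort_summary.iterrows():
            lines.append(f"  {name:38s} {row['mean']:8.2f} "
                         f"({row['ci_low']:.2f} - {row['ci_high']:.2f})")
        lines.append("")
        lines.append(f"Deformity counts (0-5): "
                     + ", ".join(f"{k}:{v}" for k, v in
                                 sorted(self.deformity_counts.items())))
        lines.append("Prevalence: "
                     + ", ".join(f"{k} {100 * v:.0f}%"
                                 for k, v in self.prevalence.items()))
        if self.stn_summary is not None:
            s = self.stn_summary
            lines.append(
                f"Subtalar neutral: {s.percent_passing:.0f}% passed through; "
                f"crossing/closest at {s.mean_timing_pct:.1f}% "
                f"({s.timing_ci95_pct[0]:.1f} - {s.timing_ci95_pct[1]:.1f}) "
                "of the gait cycle")
        lines.append("")
        lines.append("Group comparisons:")
        for c in self.comparisons:
            if c.skipped:
                lines.append(f"  {c.family:14s} {c.variable:38s} "
                             f"skipped ({c.note})")
            else:
                lines.append(f"  {c.family:14s} {c.variable:38s} "
                             f"{c.test:22s} p={c.p_value:.3f}")
        lines.append("")
        lines.append("Correlations:")
        for c in self.correlations:
            lines.append(f"  {c.pair[0]:26s} ~ {c.pair[1]:38s} "
                         f"{c.method:8s} r={c.r:+.2f} p={c.p_value:.3f}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "n": self.n,
            "comparisons": [
                {"name": c.family, "variable": c.variable, "test": c.test,
                 "statistic": c.statistic, "p_value": c.p_value,
                 "parametric": c.parametric, "skipped": c.skipped,
                 "note": c.note,
                 "groups": [{"label": g.label, "n": g.n, "mean": g.mean,
                             "ci95": g.ci95, "median": g.median}
                            for g in c.groups],
                 "posthoc": [{"pair": p.pair, "p_raw": p.p_raw,
                              "p_corrected": p.p_corrected,
                              "significant": p.significant}
                             for p in c.posthoc]}
                for c in self.comparisons],
            "correlations": [
                {"static": c.pair[0], "dynamic": c.pair[1], "method": c.method,
                 "r": c.r, "p_value": c.p_value, "n": c.n}
                for c in self.correlations],
            "cohort_summary": self.cohort_summary.to_dict(orient="index"),
            "deformity_counts": self.deformity_counts,
            "prevalence": self.prevalence,
            "stn": None if self.stn_summary is None else {
                "percent_passing": self.stn_summary.percent_passing,
                "mean_timing_pct": self.stn_summary.mean_timing_pct,
                "timing_ci95_pct": self.stn_summary.timing_ci95_pct,
                "n": self.stn_summary.n},
        }

    def save(self, out_dir: str | Path) -> None:
        """Write the JSON report and CSV summary tables."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json_report(out_dir / "stats_report.json", self.to_report())
        self.cohort_summary.to_csv(out_dir / "cohort_summary.csv")
        pd.DataFrame([
            {"comparison": c.family, "variable": c.variable, "test": c.test,
             "statistic": c.statistic, "p": c.p_value, "skipped": c.skipped,
             "note": c.note}
            for c in self.comparisons
        ]).to_csv(out_dir / "comparisons.csv", index=False)
        pd.DataFrame([
            {"static": c.pair[0], "dynamic": c.pair[1], "method": c.method,
             "r": c.r, "p": c.p_value, "n": c.n}
            for c in self.correlations
        ]).to_csv(out_dir / "correlations.csv", index=False)
        pd.DataFrame(sorted(self.deformity_counts.items()),
                     columns=["deformity_count", "n_feet"]
                     ).to_csv(out_dir / "deformity_counts.csv", index=False)
        pd.DataFrame(sorted(self.prevalence.items()),
                     columns=["deformity", "prevalence"]
                     ).to_csv(out_dir / "deformity_prevalence.csv", index=False)


class CohortAnalysis:
    """Statistical model of a processed cohort.

    Parameters
    ----------
    variables
        One row per participant with the static measures, the first-ray and
        forefoot categories and the six dynamic variables.
    profiles
        Per-participant deformity classifications (same order).
    stn_results
        Optional per-participant subtalar-neutral pass-through results.
    config
        Test configuration (alpha, minimum group size, gate policy).
    """

    def __init__(self, variables: pd.DataFrame,
                 profiles: Sequence[DeformityProfile],
                 stn_results: Sequence[StnResult] | None = None,
                 config: StatsConfig = StatsConfig()):
        if len(variables) != len(profiles):
            raise ContractError("variables and profiles must align")
        if len(variables) < 2:
            raise ContractError("cohort analysis needs >= 2 participants")
        self.variables = variables.reset_index(drop=True)
        self.profiles = list(profiles)
        self.stn_results = list(stn_results) if stn_results is not None else None
        self.config = config

    @classmethod
    def from_results(cls, results: Sequence[ParticipantResult],
                     config: StatsConfig = StatsConfig()) -> "CohortAnalysis":
        return cls(variables_frame(results), [r.profile for r in results],
                   [r.stn for r in results], config)

    @classmethod
    def from_manifest(cls, manifest_path: str | Path,
                      pipeline_config: PipelineConfig = PipelineConfig(),
                      config: StatsConfig = StatsConfig()) -> "CohortAnalysis":
        return cls.from_results(
            process_cohort_from_manifest(manifest_path, pipeline_config),
            config)

    # -- grouping helpers --------------------------------------------------

    def _two_group_mask(self, key: str) -> np.ndarray:
        return np.array([getattr(p, key) for p in self.profiles], dtype=bool)

    def fit(self) -> CohortResults:
        """Run the full comparison/correlation grid and cohort summaries."""
        df = self.variables
        comparisons: list[ComparisonResult] = []
        for name, grouping, var_names in COMPARISON_GRID:
            style, key = grouping.split(":")
            for var in var_names:
                values = df[var].to_numpy(dtype=float)
                if style == "two":
                    mask = self._two_group_mask(key)
                    if mask.all() or not mask.any():
                        result = ComparisonResult(
                            variable=var,
                            groups=[GroupSummary.from_values(key, values[mask]),
                                    GroupSummary.from_values(f"no_{key}",
                                                             values[~mask])],
                            test="none", statistic=np.nan, p_value=np.nan,
                            parametric=False, skipped=True,
                            note="insufficient comparator group")
                    else:
                        result = compare_two_groups(
                            values[mask], values[~mask],
                            labels=(key, f"no_{key}"), variable=var,
                            config=self.config)
                else:
                    groups = {
                        level: values[(df[key] == level).to_numpy()]
                        for level in (
                            ("plantarflexed", "normal", "dorsiflexed")
                            if key == "first_ray"
                            else ("varus", "normal", "valgus"))
                    }
                    empty = [k for k, v in groups.items() if v.size == 0]
                    if empty:
                        result = ComparisonResult(
                            variable=var,
                            groups=[GroupSummary.from_values(k, v)
                                    for k, v in groups.items()],
                            test="none", statistic=np.nan, p_value=np.nan,
                            parametric=False, skipped=True,
                            note=f"empty group(s): {', '.join(empty)}")
                    else:
                        result = compare_three_groups(groups, variable=var,
                                                      config=self.config)
                result.family = name
                comparisons.append(result)

        correlations: list[CorrelationResult] = []
        for static_var, dynamic_var in CORRELATION_GRID:
            try:
                correlations.append(correlate(
                    df[static_var].to_numpy(dtype=float),
                    df[dynamic_var].to_numpy(dtype=float),
                    pair=(static_var, dynamic_var), config=self.config))
            except UndefinedCorrelationError as exc:
                log.warning("correlation %s ~ %s skipped: %s",
                            static_var, dynamic_var, exc)

        summary_rows = {}
        for col in (*STATIC_COLUMNS, *GaitVariables.FIELDS):
            g = GroupSummary.from_values(col, df[col].to_numpy(dtype=float))
            summary_rows[col] = {"mean": g.mean, "ci_low": g.ci95[0],
                                 "ci_high": g.ci95[1], "n": g.n}
        cohort_summary = pd.DataFrame.from_dict(summary_rows, orient="index")

        stn_summary = (cohort_stn_summary(self.stn_results)
                       if self.stn_results else None)
        return CohortResults(
            comparisons=comparisons,
            correlations=correlations,
            cohort_summary=cohort_summary,
            deformity_counts=deformity_count_histogram(self.profiles),
            prevalence=deformity_prevalence(self.profiles),
            stn_summary=stn_summary,
            n=len(df),
        )


def run_full_analysis(variables: pd.DataFrame,
                      profiles: Sequence[DeformityProfile],
                      stn_results: Sequence[StnResult] | None = None,
                      config: StatsConfig = StatsConfig()) -> CohortResults:
    """Functional wrapper over :class:`CohortAnalysis` -> :class:`CohortResults`."""
    return CohortAnalysis(variables, profiles, stn_results, config).fit()
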