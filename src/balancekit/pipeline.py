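"""End-to-end orchestration: raw trial records to tables and PCA results.

Per-trial processing mirrors the laboratory chain: markers and force-plate
channels are low-pass filtered (4th-order 10 Hz Butterworth, zero-phase),
forces are spline-downsampled from 1 kHz to the common 100 Hz grid, COP is
computed from the downsampled record, every channel is trimmed to the
middle 10 s (platform-anchored on moving trials), joint angles are
extracted from the marker clusters and the trial is summarised by TTB-ML,
sway and discrete kinematic measures.

Cohort-level analyses follow: the 2x2 mixed ANOVA on TTB summaries, the
waveform PCA with group tests and leave-one-out surrogates per condition,
and the stepwise regression of TTB-ML mean of minima on the 12 RMS angular
velocity channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inferstats, kinem, pmpca, posture, signalio
from .kinem import JOINTS, PLANES, JointAngleTensor
from .signalio import TimeSeriesBlock
from .synthgen import SyntheticCohort, TrialData

RMS_VELOCITY_COLUMNS = [f"rmsv_{j}_{p}" for j in JOINTS for p in PLANES]


@dataclass
class TrialResult:
    angles: JointAngleTensor          # trimmed, 100 Hz
    discrete: kinem.DiscreteKinematics
    ttb: posture.TTBSummary
    sway: posture.SwaySummary
    window: signalio.TrimWindow


@dataclass
class CohortResults:
    """All per-trial and per-participant products of a cohort run."""

    manifest: pd.DataFrame
    trial_results: dict                    # (pid, condition, trial) -> TrialResult
    participant_table: pd.DataFrame        # one row per participant x condition
    averages: dict                         # condition -> {pid: JointAngleTensor}
    groups: dict = field(default_factory=dict)   # pid -> group


def process_trial(
    trial: TrialData,
    template,
    side: str = "right",
    condition: str = "static",
    cutoff: float = 10.0,
    filter_order: int = 4,
    analysis_rate: float = 100.0,
    ttb_cap: float = 10.0,
    load_threshold: float = 20.0,
) -> TrialResult:
    """Process one 15-s trial into its trimmed tensors and summaries."""
    moving = condition == "moving"
    disp = trial.platform_displacement if moving else None

    # --- kinematics: filter markers (already 100 Hz), angles, trim ---
    mblock = signalio.butterworth_lowpass(
        trial.markers.as_block(), cutoff, filter_order)
    markers_f = signalio.MarkerTrajectorySet.from_block(mblock)
    win = signalio.trim_to_middle_10s(
        markers_f.n_frames, markers_f.rate,
        platform_displacement=disp, side=side)
    angles = kinem.joint_angles(markers_f, template, side).window(
        win.start_index, win.end_index)
    velocities = kinem.angular_velocity(angles)
    discrete = kinem.discrete_measures(angles, velocities)

    # --- kinetics: filter at 1 kHz, downsample to 100 Hz, COP, TTB ---
    fblock = signalio.butterworth_lowpass(trial.forces, cutoff, filter_order)
    fblock = signalio.spline_downsample(fblock, analysis_rate)
    cop = posture.compute_cop(fblock, load_threshold=load_threshold)
    cop = cop[win.start_index : win.end_index]

    markers_w = markers_f.window(win)
    disp_w = disp[win.start_index : win.end_index] if moving else None
    boundary = posture.foot_boundary(
        markers_w, platform_displacement=disp_w)
    cop_foot = boundary.to_foot_frame(cop)
    series = posture.ttb_ml(cop_foot[:, 0], analysis_rate,
                            boundary.ml_extent, cap=ttb_cap)
    ttb = posture.ttb_summary(series)
    sway = posture.sway_summary(cop, analysis_rate)
    return TrialResult(angles, discrete, ttb, sway, win)


def analyze_cohort(cohort: SyntheticCohort, **trial_kwargs) -> CohortResults:
    """Run per-trial processing and per-participant aggregation."""
    trial_results = {}
    groups = {}
    for _, row in cohort.manifest.iterrows():
        key = (row.participant, row.condition, row.trial)
        trial_results[key] = process_trial(
            cohort.trials[key], cohort.template,
            side=row.side, condition=row.condition, **trial_kwargs)
        groups[row.participant] = row.group

    rows = []
    averages: dict = {}
    pairs = cohort.manifest[["participant", "condition"]].drop_duplicates()
    for _, pr in pairs.iterrows():
        pid, condition = pr.participant, pr.condition
        keys = [k for k in trial_results if k[0] == pid and k[1] == condition]
        res = [trial_results[k] for k in sorted(keys)]
        avg = pmpca.intra_participant_average([r.angles for r in res])
        averages.setdefault(condition, {})[pid] = avg
        rms = np.mean([r.discrete.rms_velocity for r in res], axis=0)
        row = dict(
            participant=pid, group=groups[pid], condition=condition,
            ttb_mean_min=np.mean([r.ttb.mean_of_minima for r in res]),
            ttb_abs_min=np.mean([r.ttb.absolute_minimum for r in res]),
            ttb_sd_min=np.mean([r.ttb.sd_of_minima for r in res]),
            sd_amp=np.mean([r.sway.sd_amp for r in res]),
            sway_velocity=np.mean([r.sway.sway_velocity for r in res]),
        )
        for ci, col in enumerate(RMS_VELOCITY_COLUMNS):
            row[col] = rms.ravel()[ci]
        rows.append(row)
    table = pd.DataFrame(rows)
    return CohortResults(cohort.manifest, trial_results, table, averages, groups)


TTB_MEASURES = ("ttb_mean_min", "ttb_abs_min", "ttb_sd_min")


def ttb_anova_tables(results: CohortResults) -> dict:
    """The 2x2 mixed ANOVA for each TTB summary measure."""
    out = {}
    for measure in TTB_MEASURES:
        df = results.participant_table.rename(columns={measure: "value"})
        out[measure] = inferstats.mixed_anova_2x2(
            df[["participant", "group", "condition", "value"]])
    return out


def ttb_cell_means(results: CohortResults) -> pd.DataFrame:
    """Group x condition cell means and SDs of the TTB and sway measures."""
    cols = list(TTB_MEASURES) + ["sd_amp", "sway_velocity"]
    g = results.participant_table.groupby(["group", "condition"],
                                          observed=True)[cols]
    return g.agg(["mean", "std"])


@dataclass
class ConditionPCA:
    condition: str
    participant_ids: list
    groups: np.ndarray
    params: pmpca.ZScoreParams
    result: pmpca.PCAResult
    score_tests: pd.DataFrame
    n_variables: int


def pca_analysis(results: CohortResults, condition: str,
                 variance_threshold: float = 0.90) -> ConditionPCA:
    """Waveform PCA for one condition with group tests on retained scores."""
    avg = results.averages[condition]
    pids = sorted(avg)
    groups = np.array([results.groups[p] for p in pids])
    Z, params = pmpca.assemble_and_standardize([avg[p] for p in pids])
    fit = pmpca.fit_pca(Z, variance_threshold, groups=groups)
    tests = pmpca.test_group_scores(fit, groups)
    return ConditionPCA(condition, pids, groups, params, fit, tests,
                        n_variables=params.n_variables)


def pca_surrogates(results: CohortResults, condition: str,
                   target_component: int,
                   variance_threshold: float = 0.90) -> pd.DataFrame:
    avg = results.averages[condition]
    pids = sorted(avg)
    groups = np.array([results.groups[p] for p in pids])
    return pmpca.loo_surrogate_validation(
        [avg[p] for p in pids], groups, target_component,
        variance_threshold, participant_ids=pids)


def ttb_regression(results: CohortResults, condition: str = "moving",
                   outcome: str = "ttb_mean_min",
                   p_enter: float = 0.05,
                   p_remove: float = 0.10) -> inferstats.StepwiseModel:
    """Stepwise regression of a TTB summary on the 12 RMS velocity channels."""
    sub = results.participant_table
    sub = sub[sub.condition == condition].sort_values("participant")
    return inferstats.stepwise_regression(
        sub[outcome].to_numpy(), sub[RMS_VELOCITY_COLUMNS],
        p_enter=p_enter, p_remove=p_remove)
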