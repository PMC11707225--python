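"""Synthetic single-leg balance cohorts for end-to-end pipeline testing.

The study conditions emulated here: participants stand on one leg for 15-s
trials, three trials per participant and condition, on a static platform or
on one oscillating mediolaterally as a 1.6 Hz sinusoid with 20 mm
peak-to-peak displacement. Two groups of 23 — chronic ankle instability
(CAI) and healthy controls (HC) — differ by (a) a signed joint-angle
waveform offset pattern (CAI relative to HC) across the 12 angle channels
and (b) a centre-of-pressure velocity scale per group x condition, which is
the mechanism that plants group differences in the time-to-boundary
statistics (a CAI > HC velocity scale in the static condition only yields
the group-by-condition interaction).

Everything downstream of data collection is recoverable from the generated
records: marker trajectories are exact rigid-body forward kinematics of the
planted joint angles (plus optional marker noise), and force-plate records
are constructed so the standard COP formula returns the planted COP
exactly. Ground truth is stored alongside each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .kinem import JOINTS, PLANES, JointAngleTensor, matrix_from_euler_xyz
from .signalio import (
    FORCE_CHANNELS,
    MarkerTrajectorySet,
    TimeSeriesBlock,
    write_forces_csv,
    write_manifest,
    write_markers_csv,
    write_trc,
)

GROUPS = ("CAI", "HC")
CONDITIONS = ("static", "moving")
TRIALS_PER_CONDITION = 3


class InvalidSpecError(ValueError):
    pass


class InvalidEffectError(ValueError):
    pass


class InsufficientCohortError(ValueError):
    pass


# ---------------------------------------------------------------------------
# platform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformSpec:
    """Mediolateral sinusoidal platform motion.

    Displacement is lab X (+X = subject's right), metres. With
    ``phase_origin = 0`` the trajectory is A sin(2 pi f t): t = 0 is a zero
    crossing, and for a right-foot stance the first *medially* directed
    (negative-going) crossing falls half a period later — the trimming
    anchor is therefore always well defined inside a 15-s trial.
    """

    frequency: float = 1.6        # Hz
    peak_to_peak: float = 0.020   # metres
    duration: float = 15.0        # seconds
    sample_rate: float = 100.0    # Hz
    phase_origin: float = 0.0     # radians

    def validate(self) -> None:
        if self.frequency <= 0:
            raise InvalidSpecError(f"frequency must be > 0, got {self.frequency}")
        if self.peak_to_peak < 0:
            raise InvalidSpecError("peak_to_peak must be >= 0")
        if self.duration <= 0:
            raise InvalidSpecError(f"duration must be > 0, got {self.duration}")
        if self.sample_rate <= 0:
            raise InvalidSpecError(f"sample_rate must be > 0, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


def generate_platform_trajectory(spec: PlatformSpec) -> np.ndarray:
    """Displacement series x(t) = (p2p/2) sin(2 pi f t + phase), metres."""
    spec.validate()
    t = np.arange(spec.n_samples) / spec.sample_rate
    amp = spec.peak_to_peak / 2.0
    return amp * np.sin(2.0 * np.pi * spec.frequency * t + spec.phase_origin)


# ---------------------------------------------------------------------------
# group effects
# ---------------------------------------------------------------------------

def _pattern(d: dict[str, float]) -> np.ndarray:
    out = np.zeros((len(JOINTS), len(PLANES)))
    for key, val in d.items():
        joint, plane = key.split("_")
        out[JOINTS.index(joint), PLANES.index(plane)] = float(val)
    return out


#: Neutral single-leg stance posture, degrees (channel means common to groups).
DEFAULT_BASELINE = _pattern({
    "ankle_sagittal": 5.0, "ankle_frontal": 2.0,
    "knee_sagittal": 10.0,
    "hip_sagittal": 5.0,
    "torso_sagittal": 5.0,
})

#: Signed CAI - HC waveform offsets, degrees: more dorsiflexed ankle, more
#: flexed knee, less flexed hip and torso, more adducted hip, more internally
#: rotated ankle, more externally rotated knee and hip, less externally
#: rotated torso. Magnitudes are free design parameters of the generator,
#: sized for a strong but realistic group separation on the matched
#: principal-component score (Cohen's d around 1.2 at 23 per group).
DEFAULT_CAI_OFFSETS = _pattern({
    "ankle_sagittal": 1.0, "ankle_horizontal": 0.75,
    "knee_sagittal": 1.0, "knee_horizontal": -0.75,
    "hip_sagittal": -1.0, "hip_frontal": 0.75, "hip_horizontal": -0.75,
    "torso_sagittal": -0.75, "torso_horizontal": 0.5,
})

#: Platform-entrained oscillation amplitude per channel, degrees (moving
#: condition only); frontal-plane channels respond most to a mediolateral
#: perturbation.
DEFAULT_ENTRAINMENT = _pattern({
    "ankle_frontal": 3.0, "ankle_sagittal": 0.5,
    "knee_sagittal": 1.0, "knee_frontal": 0.5,
    "hip_frontal": 2.0, "hip_sagittal": 0.5,
    "torso_frontal": 1.5,
})


@dataclass
class GroupEffectSpec:
    """Planted group and condition effects.

    ``angle_offsets_deg`` is the expected CAI - HC contrast per channel
    (degrees, (4, 3) array in joint x plane order). ``cop_velocity_scale``
    multiplies the COP traversal speed per (group, condition); TTB scales
    as its inverse, so CAI > HC in the static cell only reproduces the
    group-by-condition interaction structure. ``between_sd_deg`` is the
    between-participant SD of each channel baseline; ``noise_sd_deg`` the
    stationary SD of the within-trial angle noise, coloured AR(1) with
    ``ar_coeff`` at 100 Hz.
    """

    angle_offsets_deg: np.ndarray = field(
        default_factory=lambda: DEFAULT_CAI_OFFSETS.copy())
    baseline_deg: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASELINE.copy())
    entrainment_deg: np.ndarray = field(
        default_factory=lambda: DEFAULT_ENTRAINMENT.copy())
    between_sd_deg: float = 1.5
    noise_sd_deg: float = 1.0
    ar_coeff: float = 0.95
    cop_velocity_scale: dict = field(default_factory=lambda: {
        ("CAI", "static"): 1.5, ("HC", "static"): 1.0,
        ("CAI", "moving"): 3.7, ("HC", "moving"): 3.5,
    })
    cop_sway_sd: float = 0.008        # m, stationary ML SD of the COP process
    cop_ap_sway_sd: float = 0.006     # m, AP
    cop_mean_reversion: float = 8.0   # 1/s
    cop_bandwidth: float = 3.0        # Hz, base-path bandwidth before rescaling
    cop_entrain_amp: float = 0.004    # m, ML COP oscillation when moving
    marker_noise_sd: float = 0.0005   # m, additive white marker noise
    body_weight_n: float = 700.0      # N, supports Fz

    def validate(self) -> None:
        if self.noise_sd_deg < 0 or self.between_sd_deg < 0:
            raise InvalidEffectError("noise and between-participant SDs must be >= 0")
        if not np.all(np.isfinite(self.angle_offsets_deg)):
            raise InvalidEffectError("angle offsets must be finite")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise InvalidEffectError("AR coefficient must be in [0, 1)")
        for key, v in self.cop_velocity_scale.items():
            if v <= 0:
                raise InvalidEffectError(f"COP velocity scale {key} must be > 0")


def null_effects(**overrides) -> GroupEffectSpec:
    """An effect spec with every group contrast switched off."""
    eff = GroupEffectSpec(
        angle_offsets_deg=np.zeros((len(JOINTS), len(PLANES))),
        cop_velocity_scale={
            ("CAI", "static"): 1.0, ("HC", "static"): 1.0,
            ("CAI", "moving"): 3.5, ("HC", "moving"): 3.5,
        },
        **overrides,
    )
    return eff


# ---------------------------------------------------------------------------
# joint-angle waveforms
# ---------------------------------------------------------------------------

def _ar1_noise(rng, shape, sd, coeff):
    """Stationary AR(1) noise with the given marginal SD."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - coeff**2)
    w = rng.normal(0.0, innov_sd, size=shape)
    x = lfilter([1.0], [1.0, -coeff], w, axis=-1)
    return x


def generate_joint_waveforms(
    group: str,
    condition: str,
    effects: GroupEffectSpec,
    platform: PlatformSpec,
    rng: np.random.Generator,
    baseline_dev: np.ndarray | None = None,
) -> JointAngleTensor:
    """One trial of 12 joint-angle channels at the platform sampling rate.

    Each channel = neutral posture + participant baseline deviation +
    group offset (CAI only) + platform-entrained sinusoid (moving only) +
    coloured noise. The expected CAI - HC contrast per channel equals the
    signed offset in ``effects``. ``baseline_dev`` (joint x plane, degrees)
    carries the participant-level deviation so it can be shared across a
    participant's trials; when omitted it is drawn from
    ``N(0, between_sd_deg)``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    effects.validate()
    platform.validate()
    n = platform.n_samples
    t = np.arange(n) / platform.sample_rate
    if baseline_dev is None:
        baseline_dev = rng.normal(0.0, effects.between_sd_deg,
                                  size=(len(JOINTS), len(PLANES)))
    mean = effects.baseline_deg + baseline_dev
    if group == "CAI":
        mean = mean + effects.angle_offsets_deg
    ang = np.repeat(mean[:, :, None], n, axis=2)
    if condition == "moving":
        # phase lag grows up the chain: distal joints respond first
        lags = np.array([0.0, 0.3, 0.6, 0.9])[:, None, None]
        carrier = np.sin(2.0 * np.pi * platform.frequency * t[None, None, :]
                         + platform.phase_origin - lags)
        ang = ang + effects.entrainment_deg[:, :, None] * carrier
    ang = ang + _ar1_noise(rng, ang.shape, effects.noise_sd_deg, effects.ar_coeff)
    return JointAngleTensor(ang, platform.sample_rate)


# ---------------------------------------------------------------------------
# body template and forward kinematics
# ---------------------------------------------------------------------------

@dataclass
class BodyTemplate:
    """Five-segment stick body with marker clusters (template pose, metres).

    The template pose is the identity pose: all joint angles zero, lab axes
    X = ML (+ right), Y = AP (+ forward), Z = up. ``segments`` maps segment
    name to its marker cluster; ``joint_centres`` holds the chain pivots in
    template coordinates, ordered ankle -> torso.
    """

    segments: dict
    joint_centres: dict
    segment_order: tuple = ("foot", "shank", "thigh", "pelvis", "torso")

    def validate(self) -> None:
        for seg in self.segment_order:
            cluster = np.array(list(self.segments[seg].values()))
            if cluster.shape[0] < 3:
                raise InvalidSpecError(f"segment {seg!r} needs >= 3 markers")
            sv = np.linalg.svd(cluster - cluster.mean(axis=0), compute_uv=False)
            if sv[1] < 1e-9:
                raise InvalidSpecError(f"segment {seg!r} marker cluster is collinear")

    @property
    def marker_labels(self) -> list[str]:
        return [m for seg in self.segment_order for m in self.segments[seg]]


#: Labels of the four foot-border markers used for the foot rectangle.
FOOT_BORDER_MARKERS = ("MT1", "MT5", "TOE", "HEEL")


def default_template(
    foot_length: float = 0.25,
    foot_width: float = 0.10,
    shank_length: float = 0.40,
    thigh_length: float = 0.40,
    pelvis_height: float = 0.25,
    torso_length: float = 0.50,
) -> BodyTemplate:
    """Published-order-of-magnitude stick body (right stance).

    The foot rectangle is ``foot_length x foot_width`` with the heel 5 cm
    behind the ankle; the default 10-cm width matches a typical adult foot.
    """
    hw = foot_width / 2.0
    heel_y = -0.05
    toe_y = heel_y + foot_length
    ankle_z = 0.10
    knee_z = ankle_z + shank_length
    hip_z = knee_z + thigh_length
    torso_z = hip_z + pelvis_height
    top_z = torso_z + torso_length
    segments = {
        "foot": {
            "MT1": (-hw, toe_y - 0.05, 0.02),   # first metatarsal head, medial
            "MT5": (hw, toe_y - 0.05, 0.02),    # fifth metatarsal head, lateral
            "TOE": (0.0, toe_y, 0.02),          # first distal phalanx
            "HEEL": (0.0, heel_y, 0.02),        # calcaneus
            "FOOT_TOP": (0.0, 0.08, 0.07),
        },
        "shank": {
            "SHANK1": (0.05, 0.02, ankle_z + 0.06),
            "SHANK2": (-0.05, 0.02, ankle_z + 0.14),
            "SHANK3": (0.0, -0.05, ankle_z + 0.30),
            "SHANK4": (0.05, -0.03, ankle_z + 0.22),
        },
        "thigh": {
            "THIGH1": (0.06, 0.03, knee_z + 0.06),
            "THIGH2": (-0.06, 0.03, knee_z + 0.16),
            "THIGH3": (0.0, -0.06, knee_z + 0.34),
            "THIGH4": (0.06, -0.04, knee_z + 0.25),
        },
        "pelvis": {
            "RASI": (0.12, 0.08, hip_z + 0.12),
            "LASI": (-0.12, 0.08, hip_z + 0.12),
            "SACR": (0.0, -0.10, hip_z + 0.10),
        },
        "torso": {
            "STRN": (0.0, 0.09, torso_z + 0.20),
            "C7": (0.0, -0.07, torso_z + 0.40),
            "RSHO": (0.16, 0.0, torso_z + 0.38),
            "LSHO": (-0.16, 0.0, torso_z + 0.38),
        },
    }
    joint_centres = {
        "ankle": (0.0, 0.0, ankle_z),
        "knee": (0.0, 0.0, knee_z),
        "hip": (0.0, 0.0, hip_z),
        "torso": (0.0, 0.0, torso_z),
    }
    tmpl = BodyTemplate(segments=segments, joint_centres=joint_centres)
    tmpl.validate()
    return tmpl


def forward_kinematics(
    angles: JointAngleTensor,
    template: BodyTemplate | None = None,
    platform_displacement: np.ndarray | None = None,
    marker_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MarkerTrajectorySet:
    """Rigid-body marker trajectories driven by planted joint angles.

    The foot is the chain root: it translates with the platform (lab X) and
    does not rotate. Each segment above it is the parent composed with the
    joint's Rx(a) Ry(b) Rz(c) rotation about the joint centre, so the angle
    extraction stage recovers the planted tensor exactly in the noise-free
    case. Gaussian marker noise (``marker_noise_sd`` metres) is optional.
    """
    template = template or default_template()
    template.validate()
    n = angles.n_samples
    disp = np.zeros(n) if platform_displacement is None else np.asarray(
        platform_displacement, dtype=float)
    if disp.shape[0] != n:
        raise InvalidSpecError("platform displacement length must match angles")

    order = template.segment_order
    centres = [np.array(template.joint_centres[j]) for j in JOINTS]
    # world transforms per segment: p_w = c_w[i] + R[i] (p - c_t[i])
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    R_seg = {order[0]: eye}
    foot_off = np.zeros((n, 3))
    foot_off[:, 0] = disp
    c_w = centres[0][None, :] + foot_off  # ankle centre world position
    c_world = {}
    R_prev = eye
    for i, joint in enumerate(JOINTS):
        seg = order[i + 1]
        trip = angles.angles[i].T  # (n, 3)
        R_joint = matrix_from_euler_xyz(trip)
        R_cur = np.einsum("tij,tjk->tik", R_prev, R_joint)
        R_seg[seg] = R_cur
        c_world[seg] = (c_w, centres[i])
        if i + 1 < len(JOINTS):
            c_w = c_w + np.einsum("tij,j->ti", R_cur, centres[i + 1] - centres[i])
        R_prev = R_cur

    labels = template.marker_labels
    pos = np.empty((n, len(labels), 3))
    col = 0
    for seg in order:
        for m, p_t in template.segments[seg].items():
            p_t = np.asarray(p_t, dtype=float)
            if seg == order[0]:
                pos[:, col, :] = p_t[None, :] + foot_off
            else:
                cw, ct = c_world[seg]
                pos[:, col, :] = cw + np.einsum(
                    "tij,j->ti", R_seg[seg], p_t - ct)
            col += 1
    if marker_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when marker_noise_sd > 0")
        pos = pos + rng.normal(0.0, marker_noise_sd, size=pos.shape)
    return MarkerTrajectorySet(labels, pos, angles.rate)


# ---------------------------------------------------------------------------
# COP and force plate
# ---------------------------------------------------------------------------

def generate_cop_and_forces(
    group: str,
    condition: str,
    effects: GroupEffectSpec,
    platform: PlatformSpec,
    rng: np.random.Generator,
    foot_half_width: float = 0.05,
    foot_extent_ap: tuple = (-0.05, 0.20),
    force_rate: float = 1000.0,
    frozen: bool = False,
):
    """Force-plate record (1 kHz) plus the ground-truth COP it encodes.

    The COP is a mean-reverting, band-limited stochastic process inside
    the foot rectangle, expressed in the platform frame (the plate rides
    the platform, so plate-frame moments already measure foot-relative
    COP): an Ornstein-Uhlenbeck base path low-pass filtered at
    ``effects.cop_bandwidth`` (physiological sway is low-frequency
    dominated). The per-(group, condition) velocity scale k is an exact
    time-rescaling of that law — positions keep their marginal spread
    while every velocity scales by k, and the spectral support (bandwidth
    x k) stays below the 10 Hz analysis filter for the default scales, so
    the planted TTB contrasts survive signal conditioning. The moving
    condition adds a platform-entrained ML oscillation.

    Forces and moments are constructed so that the COP formula
    ``COP_x = -My/Fz``, ``COP_y = Mx/Fz`` (plate-surface origin) inverts to
    the ground-truth COP exactly. Returns ``(record, cop)`` with ``record``
    a 1 kHz :class:`TimeSeriesBlock` of Fx..Mz and ``cop`` an (n, 2) array.
    """
    effects.validate()
    platform.validate()
    scale = effects.cop_velocity_scale[(group, condition)]
    sd_ml, sd_ap = effects.cop_sway_sd, effects.cop_ap_sway_sd
    entrain = effects.cop_entrain_amp if condition == "moving" else 0.0
    if 3.5 * sd_ml + entrain > foot_half_width:
        raise InvalidEffectError(
            "COP spread exceeds the foot rectangle: reduce cop_sway_sd/entrain")
    n = int(round(platform.duration * force_rate))
    t = np.arange(n) / force_rate
    if frozen:
        ml = np.zeros(n)
        ap = np.full(n, np.mean(foot_extent_ap))
    else:
        ml = _sway_path(rng, n, force_rate, effects.cop_mean_reversion,
                        sd_ml, effects.cop_bandwidth, scale)
        ap = np.mean(foot_extent_ap) + _sway_path(
            rng, n, force_rate, effects.cop_mean_reversion,
            sd_ap, effects.cop_bandwidth, scale)
        ml = ml + entrain * np.sin(2.0 * np.pi * platform.frequency * t
                                   + platform.phase_origin + np.pi)
        # reflect the rare excursion back inside the rectangle
        ml = _reflect(ml, -foot_half_width, foot_half_width)
        ap = _reflect(ap, foot_extent_ap[0] + 1e-4, foot_extent_ap[1] - 1e-4)
    cop = np.stack([ml, ap], axis=1)

    fz = np.full(n, -effects.body_weight_n)
    if not frozen:
        fz = fz + _ou(rng, n, np.exp(-2.0 / force_rate), 5.0)
    fx = np.zeros(n) if frozen else _ou(rng, n, np.exp(-2.0 / force_rate), 2.0)
    fy = np.zeros(n) if frozen else _ou(rng, n, np.exp(-2.0 / force_rate), 2.0)
    my = -cop[:, 0] * fz
    mx = cop[:, 1] * fz
    mz = np.zeros(n) if frozen else _ou(rng, n, np.exp(-2.0 / force_rate), 0.5)
    record = TimeSeriesBlock(
        np.stack([fx, fy, fz, mx, my, mz]), force_rate, list(FORCE_CHANNELS))
    return record, cop


def _ou(rng, n, a, sd):
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a**2), size=n)
    return lfilter([1.0], [1.0, -a], innov)


def _sway_path(rng, n, rate, theta, sd, bandwidth, speed_scale):
    """Band-limited mean-reverting sway, time-rescaled by ``speed_scale``.

    Realises b(k t) where b is an OU process (reversion ``theta`` 1/s,
    marginal SD ``sd``) low-pass filtered at ``bandwidth`` Hz: positions
    keep their spread, velocities scale by k, spectral support is
    bandwidth x k.
    """
    from scipy.signal import butter, filtfilt

    if sd == 0:
        return np.zeros(n)
    k = speed_scale
    x = _ou(rng, n, np.exp(-theta * k / rate), sd)
    cutoff = bandwidth * k
    if cutoff < rate / 2.0:
        b, a = butter(4, cutoff / (rate / 2.0), btype="low")
        x = filtfilt(b, a, x)
    return x


def _reflect(x, lo, hi):
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class TrialData:
    """One generated trial with its ground truth."""

    platform_displacement: np.ndarray      # metres at platform.sample_rate
    angles_truth: JointAngleTensor
    markers: MarkerTrajectorySet
    forces: TimeSeriesBlock                # 1 kHz
    cop_truth: np.ndarray                  # (n_force, 2) platform frame


@dataclass
class SyntheticCohort:
    manifest: pd.DataFrame
    trials: dict                           # (participant, condition, trial) -> TrialData
    platform: PlatformSpec
    effects: GroupEffectSpec
    template: BodyTemplate
    rng_seed: int

    def trial(self, participant: str, condition: str, trial: int) -> TrialData:
        return self.trials[(participant, condition, trial)]


def generate_cohort(
    n_per_group: int = 23,
    conditions: tuple = CONDITIONS,
    effects: GroupEffectSpec | None = None,
    platform: PlatformSpec | None = None,
    template: BodyTemplate | None = None,
    seed: int = 0,
    side: str = "right",
) -> SyntheticCohort:
    """A full synthetic cohort: deterministic given ``seed``.

    ``n_per_group`` participants per group, three trials per participant
    and condition. Participant baseline postures are drawn once and shared
    across that participant's trials and conditions.
    """
    if n_per_group < 2:
        raise InsufficientCohortError(
            f"need at least 2 participants per group, got {n_per_group}")
    effects = effects if effects is not None else GroupEffectSpec()
    platform = platform or PlatformSpec()
    template = template or default_template()
    effects.validate()
    platform.validate()
    rng = np.random.default_rng(seed)

    rows, trials = [], {}
    static_disp = np.zeros(platform.n_samples)
    moving_disp = generate_platform_trajectory(platform)
    for group in GROUPS:
        for k in range(n_per_group):
            pid = f"{group}{k+1:02d}"
            baseline_dev = rng.normal(
                0.0, effects.between_sd_deg, size=(len(JOINTS), len(PLANES)))
            for condition in conditions:
                disp = moving_disp if condition == "moving" else static_disp
                for tr in range(1, TRIALS_PER_CONDITION + 1):
                    ang = generate_joint_waveforms(
                        group, condition, effects, platform, rng, baseline_dev)
                    markers = forward_kinematics(
                        ang, template, disp,
                        marker_noise_sd=effects.marker_noise_sd, rng=rng)
                    forces, cop = generate_cop_and_forces(
                        group, condition, effects, platform, rng)
                    trials[(pid, condition, tr)] = TrialData(
                        disp, ang, markers, forces, cop)
                    rows.append(dict(participant=pid, group=group,
                                     condition=condition, side=side, trial=tr))
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(manifest, trials, platform, effects, template, seed)


def write_cohort(cohort: SyntheticCohort, out_dir, marker_format: str = "trc") -> pd.DataFrame:
    """Serialise a cohort to disk (TRC or wide-CSV markers + force CSVs).

    Returns the manifest extended with file paths, also written as
    ``manifest.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in cohort.manifest.iterrows():
        key = (row.participant, row.condition, row.trial)
        td = cohort.trials[key]
        stem = f"{row.participant}_{row.condition}_t{row.trial}"
        if marker_format == "trc":
            mpath = out / f"{stem}.trc"
            write_trc(td.markers, mpath)
        else:
            mpath = out / f"{stem}_markers.csv"
            write_markers_csv(td.markers, mpath)
        fpath = out / f"{stem}_forces.csv"
        write_forces_csv(td.forces, fpath)
        rows.append(dict(row) | dict(path_markers=mpath.name, path_forces=fpath.name))
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    return manifest


def load_config(path) -> dict:
    """Read a YAML/key-value generator config (platform, effects, cohort)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def cohort_from_config(path) -> SyntheticCohort:
    cfg = load_config(path)
    platform = PlatformSpec(**cfg.get("platform", {}))
    eff_cfg = dict(cfg.get("effects", {}))
    if "angle_offsets_deg" in eff_cfg:
        eff_cfg["angle_offsets_deg"] = _pattern(eff_cfg["angle_offsets_deg"])
    effects = GroupEffectSpec(**eff_cfg)
    return generate_cohort(
        n_per_group=int(cfg.get("n_per_group", 23)),
        conditions=tuple(cfg.get("conditions", CONDITIONS)),
        effects=effects,
        platform=platform,
        seed=int(cfg.get("seed", 0)),
        side=cfg.get("side", "right"),
    )
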