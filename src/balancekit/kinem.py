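"""Joint kinematics: segment frames, Euler X-Y-Z angles, discrete measures.

The kinematic chain spans five rigid segments — foot, shank, thigh, pelvis,
torso — observed through small marker clusters. Each joint angle triplet is
the Euler/Cardan X-Y-Z decomposition of the rotation of the segment further
from the support foot relative to the nearer one:

* ankle : foot -> shank
* knee  : shank -> thigh
* hip   : thigh -> pelvis
* torso : pelvis -> torso

Axis convention (right stance; mirrored for left): X = mediolateral
(flexion/extension axis, sagittal-plane angle), Y = anteroposterior
(frontal-plane angle, inversion/adduction), Z = longitudinal
(horizontal-plane angle, axial rotation). Positive senses are dorsiflexion/
flexion, inversion/adduction, internal rotation.

Segment orientation is estimated per frame by a least-squares rigid-body
(orthogonal Procrustes) fit of the observed marker cluster to its template
cluster, which keeps the frames exactly orthonormal under marker noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signalio import MarkerTrajectorySet

JOINTS = ("ankle", "knee", "hip", "torso")
PLANES = ("sagittal", "frontal", "horizontal")

#: (reference segment, moving segment) per joint, ordered foot -> torso
JOINT_SEGMENTS = {
    "ankle": ("foot", "shank"),
    "knee": ("shank", "thigh"),
    "hip": ("thigh", "pelvis"),
    "torso": ("pelvis", "torso"),
}

GIMBAL_LIMIT_DEG = 85.0
MIRROR = np.diag([-1.0, 1.0, 1.0])  # left-stance reflection about the sagittal plane


class MissingMarkerError(KeyError):
    pass


class DegenerateClusterError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class SegmentFrame:
    """Per-sample orientation and origin of one body segment.

    ``rotations`` (n_frames, 3, 3) map template/segment coordinates into the
    lab frame; each matrix is proper orthogonal. ``origins`` (n_frames, 3)
    is the lab position of the template origin.
    """

    name: str
    rotations: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotations, dtype=float)
        if R.ndim != 3 or R.shape[1:] != (3, 3):
            raise ValueError("rotations must have shape (n_frames, 3, 3)")
        self.rotations = R
        self.origins = np.asarray(self.origins, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]


@dataclass
class JointAngleTensor:
    """Joint angles, degrees: (4 joints x 3 planes x n_samples).

    Joint order follows :data:`JOINTS`, plane order :data:`PLANES`
    (sagittal = X, frontal = Y, horizontal = Z). Channels are unwrapped
    (continuous) over time.
    """

    angles: np.ndarray
    rate: float
    gimbal_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 3 or a.shape[:2] != (len(JOINTS), len(PLANES)):
            raise ValueError(
                f"angles must have shape ({len(JOINTS)}, {len(PLANES)}, n); got {a.shape}"
            )
        self.angles = a
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[2]

    def channel(self, joint: str, plane: str) -> np.ndarray:
        return self.angles[JOINTS.index(joint), PLANES.index(plane)]

    def flat(self) -> np.ndarray:
        """Channel-major flattening: 12 blocks of n_samples each.

        Block order is (joint, plane) in :data:`JOINTS` x :data:`PLANES`
        order, i.e. ankle-sagittal first, torso-horizontal last. This is the
        fixed column layout of the waveform-PCA input matrix.
        """
        return self.angles.reshape(len(JOINTS) * len(PLANES), -1).ravel()

    def window(self, start: int, end: int) -> "JointAngleTensor":
        return JointAngleTensor(
            self.angles[:, :, start:end].copy(),
            self.rate,
            None if self.gimbal_flags is None else self.gimbal_flags[:, start:end].copy(),
        )


CHANNEL_NAMES = [f"{j}_{p}" for j in JOINTS for p in PLANES]


@dataclass
class DiscreteKinematics:
    """Per-channel range of motion (deg) and RMS angular velocity (deg/s)."""

    rom: np.ndarray            # (4, 3) max - min, degrees
    rms_velocity: np.ndarray   # (4, 3) sqrt(mean v^2), degrees/s


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------

def _procrustes_rotations(template_cluster: np.ndarray, observed: np.ndarray):
    """Batched least-squares rotation fitting observed clusters to a template.

    Returns rotations R_t (n, 3, 3) and translations o_t (n, 3) minimising
    sum_i || y_ti - (R_t x_i + o_t) ||^2 over proper rotations.
    """
    x = np.asarray(template_cluster, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape[0] < 3:
        raise DegenerateClusterError("need at least 3 markers per segment cluster")
    xc = x - x.mean(axis=0)
    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[1] < 1e-9:
        raise DegenerateClusterError("marker cluster is collinear")
    ybar = y.mean(axis=1)
    yc = y - ybar[:, None, :]
    # cross-covariance M_t = sum_i y_ti x_i^T  -> R_t = U diag(1,1,d) V^T
    M = np.einsum("tmi,mj->tij", yc, xc)
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", U, Vt)))
    D = np.zeros_like(U)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("tij,tjk,tkl->til", U, D, Vt)
    origins = ybar - np.einsum("tij,j->ti", R, x.mean(axis=0))
    return R, origins


def build_segment_frames(
    markers: MarkerTrajectorySet, template, side: str = "right"
) -> dict[str, SegmentFrame]:
    """Fit rigid-body frames for every segment of a body template.

    ``template`` is a :class:`~balancekit.synthgen.BodyTemplate` (or any
    object with ``segments: {name: {marker: xyz}}``). For a left stance the
    marker data are reflected about the sagittal plane and fitted against
    the right-side template, which mirrors the axis conventions
    consistently.
    """
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    pos = markers.positions
    if side == "left":
        pos = pos @ MIRROR.T
    frames: dict[str, SegmentFrame] = {}
    for seg, cluster in template.segments.items():
        names = list(cluster)
        for m in names:
            if m not in markers.labels:
                raise MissingMarkerError(f"segment {seg!r} needs marker {m!r}")
        idx = [markers.labels.index(m) for m in names]
        X = np.array([cluster[m] for m in names])
        R, o = _procrustes_rotations(X, pos[:, idx, :])
        frames[seg] = SegmentFrame(seg, R, o)
    return frames


# ---------------------------------------------------------------------------
# Euler X-Y-Z angles
# ---------------------------------------------------------------------------

def euler_xyz_from_matrix(R: np.ndarray) -> np.ndarray:
    """Decompose rotation matrices as Rx(a) Ry(b) Rz(c); returns degrees.

    Closed form for the X-Y-Z (Cardan) sequence: b = asin(R[0,2]),
    a = atan2(-R[1,2], R[2,2]), c = atan2(-R[0,1], R[0,0]). ``R`` may be a
    single (3, 3) matrix or a stack (n, 3, 3); the result has shape (3,)
    or (n, 3).
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    b = np.arcsin(np.clip(R[:, 0, 2], -1.0, 1.0))
    a = np.arctan2(-R[:, 1, 2], R[:, 2, 2])
    c = np.arctan2(-R[:, 0, 1], R[:, 0, 0])
    out = np.degrees(np.stack([a, b, c], axis=-1))
    return out[0] if single else out


def matrix_from_euler_xyz(angles_deg: np.ndarray) -> np.ndarray:
    """Compose Rx(a) Ry(b) Rz(c) from degree triplets ((n, 3) or (3,))."""
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    single = ang.ndim == 1
    if single:
        ang = ang[None]
    ca, cb, cc = np.cos(ang[:, 0]), np.cos(ang[:, 1]), np.cos(ang[:, 2])
    sa, sb, sc = np.sin(ang[:, 0]), np.sin(ang[:, 1]), np.sin(ang[:, 2])
    R = np.empty((ang.shape[0], 3, 3))
    R[:, 0, 0] = cb * cc
    R[:, 0, 1] = -cb * sc
    R[:, 0, 2] = sb
    R[:, 1, 0] = ca * sc + sa * sb * cc
    R[:, 1, 1] = ca * cc - sa * sb * sc
    R[:, 1, 2] = -sa * cb
    R[:, 2, 0] = sa * sc - ca * sb * cc
    R[:, 2, 1] = sa * cc + ca * sb * sc
    R[:, 2, 2] = ca * cb
    return R[0] if single else R


def joint_angles_xyz(proximal: SegmentFrame, distal: SegmentFrame):
    """X-Y-Z Euler angles of ``distal`` relative to ``proximal``, degrees.

    Returns ``(angles, gimbal)`` where ``angles`` has shape (3, n) —
    unwrapped sagittal (X), frontal (Y), horizontal (Z) series — and
    ``gimbal`` flags samples with |frontal| > 85 deg, near the X-Y-Z
    singularity.
    """
    if proximal.n_frames != distal.n_frames:
        raise AlignmentError(
            f"frame length mismatch: {proximal.n_frames} vs {distal.n_frames}"
        )
    R_rel = np.einsum("tji,tjk->tik", proximal.rotations, distal.rotations)
    ang = euler_xyz_from_matrix(R_rel)  # (n, 3)
    gimbal = np.abs(ang[:, 1]) > GIMBAL_LIMIT_DEG
    ang = np.unwrap(ang, axis=0, period=360.0)
    return ang.T.copy(), gimbal


def joint_angles(
    markers: MarkerTrajectorySet, template, side: str = "right"
) -> JointAngleTensor:
    """Full-chain joint angles from a marker trajectory set."""
    frames = build_segment_frames(markers, template, side)
    out = np.empty((len(JOINTS), len(PLANES), markers.n_frames))
    flags = np.zeros((len(JOINTS), markers.n_frames), dtype=bool)
    for ji, joint in enumerate(JOINTS):
        prox, dist = JOINT_SEGMENTS[joint]
        ang, gim = joint_angles_xyz(frames[prox], frames[dist])
        out[ji] = ang
        flags[ji] = gim
    return JointAngleTensor(out, markers.rate, flags)


# ---------------------------------------------------------------------------
# velocities and discrete measures
# ---------------------------------------------------------------------------

def angular_velocity(angles: JointAngleTensor, order: int = 1) -> np.ndarray:
    """Angular velocity tensor, degrees/s, same shape as the angles.

    Central differences in the interior, one-sided at the ends (exact on
    linear ramps). ``order=2`` differentiates twice, reproducing a reading
    of the angular measure as the second time-derivative; the conventional
    first derivative is the default.
    """
    if angles.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples to differentiate")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    v = np.gradient(angles.angles, 1.0 / angles.rate, axis=2)
    if order == 2:
        v = np.gradient(v, 1.0 / angles.rate, axis=2)
    return v


def discrete_measures(
    angles: JointAngleTensor, velocities: np.ndarray | None = None
) -> DiscreteKinematics:
    """Range of motion (max - min) and RMS angular velocity per channel."""
    if velocities is None:
        velocities = angular_velocity(angles)
    rom = angles.angles.max(axis=2) - angles.angles.min(axis=2)
    rms = np.sqrt(np.mean(np.asarray(velocities) ** 2, axis=2))
    return DiscreteKinematics(rom=rom, rms_velocity=rms)


def discrete_measures_frame(dk: DiscreteKinematics):
    """Tidy one-row-per-channel DataFrame of the discrete measures."""
    import pandas as pd

    rows = []
    for ji, j in enumerate(JOINTS):
        for pi, p in enumerate(PLANES):
            rows.append(
                dict(joint=j, plane=p, rom_deg=dk.rom[ji, pi],
                     rms_velocity_deg_s=dk.rms_velocity[ji, pi])
            )
    return pd.DataFrame(rows)
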