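"""Centre-of-pressure stability metrics: TTB-ML, sway amplitude, velocity.

Time-to-boundary (TTB) estimates, at each instant, how long the centre of
pressure (COP) would take to reach the edge of the base of support if it
kept its current mediolateral velocity. The base of support is the stance
foot modelled as a rectangle spanned by the first and fifth metatarsal
heads, the first distal phalanx and the calcaneus markers. Trials are
summarised by the mean, the absolute (global) minimum and the SD of the
local minima of the TTB series — low values mean the COP repeatedly comes
close to the boundary fast, i.e. poorer lateral stability.

On a moving platform both COP and boundary are expressed in the platform/
foot frame (the plate rides the platform and the boundary is anatomical),
so TTB measures COP motion relative to the foot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signalio import MarkerTrajectorySet, TimeSeriesBlock


class UnloadedSampleError(ValueError):
    pass


class DegenerateAxisError(ValueError):
    pass


class DegenerateTrialError(ValueError):
    pass


class BoundaryMismatchWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# COP from force-plate records
# ---------------------------------------------------------------------------

def compute_cop(
    record: TimeSeriesBlock,
    plate_offset: tuple = (0.0, 0.0, 0.0),
    load_threshold: float = 20.0,
) -> np.ndarray:
    """COP (n, 2), metres, plate frame, from a Fx..Mz force-plate record.

    ``COP_x = (-My - Fx dz)/Fz + ox`` and ``COP_y = (Mx - Fy dz)/Fz + oy``
    with ``(ox, oy, dz)`` the plate origin offset (dz = vertical distance
    from the moment origin to the plate surface). Samples with
    ``|Fz| < load_threshold`` (newtons) indicate an unloaded plate and are
    rejected.
    """
    fx, fy, fz = (record.channel(c) for c in ("Fx", "Fy", "Fz"))
    mx, my = record.channel("Mx"), record.channel("My")
    ox, oy, dz = plate_offset
    low = np.abs(fz) < load_threshold
    if low.any():
        idx = np.nonzero(low)[0]
        raise UnloadedSampleError(
            f"|Fz| below {load_threshold} N at {idx.size} samples "
            f"(first: {idx[:5].tolist()})")
    cop_x = (-my - fx * dz) / fz + ox
    cop_y = (mx - fy * dz) / fz + oy
    return np.stack([cop_x, cop_y], axis=1)


# ---------------------------------------------------------------------------
# foot boundary
# ---------------------------------------------------------------------------

@dataclass
class FootBoundary:
    """Rectangular base-of-support model in a foot-aligned frame.

    ``axis_long``/``axis_ml`` are horizontal-plane unit vectors (lab or
    platform frame); ``origin`` is the rectangle centre. Extents are signed
    coordinates of the rectangle edges in the foot frame relative to the
    origin: ``ml_extent = (b_med, b_lat)`` with b_med < 0 < b_lat.
    """

    origin: np.ndarray         # (2,)
    axis_long: np.ndarray      # (2,) heel -> toe
    axis_ml: np.ndarray        # (2,)
    ml_extent: tuple           # (b_med, b_lat) metres, relative to origin
    ap_extent: tuple           # (b_back, b_front)

    @property
    def ml_width(self) -> float:
        return self.ml_extent[1] - self.ml_extent[0]

    @property
    def corners(self) -> np.ndarray:
        """Rectangle corners (4, 2) in the lab/platform frame."""
        out = []
        for a in self.ml_extent:
            for b in self.ap_extent:
                out.append(self.origin + a * self.axis_ml + b * self.axis_long)
        return np.array(out)

    def to_foot_frame(self, xy: np.ndarray) -> np.ndarray:
        """Project lab/platform-frame points (n, 2) to (ml, ap) foot coords."""
        rel = np.atleast_2d(xy) - self.origin
        return np.stack([rel @ self.axis_ml, rel @ self.axis_long], axis=1)


def foot_boundary(
    markers: MarkerTrajectorySet,
    labels: tuple = ("MT1", "MT5", "TOE", "HEEL"),
    platform_displacement: np.ndarray | None = None,
) -> FootBoundary:
    """Foot rectangle from the four border markers, trial-averaged.

    The long axis is the horizontal-plane unit vector from the calcaneus to
    the distal-phalanx marker; the rectangle is the bounding box of the
    four trial-averaged marker projections in the (ML, long-axis) foot
    frame. If ``platform_displacement`` (metres, lab X) is given, markers
    are first re-expressed in the platform frame so the boundary is
    platform-relative on moving trials.
    """
    mt1, mt5, toe, heel = labels
    pts = {}
    for lab in labels:
        p = markers.get(lab).copy()
        if platform_displacement is not None:
            if len(platform_displacement) != markers.n_frames:
                raise ValueError("platform displacement length mismatch")
            p[:, 0] = p[:, 0] - platform_displacement
        pts[lab] = p.mean(axis=0)[:2]  # horizontal-plane projection
    axis = pts[toe] - pts[heel]
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise DegenerateAxisError("calcaneus and distal-phalanx markers coincide")
    u_long = axis / norm
    u_ml = np.array([u_long[1], -u_long[0]])
    quad = np.array([pts[lab] for lab in labels])
    centre = quad.mean(axis=0)
    rel = quad - centre
    ml = rel @ u_ml
    ap = rel @ u_long
    return FootBoundary(
        origin=centre,
        axis_long=u_long,
        axis_ml=u_ml,
        ml_extent=(float(ml.min()), float(ml.max())),
        ap_extent=(float(ap.min()), float(ap.max())),
    )


# ---------------------------------------------------------------------------
# time-to-boundary
# ---------------------------------------------------------------------------

@dataclass
class TTBSeries:
    """Per-sample TTB-ML values (seconds) with a validity mask.

    Samples where |velocity| is below threshold take the cap value and are
    invalid; samples with the COP outside the rectangle are clipped to 0
    and invalid.
    """

    ttb: np.ndarray
    valid: np.ndarray
    cap: float
    rate: float


def ttb_ml(
    ml_position: np.ndarray,
    rate: float,
    ml_extent: tuple,
    cap: float = 10.0,
    velocity_threshold: float = 1e-6,
    outside_warn_fraction: float = 0.05,
    ml_velocity: np.ndarray | None = None,
) -> TTBSeries:
    """TTB series from a foot-frame ML COP position series.

    Velocity is the central difference of the (already filtered) position
    unless ``ml_velocity`` supplies it directly. With position p and
    velocity v: moving laterally (v > 0) the boundary is b_lat, so
    ttb = (b_lat - p)/v; moving medially, (p - b_med)/|v|. Near-zero
    velocity samples take ``cap`` and are flagged invalid; positions
    outside the rectangle give 0, flagged invalid.
    """
    p = np.asarray(ml_position, dtype=float)
    b_med, b_lat = ml_extent
    if not b_med < b_lat:
        raise ValueError("ml_extent must satisfy b_med < b_lat")
    if ml_velocity is None:
        v = np.gradient(p, 1.0 / rate)
    else:
        v = np.asarray(ml_velocity, dtype=float)
        if v.shape != p.shape:
            raise ValueError("ml_velocity must match ml_position in shape")
    n = p.size
    ttb = np.full(n, cap)
    valid = np.ones(n, dtype=bool)
    slow = np.abs(v) < velocity_threshold
    valid[slow] = False
    pos_v = (~slow) & (v > 0)
    neg_v = (~slow) & (v < 0)
    with np.errstate(divide="ignore"):
        ttb[pos_v] = (b_lat - p[pos_v]) / v[pos_v]
        ttb[neg_v] = (p[neg_v] - b_med) / (-v[neg_v])
    outside = (p < b_med) | (p > b_lat)
    neg = ttb < 0
    bad = outside | neg
    ttb[bad] = 0.0
    valid[bad] = False
    if outside.mean() > outside_warn_fraction:
        warnings.warn(
            f"COP outside the foot rectangle for {100*outside.mean():.1f}% "
            "of samples: boundary/COP frames may be mismatched",
            BoundaryMismatchWarning,
            stacklevel=2,
        )
    return TTBSeries(ttb=ttb, valid=valid, cap=cap, rate=rate)


@dataclass
class TTBSummary:
    """Trial summary of a TTB series: the three minima statistics."""

    mean_of_minima: float
    absolute_minimum: float
    sd_of_minima: float
    n_minima: int
    degenerate: bool = False


def local_minima_indices(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Indices of valid local minima (strict; plateaus take the first sample).

    A sample qualifies when, inside one contiguous run of valid samples, the
    nearest differing neighbours on both sides are strictly larger; a flat
    stretch satisfying this counts once at its first sample. Run edges have
    no outer neighbour and cannot qualify.
    """
    v = np.asarray(values, dtype=float)
    ok = np.asarray(valid, dtype=bool)
    out = []
    n = v.size
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        # run [i, j]
        k = i
        while k <= j:
            m = k
            while m + 1 <= j and v[m + 1] == v[k]:
                m += 1
            left_ok = k - 1 >= i and v[k - 1] > v[k]
            right_ok = m + 1 <= j and v[m + 1] > v[k]
            if left_ok and right_ok:
                out.append(k)
            k = m + 1
        i = j + 1
    return np.array(out, dtype=int)


def ttb_summary(series: TTBSeries) -> TTBSummary:
    """Mean / absolute / SD of the TTB local minima over valid samples.

    If the series has no interior local minimum (e.g. monotone within every
    valid run), the global minimum over valid samples stands in as the
    single minimum and the summary is flagged ``degenerate``. A series with
    no valid samples at all raises :class:`DegenerateTrialError`.
    """
    if not series.valid.any():
        raise DegenerateTrialError("no valid TTB samples in trial")
    vals = series.ttb[series.valid]
    abs_min = float(vals.min())
    idx = local_minima_indices(series.ttb, series.valid)
    if idx.size == 0:
        return TTBSummary(abs_min, abs_min, 0.0, 1, degenerate=True)
    minima = series.ttb[idx]
    sd = float(np.std(minima, ddof=1)) if idx.size > 1 else 0.0
    return TTBSummary(
        mean_of_minima=float(minima.mean()),
        absolute_minimum=abs_min,
        sd_of_minima=sd,
        n_minima=int(idx.size),
    )


# ---------------------------------------------------------------------------
# sway metrics
# ---------------------------------------------------------------------------

@dataclass
class SwaySummary:
    sd_amp: float          # metres: SD of COP distance from trajectory centre
    sway_velocity: float   # metres/s: path length / duration


def sway_summary(cop_xy: np.ndarray, rate: float) -> SwaySummary:
    """SDAmp and sway velocity of a 2-D COP trajectory."""
    cop = np.atleast_2d(np.asarray(cop_xy, dtype=float))
    if cop.shape[0] < 2:
        raise ValueError("need at least 2 COP samples")
    centre = cop.mean(axis=0)
    amp = np.linalg.norm(cop - centre, axis=1)
    path = np.linalg.norm(np.diff(cop, axis=0), axis=1).sum()
    duration = (cop.shape[0] - 1) / rate
    return SwaySummary(
        sd_amp=float(np.std(amp, ddof=1)),
        sway_velocity=float(path / duration),
    )
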