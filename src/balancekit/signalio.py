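"""File formats and signal conditioning for the balance pipeline.

Containers
----------
:class:`TimeSeriesBlock`
    A labelled multichannel series at a fixed sampling rate (force-plate
    channels, platform displacement, COP components, ...).
:class:`MarkerTrajectorySet`
    Labelled 3-D marker positions over time, metres, lab frame.

Conditioning
------------
Zero-phase fourth-order low-pass Butterworth filtering (10 Hz default),
cubic-spline downsampling onto a common 100 Hz grid, and trimming of a
15-s trial to its middle 10 s anchored at the platform zero crossing where
the platform starts moving medially (centred window for static trials).

Formats
-------
TRC marker files (tab-separated, millimetres, standard DataRate header),
wide CSV marker files (``<marker>_X/_Y/_Z`` columns, metres), force-plate
CSV (``t,Fx,Fy,Fz,Mx,My,Mz``) and a cohort manifest CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt


class FormatError(ValueError):
    """A file does not parse under the requested dialect."""


class InvalidFilterError(ValueError):
    """Filter specification violates the Nyquist constraint."""


class InvalidResampleError(ValueError):
    """Requested resampling rate exceeds the source rate."""


class TrimError(ValueError):
    """No qualifying trim window exists in the trial."""


class GapError(ValueError):
    """A marker gap is too long to interpolate safely."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesBlock:
    """Channels-by-time samples at a fixed rate.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    rate : float
        Sampling rate in Hz, > 0.
    labels : list of str
        One label per channel.
    start_time : float
        Time of the first sample, seconds.
    """

    data: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sample rate must be > 0, got {self.rate}")
        if self.labels and len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels must match number of channels")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def window(self, win: "TrimWindow") -> "TimeSeriesBlock":
        """Slice the block to a trim window (start time follows the slice)."""
        return replace(
            self,
            data=self.data[:, win.start_index : win.end_index].copy(),
            start_time=self.start_time + win.start_index / self.rate,
        )


@dataclass
class MarkerTrajectorySet:
    """Labelled 3-D marker positions (metres, lab frame).

    ``positions`` has shape (n_frames, n_markers, 3) with marker order
    matching ``labels``.
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("positions second axis must match labels")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.rate

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        return self.positions[:, self.labels.index(label), :]

    def window(self, win: "TrimWindow") -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            labels=list(self.labels),
            positions=self.positions[win.start_index : win.end_index].copy(),
            rate=self.rate,
            start_time=self.start_time + win.start_index / self.rate,
        )

    def as_block(self) -> TimeSeriesBlock:
        """Flatten to a channels-by-time block (``<marker>_X/_Y/_Z`` labels)."""
        n_f, n_m, _ = self.positions.shape
        data = self.positions.transpose(1, 2, 0).reshape(n_m * 3, n_f)
        labels = [f"{m}_{ax}" for m in self.labels for ax in "XYZ"]
        return TimeSeriesBlock(data, self.rate, labels, self.start_time)

    @classmethod
    def from_block(cls, block: TimeSeriesBlock) -> "MarkerTrajectorySet":
        markers: list[str] = []
        for lab in block.labels:
            base = lab.rsplit("_", 1)[0]
            if base not in markers:
                markers.append(base)
        pos = np.empty((block.n_samples, len(markers), 3))
        for j, m in enumerate(markers):
            for k, ax in enumerate("XYZ"):
                pos[:, j, k] = block.channel(f"{m}_{ax}")
        return cls(markers, pos, block.rate, block.start_time)


@dataclass(frozen=True)
class TrimWindow:
    """Half-open 0-based sample window [start_index, end_index)."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(f"invalid window [{self.start_index}, {self.end_index})")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def butterworth_lowpass(
    block: TimeSeriesBlock, cutoff: float = 10.0, order: int = 4
) -> TimeSeriesBlock:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    The dual pass doubles the effective order and squares the magnitude
    response; no cutoff-frequency correction is applied, keeping kinematic
    and kinetic channels time-aligned.
    """
    nyq = block.rate / 2.0
    if cutoff >= nyq:
        raise InvalidFilterError(
            f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz"
        )
    if cutoff <= 0:
        raise InvalidFilterError("cutoff must be > 0")
    b, a = butter(order, cutoff / nyq, btype="low")
    return replace(block, data=filtfilt(b, a, block.data, axis=1))


def spline_downsample(block: TimeSeriesBlock, target_rate: float = 100.0) -> TimeSeriesBlock:
    """Cubic-spline resampling onto a grid aligned at ``start_time``.

    Output length is ``round(duration * target_rate)``; exact for
    polynomials of degree <= 3.
    """
    if target_rate <= 0:
        raise InvalidResampleError("target rate must be > 0")
    if target_rate > block.rate:
        raise InvalidResampleError(
            f"target rate {target_rate} Hz exceeds source rate {block.rate} Hz"
        )
    if target_rate == block.rate:
        return replace(block, data=block.data.copy())
    n_out = int(round(block.duration * target_rate))
    t_new = block.start_time + np.arange(n_out) / target_rate
    spl = CubicSpline(block.times, block.data, axis=1)
    return replace(block, data=spl(t_new), rate=target_rate)


def trim_to_middle_10s(
    n_samples: int,
    rate: float,
    platform_displacement: np.ndarray | None = None,
    side: str = "right",
    window_duration: float = 10.0,
) -> TrimWindow:
    """Locate the analysed 10-s window inside a longer trial.

    Moving condition (``platform_displacement`` given, lab-X metres,
    +X = subject's right): the window starts at the platform zero crossing
    where the platform begins moving medially — toward the body midline of
    the ``side`` stance foot, i.e. negative-going for a right stance and
    positive-going for a left stance — choosing the qualifying crossing
    nearest the centred start ``(duration - 10 s)/2`` (ties -> earlier).

    Static condition (no platform channel): the centred window.
    """
    win_n = int(round(window_duration * rate))
    if win_n > n_samples:
        raise TrimError(
            f"trial of {n_samples} samples shorter than {window_duration}-s window"
        )
    centred = (n_samples - win_n) / 2.0
    if platform_displacement is None:
        return TrimWindow(int(round(centred)), int(round(centred)) + win_n)

    x = np.asarray(platform_displacement, dtype=float)
    if x.shape[0] != n_samples:
        raise TrimError("platform channel length does not match trial length")
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    # medial = -X for right stance, +X for left stance
    want_negative_going = side == "right"
    if want_negative_going:
        cross = np.nonzero((x[:-1] >= 0) & (x[1:] < 0))[0]
    else:
        cross = np.nonzero((x[:-1] <= 0) & (x[1:] > 0))[0]
    starts = []
    for k in cross:
        denom = x[k + 1] - x[k]
        frac = -x[k] / denom if denom != 0 else 0.0
        idx = int(round(k + frac))
        if 0 <= idx <= n_samples - win_n:
            starts.append(idx)
    if not starts:
        raise TrimError("no medially-directed zero crossing leaves a full window")
    starts = np.array(sorted(starts))
    best = starts[np.argmin(np.abs(starts - centred))]  # argmin ties -> earlier
    return TrimWindow(int(best), int(best) + win_n)


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(markers: MarkerTrajectorySet, path) -> None:
    """Write a standard TRC file (tab-separated, millimetres)."""
    n_f, n_m = markers.n_frames, markers.n_markers
    rate = markers.rate
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{getattr(path, 'name', str(path))}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n_f}\t{n_m}\tmm\t{rate:g}\t1\t{n_f}",
        "Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_m)),
        "",
    ]
    mm = markers.positions * 1000.0
    times = markers.times
    rows = []
    for i in range(n_f):
        vals = "\t".join(f"{v:.6f}" for v in mm[i].ravel())
        rows.append(f"{i+1}\t{times[i]:.6f}\t{vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines + rows) + "\n")


def read_trc(path) -> MarkerTrajectorySet:
    """Read a TRC marker file; positions are converted to metres."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated TRC file ({len(lines)} lines)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"]
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed TRC header line 3: {exc}") from exc
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if scale is None:
        raise FormatError(f"{path}: unknown TRC unit {units!r} on line 3")
    label_cells = lines[3].split("\t")[2:]
    labels = [c for c in label_cells if c.strip()]
    if len(labels) != n_markers:
        raise FormatError(
            f"{path}: header declares {n_markers} markers, found {len(labels)} labels"
        )
    rows, times = [], []
    for ln_no, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2 + 3 * n_markers:
            raise FormatError(
                f"{path}: line {ln_no}: expected {2 + 3*n_markers} cells, got {len(cells)}"
            )
        try:
            times.append(float(cells[1]))
            rows.append([float(c) for c in cells[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln_no}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: TRC file contains no data rows")
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3) * scale
    return MarkerTrajectorySet(labels, pos, rate, start_time=times[0])


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def write_markers_csv(markers: MarkerTrajectorySet, path) -> None:
    """Write markers as a wide CSV (``time`` column + ``<marker>_X/_Y/_Z``, metres)."""
    block = markers.as_block()
    df = pd.DataFrame(block.data.T, columns=block.labels)
    df.insert(0, "time", markers.times)
    df.to_csv(path, index=False)


def read_markers_csv(path, max_gap: int = 10) -> MarkerTrajectorySet:
    """Read a wide marker CSV (metres); spline-fill short gaps.

    Runs of up to ``max_gap`` consecutive missing frames on a marker
    coordinate are filled by cubic-spline interpolation; a longer run is a
    hard :class:`GapError`.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if "time" not in df.columns or len(df) == 0:
        raise FormatError(f"{path}: wide marker CSV needs a 'time' column and data rows")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two frames")
    rate = 1.0 / np.median(np.diff(t))
    cols = [c for c in df.columns if c != "time"]
    data = df[cols].to_numpy(dtype=float).T
    for ci, col in enumerate(cols):
        y = data[ci]
        miss = np.isnan(y)
        if not miss.any():
            continue
        run = _longest_run(miss)
        if run > max_gap:
            raise GapError(
                f"{path}: column {col!r} has {run} consecutive missing frames "
                f"(limit {max_gap})"
            )
        if miss.all() or (~miss).sum() < 4:
            raise GapError(f"{path}: column {col!r} has too few observed frames")
        spl = CubicSpline(t[~miss], y[~miss])
        y[miss] = spl(t[miss])
    block = TimeSeriesBlock(data, rate, cols, start_time=t[0])
    return MarkerTrajectorySet.from_block(block)


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def read_markers(path, dialect: str) -> MarkerTrajectorySet:
    """Read markers under a named dialect (``'trc'`` or ``'wide-csv'``)."""
    if dialect == "trc":
        return read_trc(path)
    if dialect in ("wide-csv", "csv"):
        return read_markers_csv(path)
    raise FormatError(f"unknown marker dialect {dialect!r}")


# ---------------------------------------------------------------------------
# force-plate CSV and manifest
# ---------------------------------------------------------------------------

FORCE_CHANNELS = ["Fx", "Fy", "Fz", "Mx", "My", "Mz"]


def write_forces_csv(block: TimeSeriesBlock, path) -> None:
    df = pd.DataFrame(block.data.T, columns=block.labels)
    df.insert(0, "t", block.times)
    df.to_csv(path, index=False)


def read_forces_csv(path) -> TimeSeriesBlock:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in ["t"] + FORCE_CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing force columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    rate = 1.0 / np.median(np.diff(t))
    data = df[FORCE_CHANNELS].to_numpy(dtype=float).T
    return TimeSeriesBlock(data, rate, list(FORCE_CHANNELS), start_time=t[0])


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "group", "condition", "side", "trial"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
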