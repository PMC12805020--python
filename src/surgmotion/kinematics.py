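"""Motion-path parameters of an instrument-tip trajectory.

Six aggregate kinematic metrics are computed per instrument per case:

* **total path length** (px) — cumulative tip travel distance;
* **average velocity** (px/s) — mean per-step speed;
* **average acceleration** (px/s^2) — mean magnitude of the velocity
  finite difference;
* **RMS jerk** (px/s^3) — root-mean-square magnitude of the acceleration
  finite difference, a smoothness index (lower = smoother);
* **average angular change** (deg) — mean unsigned turning angle between
  consecutive displacement vectors;
* **workspace coverage** (px^2) — convex hull area of all tracked points.

Derivatives are vector finite differences at the frame timestep, converted
to time units by the fps factor. No displacement, angle or derivative is
ever taken across a tracking gap: motion while tracking was paused is
unobserved. Metrics undefined on a too-short track are reported as NaN,
never as 0.

Raw coordinates are differentiated as-is; an optional centered
moving-average pre-filter (`smooth_track`) is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .track_io import CaseRecord, InstrumentTrack, TrackSegment

__all__ = [
    "METRIC_NAMES",
    "CaseMetrics",
    "step_displacements",
    "total_path_length",
    "avg_velocity",
    "avg_acceleration",
    "rms_jerk",
    "angular_change",
    "workspace_coverage",
    "grid_workspace_coverage",
    "smooth_track",
    "case_metrics",
]

#: Canonical metric column order used throughout tables and reports.
METRIC_NAMES = (
    "path_length",
    "avg_velocity",
    "avg_acceleration",
    "rms_jerk",
    "avg_angular_change",
    "workspace_coverage",
)


@dataclass(frozen=True)
class CaseMetrics:
    """The six aggregated motion parameters for one (instrument, case)."""

    instrument: str
    case_number: int
    video_index: int
    path_length: float
    avg_velocity: float
    avg_acceleration: float
    rms_jerk: float
    avg_angular_change: float
    workspace_coverage: float
    n_points: int
    n_segments: int


def _segment_displacements(track: InstrumentTrack) -> list[np.ndarray]:
    """Per-segment displacement arrays (k-1, 2); gaps contribute nothing."""
    return [np.diff(seg.xy, axis=0) for seg in track.segments if len(seg) >= 2]


def step_displacements(track: InstrumentTrack) -> np.ndarray:
    """All per-step displacement vectors (px/frame) as an (m, 2) array.

    One displacement per consecutive frame pair within a segment; none
    spans a gap between segments.
    """
    per_seg = _segment_displacements(track)
    if not per_seg:
        return np.empty((0, 2))
    return np.concatenate(per_seg, axis=0)


def total_path_length(track: InstrumentTrack) -> float:
    """Cumulative Euclidean distance traveled by the tip, in pixels."""
    d = step_displacements(track)
    return float(np.hypot(d[:, 0], d[:, 1]).sum()) if d.size else 0.0


def avg_velocity(track: InstrumentTrack) -> float:
    """Mean per-step speed in px/s; NaN when the track has no displacement."""
    d = step_displacements(track)
    if d.shape[0] == 0:
        return math.nan
    return float(np.hypot(d[:, 0], d[:, 1]).mean() * track.fps)


def _segment_accels(track: InstrumentTrack) -> list[np.ndarray]:
    out = []
    for d in _segment_displacements(track):
        if d.shape[0] >= 2:
            v = d * track.fps
            out.append(np.diff(v, axis=0) * track.fps)
    return out


def avg_acceleration(track: InstrumentTrack) -> float:
    """Mean magnitude of the velocity finite difference, px/s^2.

    Requires at least two consecutive displacements within some segment;
    NaN otherwise.
    """
    accs = _segment_accels(track)
    if not accs:
        return math.nan
    a = np.concatenate(accs, axis=0)
    return float(np.hypot(a[:, 0], a[:, 1]).mean())


def rms_jerk(track: InstrumentTrack) -> float:
    """Root-mean-square magnitude of the acceleration finite difference,
    px/s^3. Requires >= 3 consecutive displacements in some segment."""
    jerks = []
    for a in _segment_accels(track):
        if a.shape[0] >= 2:
            jerks.append(np.diff(a, axis=0) * track.fps)
    if not jerks:
        return math.nan
    j = np.concatenate(jerks, axis=0)
    return float(np.sqrt((j ** 2).sum(axis=1).mean()))


def angular_change(track: InstrumentTrack) -> tuple[float, float]:
    """(total, average) unsigned turning angle in degrees.

    At each interior vertex of a segment, the angle in [0, 180] between the
    incoming and outgoing displacement vectors. Vertices where either
    vector has zero length are skipped and excluded from the average's
    denominator. Returns (NaN, NaN) when no valid vertex exists.
    """
    angles: list[np.ndarray] = []
    for d in _segment_displacements(track):
        if d.shape[0] < 2:
            continue
        u, v = d[:-1], d[1:]
        nu = np.hypot(u[:, 0], u[:, 1])
        nv = np.hypot(v[:, 0], v[:, 1])
        ok = (nu > 0) & (nv > 0)
        if not ok.any():
            continue
        u, v = u[ok], v[ok]
        dot = (u * v).sum(axis=1)
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        # atan2 form is numerically stable near 0 and 180 degrees
        angles.append(np.degrees(np.arctan2(np.abs(cross), dot)))
    if not angles:
        return math.nan, math.nan
    all_angles = np.concatenate(angles)
    total = float(all_angles.sum())
    return total, total / all_angles.size


def workspace_coverage(track: InstrumentTrack) -> float:
    """Convex hull area (px^2) of all tracked points across segments.

    Fewer than 3 distinct points, or a collinear cloud, yields 0.
    """
    pts = np.unique(track.all_xy(), axis=0)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0  # degenerate (collinear) cloud


def grid_workspace_coverage(track: InstrumentTrack, cell: float = 10.0) -> float:
    """Occupancy-grid alternative to the hull: number of visited
    ``cell``-sized pixels cells times the cell area. For sensitivity
    analysis of the workspace definition; not used by default."""
    pts = track.all_xy()
    if pts.size == 0:
        return 0.0
    cells = np.unique(np.floor(pts / cell).astype(np.int64), axis=0)
    return float(cells.shape[0] * cell * cell)


def smooth_track(track: InstrumentTrack, window: int = 3) -> InstrumentTrack:
    """Centered moving-average pre-filter applied per segment.

    Off by default in all pipelines; provided for sensitivity analysis of
    differentiation noise. Segments shorter than ``window`` pass through.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    segs = []
    half = window // 2
    for seg in track.segments:
        if len(seg) < window:
            segs.append(TrackSegment(seg.frames.copy(), seg.xy.copy()))
            continue
        kern = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(seg.xy[:, k], kern, mode="valid") for k in (0, 1)]
        )
        segs.append(TrackSegment(seg.frames[half:-half], sm))
    return InstrumentTrack(
        instrument=track.instrument,
        segments=segs,
        fps=track.fps,
        frame_width=track.frame_width,
        frame_height=track.frame_height,
    )


def track_metrics(track: InstrumentTrack, case_number: int, video_index: int) -> CaseMetrics:
    """All six metrics for one track, with NaN markers where undefined."""
    _, avg_ang = angular_change(track) if track.n_points else (math.nan, math.nan)
    return CaseMetrics(
        instrument=track.instrument,
        case_number=case_number,
        video_index=video_index,
        path_length=total_path_length(track),
        avg_velocity=avg_velocity(track),
        avg_acceleration=avg_acceleration(track),
        rms_jerk=rms_jerk(track),
        avg_angular_change=avg_ang,
        workspace_coverage=workspace_coverage(track),
        n_points=track.n_points,
        n_segments=len(track.segments),
    )


def case_metrics(record: CaseRecord) -> list[CaseMetrics]:
    """One :class:`CaseMetrics` per instrument track in the case."""
    return [
        track_metrics(t, record.case_number, record.video_index)
        for t in record.tracks
    ]
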