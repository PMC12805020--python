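"""Reading, validating and writing instrument-tip trajectories.

The canonical interchange format is a plain CSV with one row per tracked
frame and columns ``case_number, video_index, instrument, frame, x, y``.
Coordinates are 0-based pixel centers, origin at the top-left of the video
frame, x rightward (column) and y downward (row) — the convention of
point-annotation exports from video annotation tools.

A pause in tracking (instrument out of view, tip not localizable) is
represented purely by a gap in the frame index; consecutive frames within
one uninterrupted run form a :class:`TrackSegment`. No sentinel rows are
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

from .exceptions import FormatError, ValidationError

__all__ = [
    "CANONICAL_INSTRUMENTS",
    "TRACK_COLUMNS",
    "TrackPoint",
    "TrackSegment",
    "InstrumentTrack",
    "CaseRecord",
    "segment_frames",
    "read_tracks",
    "write_tracks",
    "read_cvat_points",
]

#: The 11 instrument classes tracked in a standard phacoemulsification
#: cataract procedure. The vocabulary is extensible: unknown labels warn
#: but are passed through.
CANONICAL_INSTRUMENTS: tuple[str, ...] = (
    "sideport_knife",
    "forceps",
    "cannula",
    "keratome",
    "cystotome",
    "phaco_handpiece",
    "chopper",
    "ia_handpiece",
    "lens_injector",
    "iol_inserter",
    "weckcel_sponge",
)

TRACK_COLUMNS = ("case_number", "video_index", "instrument", "frame", "x", "y")

DEFAULT_FPS = 15.0
DEFAULT_FRAME_WIDTH = 1920
DEFAULT_FRAME_HEIGHT = 1080


@dataclass(frozen=True)
class TrackPoint:
    """One tracked tip position: frame index (0-based) and pixel coordinates."""

    frame: int
    x: float
    y: float


@dataclass
class TrackSegment:
    """One uninterrupted tracked run: frame indices increase by exactly 1.

    Stored columnar (``frames`` int array, ``xy`` (n, 2) float array) for
    vectorized kinematics; :attr:`points` offers the row view.
    """

    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValidationError("segment frames and xy shapes are inconsistent")
        if self.frames.size < 1:
            raise ValidationError("a segment needs at least one point")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValidationError("frames within a segment must increase by exactly 1")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(f), float(x), float(y))
            for f, (x, y) in zip(self.frames, self.xy)
        ]


@dataclass
class InstrumentTrack:
    """All tracked segments for one instrument within one surgical case."""

    instrument: str
    segments: list[TrackSegment] = field(default_factory=list)
    fps: float = DEFAULT_FPS
    frame_width: int = DEFAULT_FRAME_WIDTH
    frame_height: int = DEFAULT_FRAME_HEIGHT

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        last_end = -1
        for seg in self.segments:
            if seg.frames[0] <= last_end:
                raise ValidationError(
                    f"segments of {self.instrument!r} overlap or are unordered"
                )
            last_end = int(seg.frames[-1])

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.segments)

    def all_xy(self) -> np.ndarray:
        """All tip coordinates across segments as one (n, 2) array."""
        if not self.segments:
            return np.empty((0, 2))
        return np.concatenate([s.xy for s in self.segments], axis=0)


@dataclass
class CaseRecord:
    """One surgical case: its case number, position in the recorded video
    series, and the instrument tracks observed in it."""

    case_number: int
    video_index: int
    tracks: list[InstrumentTrack] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.case_number < 1 or self.video_index < 1:
            raise ValidationError("case_number and video_index must be >= 1")
        labels = [t.instrument for t in self.tracks]
        if len(labels) != len(set(labels)):
            raise ValidationError(
                f"case {self.case_number}: more than one track per instrument"
            )


def segment_frames(frames: np.ndarray, xy: np.ndarray) -> list[TrackSegment]:
    """Split a frame-sorted point sequence into contiguous segments.

    A new segment starts wherever the frame gap exceeds 1. Idempotent on
    already-contiguous input and conserves the total point count.
    """
    frames = np.asarray(frames, dtype=np.int64)
    xy = np.asarray(xy, dtype=np.float64)
    if frames.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(frames) != 1) + 1
    return [
        TrackSegment(f, p)
        for f, p in zip(np.split(frames, breaks), np.split(xy, breaks))
    ]


def _check_bounds(xy: np.ndarray, width: int, height: int, context: str) -> None:
    # Edge annotations are legitimate; out-of-bounds warns rather than fails.
    if xy.size and (
        xy[:, 0].min() < 0
        or xy[:, 0].max() > width
        or xy[:, 1].min() < 0
        or xy[:, 1].max() > height
    ):
        warnings.warn(
            f"{context}: coordinates outside the {width}x{height} frame",
            stacklevel=3,
        )


def read_tracks(
    path,
    fps: float = DEFAULT_FPS,
    frame_geom: tuple[int, int] = (DEFAULT_FRAME_WIDTH, DEFAULT_FRAME_HEIGHT),
) -> list[CaseRecord]:
    """Read a canonical trajectory CSV into case records.

    Parameters
    ----------
    path
        CSV with columns ``case_number, video_index, instrument, frame, x, y``.
    fps
        Recording frame rate attached to every track (frames/second).
    frame_geom
        ``(width, height)`` of the video frame in pixels.

    Returns
    -------
    list of CaseRecord, sorted by case number. Rows are grouped per
    (case, instrument); frame gaps > 1 split tracks into segments.
    """
    # round_trip parser: the canonical CSV stores full float reprs and a
    # read-back must reproduce them bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    width, height = frame_geom
    records: list[CaseRecord] = []
    if df.empty:
        return records
    known = set(CANONICAL_INSTRUMENTS)
    for case_number, case_df in df.groupby("case_number", sort=True):
        vidx = case_df["video_index"].unique()
        if vidx.size > 1:
            raise ValidationError(
                f"case {case_number}: conflicting video_index values {sorted(vidx)}"
            )
        tracks = []
        for instrument, g in case_df.groupby("instrument", sort=True):
            if instrument not in known:
                warnings.warn(
                    f"unknown instrument label {instrument!r}; keeping it",
                    stacklevel=2,
                )
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy(dtype=np.int64)
            if np.any(np.diff(frames) <= 0):
                raise ValidationError(
                    f"case {case_number}, {instrument}: duplicate or "
                    "non-increasing frame indices"
                )
            if frames[0] < 0:
                raise ValidationError(
                    f"case {case_number}, {instrument}: negative frame index"
                )
            xy = g[["x", "y"]].to_numpy(dtype=np.float64)
            _check_bounds(xy, width, height, f"case {case_number}, {instrument}")
            tracks.append(
                InstrumentTrack(
                    instrument=str(instrument),
                    segments=segment_frames(frames, xy),
                    fps=fps,
                    frame_width=width,
                    frame_height=height,
                )
            )
        records.append(
            CaseRecord(
                case_number=int(case_number),
                video_index=int(vidx[0]),
                tracks=tracks,
            )
        )
    return records


def tracks_to_frame(records: list[CaseRecord]) -> pd.DataFrame:
    """Flatten case records to the canonical one-row-per-frame table."""
    rows = []
    for rec in sorted(records, key=lambda r: r.case_number):
        for track in sorted(rec.tracks, key=lambda t: t.instrument):
            for seg in track.segments:
                for f, (x, y) in zip(seg.frames, seg.xy):
                    rows.append(
                        (rec.case_number, rec.video_index, track.instrument,
                         int(f), float(x), float(y))
                    )
    return pd.DataFrame(rows, columns=list(TRACK_COLUMNS))


def write_tracks(records: list[CaseRecord], path) -> None:
    """Write case records as the canonical CSV.

    Row order is deterministic (case, instrument, frame); floats are
    rendered with ``repr`` so a read-back reproduces them exactly. Cases
    with no tracks contribute no rows.
    """
    df = tracks_to_frame(records)
    df.to_csv(path, index=False)


def read_cvat_points(path, label_map: dict[str, str]) -> list[InstrumentTrack]:
    """Ingest a CVAT XML point-annotation export.

    Each ``<track>`` whose label appears in ``label_map`` becomes one
    :class:`InstrumentTrack`; frames marked ``outside="1"`` break the run
    into segments (tracking paused). Labels absent from ``label_map`` are
    collected and reported in a single warning, then skipped.

    Returns the tracks in document order.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed CVAT XML: {exc}") from exc
    tracks: list[InstrumentTrack] = []
    skipped: list[str] = []
    for node in tree.iter("track"):
        label = node.get("label", "")
        if label not in label_map:
            skipped.append(label)
            continue
        frames, xs, ys = [], [], []
        for pt in node.iter("points"):
            if pt.get("outside") == "1":
                frames.append(None)  # break marker
                continue
            x, y = pt.get("points", "").split(";")[0].split(",")[:2]
            frames.append(int(pt.get("frame")))
            xs.append(float(x))
            ys.append(float(y))
        # rebuild contiguous segments, honoring explicit outside breaks
        segments: list[TrackSegment] = []
        cur_f: list[int] = []
        cur_xy: list[tuple[float, float]] = []
        it = iter(zip(xs, ys))
        prev = None
        for f in frames:
            if f is None:
                if cur_f:
                    segments.append(TrackSegment(np.array(cur_f), np.array(cur_xy)))
                    cur_f, cur_xy = [], []
                prev = None
                continue
            x, y = next(it)
            if prev is not None and f != prev + 1 and cur_f:
                segments.append(TrackSegment(np.array(cur_f), np.array(cur_xy)))
                cur_f, cur_xy = [], []
            cur_f.append(f)
            cur_xy.append((x, y))
            prev = f
        if cur_f:
            segments.append(TrackSegment(np.array(cur_f), np.array(cur_xy)))
        tracks.append(
            InstrumentTrack(instrument=label_map[label], segments=segments)
        )
    if skipped:
        warnings.warn(
            "skipped CVAT labels not in label_map: " + ", ".join(sorted(set(skipped))),
            stacklevel=2,
        )
    return tracks
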