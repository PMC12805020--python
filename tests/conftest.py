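import numpy as np
import pytest

from surgmotion.track_io import (
    CaseRecord,
    InstrumentTrack,
    segment_frames,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_track(coords, fps=15.0, start_frame=0, instrument="cannula",
               gaps_after=()):
    """Build an InstrumentTrack from a coordinate list, optionally inserting
    a frame gap after the given 0-based point indices."""
    coords = np.asarray(coords, dtype=float)
    frames = np.arange(start_frame, start_frame + len(coords), dtype=np.int64)
    bump = np.zeros(len(coords), dtype=np.int64)
    for g in gaps_after:
        bump[g + 1:] += 3
    frames = frames + bump
    return InstrumentTrack(
        instrument=instrument,
        segments=segment_frames(frames, coords),
        fps=fps,
    )


def random_track(rng, n_points=50, n_gaps=2, fps=15.0, scale=40.0,
                 instrument="cannula"):
    coords = np.cumsum(rng.normal(0, scale / 10, size=(n_points, 2)), axis=0) + 500
    gaps = sorted(rng.choice(np.arange(1, n_points - 2), size=n_gaps, replace=False)) if n_gaps else []
    return make_track(coords, fps=fps, gaps_after=gaps, instrument=instrument)


def random_records(rng, n_cases=4, instruments=("cannula", "forceps")):
    records = []
    case_numbers = np.sort(rng.choice(np.arange(1, 200), size=n_cases, replace=False))
    for vidx, case in enumerate(case_numbers, start=1):
        tracks = [
            random_track(rng, n_points=int(rng.integers(5, 25)),
                         n_gaps=int(rng.integers(0, 3)), instrument=ins)
            for ins in instruments
        ]
        records.append(CaseRecord(case_number=int(case), video_index=vidx,
                                  tracks=tracks))
    return records


@pytest.fixture
def l_track():
    """The 3-point L-shaped track: (0,0) -> (1,0) -> (1,1)."""
    return make_track([(0, 0), (1, 0), (1, 1)])
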