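"""Surrogate learning-curve data with the statistical structure the
analysis assumes.

Real tip trajectories from the study setting are not redistributable, so
this module generates stand-ins at two levels:

1. **Trajectory level** — a correlated random walk per (instrument, case):
   step lengths from a gamma distribution whose scale decays exponentially
   with case number (practice shortens travel), turning angles from a von
   Mises distribution whose concentration rises with case number (practice
   straightens motion), random tracking pauses inserted as frame gaps, and
   an optional abrupt step-scale multiplier past a change-point case.
   Feeding these through the kinematics layer exercises the full pipeline.

2. **Metric level** — per-case metric values generated directly as
   y_c = base * (1 + trend * (c - c_min)) * (1 + shift * 1[c > tau]) * eps_c
   with lognormal noise eps_c, giving exact ground truth for testing the
   statistics layer in isolation.

The default configuration emulates the acquisition design the analysis is
meant for: 100 videos of a single trainee spanning surgical cases 6-760,
11 instrument classes, 15 frames/s, a 1920x1080 px frame, monotone decaying
motion metrics with case-level noise. Default trend magnitudes put the
percent change per 10 videos in the -2% .. -12% band — a plausible learning
curve, not a reproduction of any particular surgeon.

All randomness flows through ``numpy.random.Generator`` (PCG64) seeded from
the config, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigError
from .track_io import (
    CANONICAL_INSTRUMENTS,
    CaseRecord,
    InstrumentTrack,
    segment_frames,
)

__all__ = [
    "InstrumentSimParams",
    "SimConfig",
    "sample_case_schedule",
    "generate_trajectory",
    "generate_case",
    "generate_dataset",
    "generate_metric_series",
]


@dataclass
class InstrumentSimParams:
    """Correlated-random-walk parameters for one instrument class.

    step_scale
        Baseline mean step length s0 in px/frame at the first case.
    step_trend
        Exponential rate beta (1/case): s(c) = s0 * exp(beta * (c - c_min)).
        Negative values shorten steps over training.
    kappa0, kappa_trend
        Von Mises turning-angle concentration kappa(c) = kappa0 *
        exp(kappa_trend * (c - c_min)); rising concentration means
        straighter motion (smaller angular change).
    pause_prob
        Per-frame probability that tracking pauses (a frame gap starts).
    n_frames
        Number of tracked frames per case for this instrument.
    changepoint_case, changepoint_mult
        Past case ``changepoint_case`` the step scale is multiplied by
        ``changepoint_mult`` (None disables the shift).
    noise_sigma
        Lognormal sigma of a per-case multiplier on the step scale,
        modelling case-to-case variability (case difficulty, anatomy).
    """

    step_scale: float = 6.0
    step_trend: float = -0.0011
    kappa0: float = 1.0
    kappa_trend: float = 0.0011
    pause_prob: float = 0.002
    n_frames: int = 1500
    changepoint_case: int | None = None
    changepoint_mult: float = 1.0
    noise_sigma: float = 0.15


@dataclass
class SimConfig:
    """Full parameterization of the synthetic learning-curve generator."""

    n_videos: int = 100
    case_range: tuple[int, int] = (6, 760)
    fps: float = 15.0
    frame_width: int = 1920
    frame_height: int = 1080
    instruments: dict[str, InstrumentSimParams] = field(
        default_factory=lambda: {
            name: InstrumentSimParams() for name in CANONICAL_INSTRUMENTS
        }
    )
    schedule_skew: float = 0.0  # >0 front-loads recordings toward early cases
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.case_range
        if hi <= lo:
            raise ConfigError("case_range must be increasing")
        if self.n_videos < 4:
            raise ConfigError("n_videos must be >= 4")
        if hi - lo + 1 < self.n_videos:
            raise ConfigError(
                f"case range {self.case_range} cannot hold {self.n_videos} "
                "distinct cases"
            )
        for name, p in self.instruments.items():
            if p.changepoint_mult <= 0:
                raise ConfigError(f"{name}: changepoint_mult must be > 0")
            if p.noise_sigma < 0:
                raise ConfigError(f"{name}: noise_sigma must be >= 0")


def sample_case_schedule(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw the recorded-video schedule: n_videos distinct case numbers.

    Cases are drawn without replacement from the configured range with
    weights proportional to exp(-skew * u), u the normalized position in
    the range; skew = 0 gives uniform spacing in expectation, skew > 0
    concentrates recordings in the early/middle phase of training.

    Returns a list of ``(video_index, case_number)`` sorted by case number.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.case_range
    candidates = np.arange(lo, hi + 1)
    u = (candidates - lo) / max(hi - lo, 1)
    w = np.exp(-cfg.schedule_skew * u)
    w /= w.sum()
    cases = np.sort(rng.choice(candidates, size=cfg.n_videos, replace=False, p=w))
    return [(i + 1, int(c)) for i, c in enumerate(cases)]


def generate_trajectory(
    case_number: int,
    params: InstrumentSimParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    instrument: str = "cannula",
) -> InstrumentTrack:
    """One correlated-random-walk tip trajectory for one case.

    The walk starts near the frame center, draws step lengths from a
    gamma(2, s(c)/2) distribution (mean s(c)) and headings as a cumulative
    sum of von Mises turning angles; it reflects off the frame borders so
    coordinates stay inside the frame. Pauses appear as frame-index gaps
    of geometric length, splitting the track into segments.
    """
    lo, _ = cfg.case_range
    dc = case_number - lo
    scale = params.step_scale * float(np.exp(params.step_trend * dc))
    if params.changepoint_case is not None and case_number > params.changepoint_case:
        scale *= params.changepoint_mult
    if params.noise_sigma > 0:
        scale *= float(rng.lognormal(0.0, params.noise_sigma))
    kappa = params.kappa0 * float(np.exp(params.kappa_trend * dc))

    n = params.n_frames
    steps = rng.gamma(shape=2.0, scale=scale / 2.0, size=n - 1)
    turns = rng.vonmises(0.0, kappa, size=n - 1)
    headings = rng.uniform(0, 2 * np.pi) + np.cumsum(turns)
    dx = steps * np.cos(headings)
    dy = steps * np.sin(headings)
    pos = np.empty((n, 2))
    pos[0] = (cfg.frame_width / 2.0, cfg.frame_height / 2.0)
    pos[1:, 0] = pos[0, 0] + np.cumsum(dx)
    pos[1:, 1] = pos[0, 1] + np.cumsum(dy)
    # reflect off borders (triangle-wave fold keeps the walk inside)
    for k, size in ((0, cfg.frame_width), (1, cfg.frame_height)):
        m = pos[:, k] % (2.0 * size)
        pos[:, k] = np.where(m <= size, m, 2.0 * size - m)

    # insert tracking pauses as frame gaps
    frames = np.arange(n, dtype=np.int64)
    if params.pause_prob > 0:
        pauses = rng.random(n - 1) < params.pause_prob
        gap_at = np.flatnonzero(pauses) + 1
        if gap_at.size:
            gaps = rng.geometric(0.2, size=gap_at.size) + 1
            offset = np.zeros(n, dtype=np.int64)
            np.add.at(offset, gap_at, gaps)
            frames = frames + np.cumsum(offset)

    return InstrumentTrack(
        instrument=instrument,
        segments=segment_frames(frames, pos),
        fps=cfg.fps,
        frame_width=cfg.frame_width,
        frame_height=cfg.frame_height,
    )


def generate_case(
    case_number: int,
    video_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> CaseRecord:
    """One synthetic case with a track for every configured instrument."""
    tracks = [
        generate_trajectory(case_number, params, cfg, rng, instrument=name)
        for name, params in cfg.instruments.items()
    ]
    return CaseRecord(case_number=case_number, video_index=video_index, tracks=tracks)


def generate_dataset(cfg: SimConfig) -> tuple[list[CaseRecord], dict]:
    """The full synthetic study: schedule + trajectories + ground truth.

    Returns ``(records, truth)`` where ``truth`` records the seed, the
    schedule and the per-instrument generating parameters, for recovery
    scoring against the analysis output.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = sample_case_schedule(cfg, rng)
    records = [
        generate_case(case, vidx, cfg, rng) for vidx, case in schedule
    ]
    truth = {
        "seed": cfg.seed,
        "schedule": [{"video_index": v, "case_number": c} for v, c in schedule],
        "instruments": {
            name: asdict(p) for name, p in cfg.instruments.items()
        },
    }
    return records, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)


def generate_metric_series(
    trend: float,
    base: float,
    schedule,
    tau: int | None = None,
    shift: float = 0.0,
    sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct per-case metric series with known ground truth.

    y_c = base * (1 + trend*(c - c_min)) * (1 + shift*1[c > tau]) * eps_c,
    eps_c ~ lognormal(0, sigma). ``schedule`` is a sequence of case
    numbers or of (video_index, case_number) pairs.

    Returns ``(case_numbers, y)``.

    Raises
    ------
    ConfigError
        If base <= 0 or the trend drives the noiseless mean nonpositive
        anywhere in the schedule range.
    """
    if base <= 0:
        raise ConfigError("base level must be positive")
    sched = np.asarray(schedule)
    cases = sched[:, 1] if sched.ndim == 2 else sched
    cases = np.sort(cases.astype(np.int64))
    cmin = cases.min()
    mean = base * (1.0 + trend * (cases - cmin))
    if tau is not None:
        mean = mean * np.where(cases > tau, 1.0 + shift, 1.0)
    if np.any(mean <= 0):
        raise ConfigError(
            "trend/shift drive the metric nonpositive within the schedule"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.lognormal(0.0, sigma, size=cases.size) if sigma > 0 else 1.0
    return cases, mean * eps
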