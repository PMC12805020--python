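"""Compute the six motion-path parameters for a single tracked trajectory.

A small hand-built track demonstrates each metric's meaning; segment gaps
(tracking pauses) never contribute displacements.
"""

import numpy as np

from surgmotion import InstrumentTrack, segment_frames
from surgmotion.kinematics import track_metrics

# an L-shaped move, a pause (frames 3-9 untracked), then a straight dash
frames = np.array([0, 1, 2, 10, 11, 12, 13])
xy = np.array([(100, 100), (150, 100), (150, 150),
               (400, 400), (430, 400), (460, 400), (490, 400)], dtype=float)

track = InstrumentTrack(
    instrument="cystotome",
    segments=segment_frames(frames, xy),
    fps=15.0,
)
m = track_metrics(track, case_number=42, video_index=7)

print(f"segments: {m.n_segments} (the frame gap splits the track)")
print(f"path length        {m.path_length:8.1f} px   (pause jump excluded)")
print(f"avg velocity       {m.avg_velocity:8.1f} px/s")
print(f"avg acceleration   {m.avg_acceleration:8.1f} px/s^2")
print(f"rms jerk           {m.rms_jerk:8.1f} px/s^3 (0 = perfectly smooth)")
print(f"avg angular change {m.avg_angular_change:8.1f} deg  "
      "(one 90-deg turn averaged over 3 vertices)")
print(f"workspace coverage {m.workspace_coverage:8.1f} px^2 (convex hull area)")
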