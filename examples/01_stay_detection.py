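"""Detect stays in a small hand-built GPS trajectory.

A stay is a run of points that remain within 50 m of where the run began
for at least 5 minutes.  The trajectory below visits two places with a
walk in between; the detector should find exactly two stays.
"""

import pandas as pd

import hazsense as hz
from hazsense.geo import offset_lonlat

ORIGIN = (-0.1276, 51.5072)  # central London

# (east_m, north_m, seconds): two dwells separated by fast movement
track = [
    (0, 0, 0), (8, 5, 200), (-6, 3, 420),            # dwell at the origin
    (150, 0, 520), (350, 0, 620),                    # walking away
    (600, 0, 720), (592, 7, 950), (605, -5, 1200),   # dwell 600 m east
    (1200, 0, 1350),                                 # leaving again
]

rows = []
for x, y, t in track:
    lon, lat = offset_lonlat(*ORIGIN, x, y)
    rows.append(("alice", pd.Timestamp("2020-02-03 09:00:00") + pd.Timedelta(seconds=t), lon, lat))
points = pd.DataFrame(rows, columns=["user_id", "timestamp", "longitude", "latitude"])

stays = hz.detect_stays(points, hz.StayParams(d_max_m=50, t_min_s=300))
print(stays[["start_time", "duration_s", "n_points"]].to_string(index=False))
print(f"\n{len(stays)} stays: each lasted >= 300 s within a 50 m radius; "
      "the walk between them never pauses long enough to count.")
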