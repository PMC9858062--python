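"""Independent exhaustive-window oracle for stay detection.

Enumerates every index window [i, j], keeps those whose members all lie
within d_max of the window's first point and whose time span is at least
t_min, and selects maximal non-overlapping windows left to right.  It is a
brute-force reference kept deliberately separate from the package's greedy
scan.
"""

from hazsense.geo import haversine_m


def oracle_windows(lon, lat, t_seconds, d_max, t_min):
    """Return [(i, j), ...] index windows of the stays a brute-force scan finds."""
    m = len(lon)
    valid = []
    for i in range(m):
        for j in range(i + 1, m):
            if all(haversine_m(lon[i], lat[i], lon[k], lat[k]) <= d_max for k in range(i, j + 1)):
                if t_seconds[j] - t_seconds[i] >= t_min:
                    valid.append((i, j))
            else:
                break  # window broken; longer j cannot repair it
    chosen = []
    pos = 0
    while True:
        candidates = [(i, j) for i, j in valid if i >= pos]
        if not candidates:
            return chosen
        start = min(i for i, _ in candidates)
        end = max(j for i, j in candidates if i == start)
        chosen.append((start, end))
        pos = end + 1
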