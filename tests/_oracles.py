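"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — O(cells x edges) distance scans,
full enumeration of sign/group assignments — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# geometry: exhaustive signed distance to a polygon set
# ---------------------------------------------------------------------------

def _point_segment_distance(px, py, ax, ay, bx, by):
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    vv = vx * vx + vy * vy
    t = 0.0 if vv == 0 else max(0.0, min(1.0, (wx * vx + wy * vy) / vv))
    dx, dy = px - (ax + t * vx), py - (ay + t * vy)
    return math.hypot(dx, dy)


def _point_in_polygon(px, py, coords):
    # even-odd crossing number
    inside = False
    n = len(coords)
    for i in range(n):
        ax, ay = coords[i]
        bx, by = coords[(i + 1) % n]
        if (ay > py) != (by > py):
            xcross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < xcross:
                inside = not inside
    return inside


def brute_force_signed_distance(point, polygons):
    """Signed distance of one point to a list of polygon coordinate rings."""
    px, py = point
    d = math.inf
    for coords in polygons:
        n = len(coords)
        for i in range(n):
            ax, ay = coords[i]
            bx, by = coords[(i + 1) % n]
            d = min(d, _point_segment_distance(px, py, ax, ay, bx, by))
    inside = any(_point_in_polygon(px, py, coords) for coords in polygons)
    return -d if inside else d


def brute_force_region_labels(points, polygons, band_width):
    labels = []
    for p in points:
        d = brute_force_signed_distance(p, polygons)
        if d < 0:
            labels.append("TC")
        elif d < band_width:
            labels.append("TF")
        else:
            labels.append("PT")
    return np.array(labels, dtype=object)


# ---------------------------------------------------------------------------
# exact Wilcoxon tests by full enumeration
# ---------------------------------------------------------------------------

def _rankdata(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def enumerate_signed_rank_p(a, b):
    """Two-sided exact p over all 2^n sign assignments (zero diffs dropped)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0, 0.0
    ranks = _rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    le = ge = 0
    total = 0
    for signs in itertools.product((1, -1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(le, ge) / total), w_obs


def enumerate_rank_sum_p(a, b):
    """Two-sided exact p over all C(m+n, m) group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = len(a)
    joint = np.concatenate([a, b])
    ranks = _rankdata(joint)
    ra_obs = ranks[:m].sum()
    u_obs = ra_obs - m * (m + 1) / 2.0
    le = ge = total = 0
    for idx in itertools.combinations(range(len(joint)), m):
        ra = ranks[list(idx)].sum()
        le += ra <= ra_obs + 1e-9
        ge += ra >= ra_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(le, ge) / total), u_obs
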