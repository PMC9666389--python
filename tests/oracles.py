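"""Independent reference implementations used only as test oracles.

These deliberately take different computational routes from the package:
the Clarke oracle is the published rule set written as inequalities, the
Parkes oracle interpolates the published boundary polylines, and the
pairing oracle is an exhaustive O(n*m) scan.
"""

from __future__ import annotations

import numpy as np

MGDL = 18.016


def clarke_zone_rules(ref_mgdl: float, pred_mgdl: float) -> str:
    """Published Clarke rule set (reference, predicted in mg/dL)."""
    r, p = ref_mgdl, pred_mgdl
    if (r <= 70 and p <= 70) or (0.8 * r <= p <= 1.2 * r):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 1.4 * r - 182):
        return "C"
    if (r >= 240 and 70 <= p <= 180) or (r <= 175 / 3 and 70 <= p <= 180) or (
        175 / 3 <= r <= 70 and p >= 1.2 * r
    ):
        return "D"
    return "B"


# Parkes type-1 boundary polylines (mg/dL), measured-above-reference side
# then measured-below-reference side, from the published vertex lists.
_PARKES_UPPER = {
    "B": [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550), (550, 550)],
    "C": [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550), (550, 550)],
    "D": [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550), (550, 550)],
    "E": [(0, 150), (35, 155), (50, 550), (550, 550)],
}
_PARKES_LOWER = {
    "B": [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)],
    "C": [(120, 0), (120, 30), (260, 130), (550, 250)],
    "D": [(250, 0), (250, 40), (550, 150)],
}


def _polyline_y(polyline, x):
    xs = np.array([p[0] for p in polyline], dtype=float)
    ys = np.array([p[1] for p in polyline], dtype=float)
    if x < xs[0]:
        return ys[0]
    return float(np.interp(x, xs, ys))


def parkes_zone_polylines(ref_mgdl: float, pred_mgdl: float) -> str:
    """Zone by comparing the point against the boundary polylines."""
    x, y = ref_mgdl, pred_mgdl
    if y >= x:  # above or on the identity line: check upper boundaries
        zone = "A"
        for z in ("B", "C", "D", "E"):
            if y > _polyline_y(_PARKES_UPPER[z], x):
                zone = z
        return zone
    zone = "A"
    for z in ("B", "C", "D"):
        if y < _polyline_y(_PARKES_LOWER[z], x):
            zone = z
    return zone


def brute_force_pairs(smbg_times, cgm_times, window_s):
    """For each SMBG time, index of the matched CGM reading or None.

    Exhaustive scan over every (SMBG, CGM) combination; tie at equal |dt|
    resolved toward the earlier CGM reading.
    """
    out = []
    for t in smbg_times:
        best = None
        best_dt = None
        for j, tc in enumerate(cgm_times):
            dt = abs(tc - t)
            if dt > window_s:
                continue
            if best is None or dt < best_dt or (dt == best_dt and tc < cgm_times[best]):
                best, best_dt = j, dt
        out.append(best)
    return out
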