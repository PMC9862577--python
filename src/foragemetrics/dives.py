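"""Dive detection, quality filtering, phase segmentation, and the
high-resolution dive metrics.

A dive is any submerged excursion exceeding 15 m depth and lasting more
than 5 min. Six exclusion rules remove recording errors and outlier
behaviors before analysis. Phases are delimited with a 0.75 m/s vertical
speed threshold: descent runs from the dive start to the first time the
(smoothed) descending speed drops below the threshold, ascent from the
last time the ascending speed is below the threshold to the dive end,
bottom in between.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import segment_sinuosity, select_k_dzi
from .types import DepthSeries, Dive

#: Minimum max-depth (m) and duration (s) for a submerged excursion to
#: count as a dive.
MIN_DEPTH = 15.0
MIN_DURATION = 300.0

#: Vertical speed threshold (m/s) separating transit from bottom phase.
PHASE_SPEED_THRESHOLD = 0.75

#: Vertical sinuosity above which a broken-stick segment is hunting.
HUNTING_SINUOSITY = 1.0 / 0.9

# Exclusion-rule bounds for outlier dives
MAX_VERTICAL_SPEED = 4.0   # m/s
MAX_DIVE_DURATION = 2800.0  # s
MAX_DIVE_DEPTH = 1200.0     # m
MAX_SURFACE_DURATION = 300.0  # s


def upsample_depth(depth: DepthSeries) -> DepthSeries:
    """Linearly upsample a 0.5 Hz depth record to 1 Hz; 1 Hz input is
    returned unchanged."""
    dt = np.median(np.diff(depth.t))
    if abs(dt - 1.0) < 1e-9:
        return depth
    t = np.arange(depth.t[0], depth.t[-1] + 0.5, 1.0)
    return DepthSeries(t, np.interp(t, depth.t, depth.depth))


def detect_dives(depth: DepthSeries, individual_id: int = 0,
                 min_depth: float = MIN_DEPTH,
                 min_duration: float = MIN_DURATION,
                 surface_threshold: float = 1.0) -> list[Dive]:
    """Maximal submerged intervals qualifying as dives, time-ordered.

    ``surface_duration`` of each dive is the gap to the next detected
    dive start (NaN for the last dive).
    """
    if len(depth) == 0:
        return []
    sub = depth.depth > surface_threshold
    # run boundaries of the submerged mask
    edges = np.flatnonzero(np.diff(sub.astype(np.int8)))
    starts = ([0] if sub[0] else []) + list(edges[~sub[edges]] + 1)
    ends = list(edges[sub[edges]]) + ([len(depth) - 1] if sub[-1] else [])
    dives: list[Dive] = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = depth.t[i0], depth.t[i1]
        prof = DepthSeries(depth.t[i0:i1 + 1], depth.depth[i0:i1 + 1])
        if t1 - t0 <= min_duration:
            continue
        if np.max(prof.depth) <= min_depth:
            continue
        dives.append(Dive(individual_id, len(dives), float(t0), float(t1),
                          prof, float(np.max(prof.depth))))
    for a, b in zip(dives, dives[1:]):
        a.surface_duration = b.start - a.end
    return dives


def filter_dives(dives: list[Dive]) -> tuple[list[Dive], pd.DataFrame]:
    """Apply the six exclusion rules; returns retained dives and a table
    of per-dive exclusion reasons.

    Rules: (1) missing depth records, (2) duplicated timestamps,
    (3) |vertical speed| > 4 m/s, (4) duration > 2800 s, (5) max depth
    > 1200 m, (6) post-dive surface interval > 300 s.
    """
    kept: list[Dive] = []
    reasons = []
    for d in dives:
        t, z = d.profile.t, d.profile.depth
        dt = np.diff(t)
        reason = None
        if np.any(np.isnan(z)) or np.any(dt > 1.0 + 1e-9):
            reason = "missing_records"
        elif np.any(dt <= 0):
            reason = "duplicate_timestamps"
        elif np.any(np.abs(np.diff(z) / dt) > MAX_VERTICAL_SPEED):
            reason = "vertical_speed"
        elif d.duration > MAX_DIVE_DURATION:
            reason = "duration"
        elif d.max_depth > MAX_DIVE_DEPTH:
            reason = "max_depth"
        elif d.surface_duration > MAX_SURFACE_DURATION:
            reason = "surface_duration"
        if reason is None:
            kept.append(d)
        else:
            reasons.append({"dive_id": d.dive_id, "reason": reason})
    return kept, pd.DataFrame(reasons, columns=["dive_id", "reason"])


def _smooth(v: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if v.size == 0:
        return v
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def segment_phases(dive: Dive, threshold: float = PHASE_SPEED_THRESHOLD,
                   smooth: bool = True) -> tuple[float, float]:
    """Delimit descent/bottom/ascent; stores and returns
    ``(descent_end, ascent_start)`` times.

    Vertical speed is the forward first difference of depth (positive =
    descending), optionally smoothed with a centered 5 s moving average.
    Degenerate dives (descent_end >= ascent_start) get a zero-length
    bottom at the vertex.
    """
    t, z = dive.profile.t, dive.profile.depth
    if t.size < 3:
        raise ValueError("profile too short to segment")
    v = np.diff(z) / np.diff(t)  # speed over [t_i, t_{i+1})
    vs = _smooth(v) if smooth else v
    below_desc = np.flatnonzero(vs < threshold)
    i_desc = int(below_desc[0]) if below_desc.size else v.size - 1
    below_asc = np.flatnonzero(-vs < threshold)
    i_asc = int(below_asc[-1]) + 1 if below_asc.size else 1
    if i_asc <= i_desc:  # no bottom phase: collapse at the vertex
        i_desc = i_asc = int(np.argmax(z))
    dive.descent_end = float(t[i_desc])
    dive.ascent_start = float(t[i_asc])
    return dive.descent_end, dive.ascent_start


def compute_dive_metrics(dive: Dive) -> dict:
    """High-resolution dive metrics (all but hunting time).

    Rates are summed vertical distance over phase duration; efficiency
    is bottom duration over dive plus post-dive surface duration;
    bottom sinuosity is total bottom vertical distance over the minimal
    down-then-up path through the maximum depth.
    """
    if np.isnan(dive.descent_end) or np.isnan(dive.ascent_start):
        raise ValueError("segment_phases must run first")
    t, z = dive.profile.t, dive.profile.depth
    desc = t <= dive.descent_end
    asc = t >= dive.ascent_start
    bot = (t >= dive.descent_end) & (t <= dive.ascent_start)

    def _rate(mask: np.ndarray) -> float:
        tt, zz = t[mask], z[mask]
        if tt.size < 2 or tt[-1] == tt[0]:
            return np.nan
        return float(np.sum(np.abs(np.diff(zz))) / (tt[-1] - tt[0]))

    t_bottom = dive.ascent_start - dive.descent_end
    t_dive = dive.duration
    if np.isnan(dive.surface_duration):
        efficiency = np.nan
    else:
        efficiency = t_bottom / (t_dive + dive.surface_duration)
    zb = z[bot]
    if zb.size >= 2:
        d_bottom = float(np.sum(np.abs(np.diff(zb))))
        ld = abs(zb[0] - dive.max_depth) + abs(dive.max_depth - zb[-1])
        sinuosity = d_bottom / ld if ld > 0 else (np.inf if d_bottom > 0 else 1.0)
    else:
        sinuosity = 1.0
    return {
        "descent_rate": _rate(desc),
        "ascent_rate": _rate(asc),
        "bottom_duration": float(t_bottom),
        "surface_duration": float(dive.surface_duration),
        "efficiency": float(efficiency),
        "sinuosity": float(sinuosity),
    }


def hunting_time_highres(dive: Dive, tol: float = 0.05,
                         k_max: int = 30) -> tuple[float, pd.DataFrame]:
    """Hunting time from the optimized broken-stick segmentation.

    The profile is segmented with the number of segments chosen by the
    summarization-quality index; a segment is hunting when its vertical
    sinuosity exceeds 1/0.9 (a zero net depth change with nonzero travel
    counts as hunting). Returns total hunting seconds and the per-segment
    table.
    """
    fit = select_k_dzi(dive.profile, tol=tol, k_max=k_max)
    t, z = dive.profile.t, dive.profile.depth
    rows = []
    total = 0.0
    for a, b in zip(fit.knot_t[:-1], fit.knot_t[1:]):
        m = (t >= a) & (t <= b)
        sin = segment_sinuosity(t[m], z[m])
        hunting = sin > HUNTING_SINUOSITY
        dur = float(b - a)
        if hunting:
            total += dur
        rows.append({"t_start": float(a), "t_end": float(b),
                     "sinuosity": sin, "hunting": hunting,
                     "duration": dur})
    return total, pd.DataFrame(rows)
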