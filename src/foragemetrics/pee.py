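"""Prey-encounter-event (PEE) detection from tri-axial acceleration.

Feeding attempts of diving predators appear as short high-amplitude
bursts of head acceleration. The detector works in three steps:

1. separate dynamic from static (gravitational) acceleration with an
   order-3 high-pass Butterworth filter, 0.33 Hz cutoff, applied
   forward-backward so burst timing is not shifted;
2. reduce each axis to 1 Hz by taking the standard deviation within each
   second, then smooth with a 5 s running standard deviation;
3. split each smoothed axis into two regimes with an exact 1-D 2-means
   clustering; seconds where all three axes sit in the high-mean cluster
   form events, and events separated by less than one second are merged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .types import AccelSeries, Dive, PeeEvent

#: High-pass cutoff (Hz) separating body dynamics from gravity.
HIGHPASS_CUTOFF = 0.33
HIGHPASS_ORDER = 3

#: Minimum separation (s) between distinct events.
MIN_SEPARATION = 1.0

#: Cluster-mean separation below this fraction of the overall SD marks a
#: degenerate (flat) signal: no high states are declared.
DEGENERATE_EPS = 0.1


def highpass_butterworth(x: np.ndarray, fs: float,
                         cutoff: float = HIGHPASS_CUTOFF,
                         order: int = HIGHPASS_ORDER) -> np.ndarray:
    """Zero-phase high-pass Butterworth filter (dynamic component)."""
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if x.size <= 3 * order:
        raise ValueError("signal too short for the filter order")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _binned_sd(x: np.ndarray, fs: float) -> np.ndarray:
    """Sample SD (ddof 1) within consecutive 1 s bins."""
    n_per = int(round(fs))
    if abs(fs - n_per) > 1e-9:
        # 12.5 Hz style rates: bin by floor(t) instead of reshaping
        sec = (np.arange(x.size) / fs).astype(int)
        n_bins = sec[-1] + 1
        sums = np.bincount(sec, weights=x, minlength=n_bins)
        sqs = np.bincount(sec, weights=x * x, minlength=n_bins)
        cnt = np.bincount(sec, minlength=n_bins).astype(float)
        m = sums / cnt
        return np.sqrt(np.maximum((sqs - cnt * m * m), 0.0)
                       / np.maximum(cnt - 1.0, 1.0))
    n_bins = x.size // n_per
    xb = x[:n_bins * n_per].reshape(n_bins, n_per)
    return xb.std(axis=1, ddof=1)


def _running_sd(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running SD, window shrinking at the edges."""
    out = np.empty_like(x)
    h = window // 2
    if x.size >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[h:x.size - h] = sw.std(axis=1)
    for i in list(range(min(h, x.size))) + list(range(max(0, x.size - h), x.size)):
        out[i] = x[max(0, i - h): i + h + 1].std()
    return out


def smoothed_dynamic_sd(accel: AccelSeries,
                        cutoff: float = HIGHPASS_CUTOFF) -> pd.DataFrame:
    """1 Hz smoothed SD of dynamic acceleration for the three axes.

    Returns a frame with columns t, sd_x, sd_y, sd_z; t is the start of
    each one-second bin.
    """
    if accel.duration < 5.0:
        raise ValueError("need at least 5 s of acceleration data")
    cols = {}
    for name, x in (("sd_x", accel.ax), ("sd_y", accel.ay), ("sd_z", accel.az)):
        dyn = highpass_butterworth(x, accel.fs, cutoff=cutoff)
        cols[name] = _running_sd(_binned_sd(dyn, accel.fs))
    n = len(cols["sd_x"])
    return pd.DataFrame({"t": accel.t0 + np.arange(n, dtype=float), **cols})


def two_means_high_state(values: np.ndarray,
                         eps: float = DEGENERATE_EPS) -> tuple[np.ndarray, tuple]:
    """Exact 1-D 2-means: membership in the higher-mean cluster.

    Solved by sorting and scanning every split that minimizes the
    within-cluster sum of squares — deterministic, no iterative seeding.
    Flat signals (cluster-mean separation below ``eps`` times the overall
    SD, or zero variance) are declared all-low to avoid hallucinating
    events on noise-free records.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd_all = v.std()
    if sd_all <= 1e-12 * max(1.0, abs(float(v.mean()))):
        return np.zeros(v.size, dtype=bool), (float(v[0]), float(v[0]))
    order = np.argsort(v, kind="stable")
    s = v[order]
    csum = np.cumsum(s)
    total = csum[-1]
    n = v.size
    k = np.arange(1, n)  # low cluster = s[:k]
    mean_lo = csum[:-1] / k
    mean_hi = (total - csum[:-1]) / (n - k)
    csq = np.cumsum(s * s)
    ss = (csq[:-1] - k * mean_lo ** 2) + (csq[-1] - csq[:-1] - (n - k) * mean_hi ** 2)
    j = int(np.argmin(ss))
    lo, hi = float(mean_lo[j]), float(mean_hi[j])
    if hi - lo < eps * sd_all:
        return np.zeros(n, dtype=bool), (lo, hi)
    high = np.zeros(n, dtype=bool)
    high[order[j + 1:]] = True
    return high, (lo, hi)


def _merge_events(intervals: list[tuple[float, float]],
                  min_sep: float = MIN_SEPARATION) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a - merged[-1][1] < min_sep:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def detect_pee(sd3: pd.DataFrame, individual_id: int = 0,
               eps: float = DEGENERATE_EPS) -> list[PeeEvent]:
    """Events where all three smoothed-SD axes are in their high cluster.

    ``sd3`` must carry aligned 1 Hz columns t, sd_x, sd_y, sd_z. Maximal
    triple-high runs closer than one second apart are merged. Event end
    is the right edge of the last high one-second bin.
    """
    for c in ("t", "sd_x", "sd_y", "sd_z"):
        if c not in sd3.columns:
            raise ValueError(f"missing column {c}")
    t = sd3["t"].to_numpy(dtype=float)
    if t.size >= 2 and not np.allclose(np.diff(t), 1.0):
        raise ValueError("axes must share one aligned 1 Hz clock")
    high = np.ones(t.size, dtype=bool)
    for c in ("sd_x", "sd_y", "sd_z"):
        h, _ = two_means_high_state(sd3[c].to_numpy(dtype=float), eps=eps)
        high &= h
    if not high.any():
        return []
    edges = np.flatnonzero(np.diff(high.astype(np.int8)))
    starts = ([0] if high[0] else []) + list(edges[~high[edges]] + 1)
    ends = list(edges[high[edges]]) + ([t.size - 1] if high[-1] else [])
    runs = [(t[i0], t[i1] + 1.0) for i0, i1 in zip(starts, ends)]
    return [PeeEvent(individual_id, a, b) for a, b in _merge_events(runs)]


def count_pee(events: list[PeeEvent], dives: list[Dive],
              day_origin: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """nPEE per dive and per calendar day.

    An event belongs to the dive whose closed [start, end] interval
    contains its start time (ties to the earlier dive); events outside
    any dive count toward day totals only. Days are 86400 s bins from
    ``day_origin``.
    """
    for a, b in zip(dives, dives[1:]):
        if b.start < a.end:
            raise ValueError("overlapping dives")
    per_dive = {d.dive_id: 0 for d in dives}
    day_counts: dict[int, int] = {}
    starts = np.array([d.start for d in dives])
    ends = np.array([d.end for d in dives])
    for ev in events:
        day = int((ev.start - day_origin) // 86400.0)
        day_counts[day] = day_counts.get(day, 0) + 1
        if starts.size:
            i = np.searchsorted(starts, ev.start, side="right") - 1
            if i >= 0 and ev.start <= ends[i]:
                per_dive[dives[i].dive_id] += 1
    dive_df = pd.DataFrame({
        "dive_id": list(per_dive.keys()),
        "npee": list(per_dive.values()),
    })
    day_df = pd.DataFrame(
        sorted(day_counts.items()), columns=["day", "npee_day"])
    return dive_df, day_df
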