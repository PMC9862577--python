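"""Horizontal-movement metrics at per-dive resolution.

Four metrics summarize area-restricted-search behavior along the track:
horizontal speed between consecutive dives, absolute turning angle at
each dive, first-passage time out of a fixed 25 km circle, and a move
persistence index capturing autocorrelation in speed and heading.

All great-circle computations use a spherical Earth of radius 6371 km.
The move persistence index here is a windowed empirical estimator — a
regression-through-origin of each 4 h displacement vector on the
previous one — not the latent-state space formulation used with Argos
data; it shares the [0, 1] range and the straight-track-high /
random-walk-low contract.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

EARTH_RADIUS = 6_371_000.0  # m

#: Fixed first-passage-time circle radius (m).
FPT_RADIUS = 25_000.0

#: Time step (s) at which move persistence is estimated.
MP_STEP = 4 * 3600.0


def haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters (spherical Earth)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def initial_bearing(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing in degrees from north, [0, 360)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def _to_xyz(lon, lat):
    lon, lat = np.radians(lon), np.radians(lat)
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _from_xyz(v):
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(v[..., 2]))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lon, lat


def interpolate_position(track: pd.DataFrame, times: np.ndarray) -> pd.DataFrame:
    """Great-circle (slerp) interpolation of lon/lat at given times.

    Times outside the track span get NaN locations. ``track`` needs
    columns t, lon, lat with strictly increasing t.
    """
    tt = track["t"].to_numpy(dtype=float)
    xyz = _to_xyz(track["lon"].to_numpy(float), track["lat"].to_numpy(float))
    times = np.asarray(times, dtype=float)
    lon = np.full(times.size, np.nan)
    lat = np.full(times.size, np.nan)
    inside = (times >= tt[0]) & (times <= tt[-1])
    for idx in np.flatnonzero(inside):
        ti = times[idx]
        j = np.searchsorted(tt, ti, side="right") - 1
        j = min(j, tt.size - 2)
        if tt[j + 1] == tt[j]:
            w = 0.0
        else:
            w = (ti - tt[j]) / (tt[j + 1] - tt[j])
        a, b = xyz[j], xyz[j + 1]
        omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
        if omega < 1e-12:
            p = a
        else:
            p = (np.sin((1 - w) * omega) * a + np.sin(w * omega) * b) / np.sin(omega)
        lon[idx], lat[idx] = _from_xyz(p)
    return pd.DataFrame({"t": times, "lon": lon, "lat": lat})


def dive_locations(track: pd.DataFrame, dive_times: np.ndarray) -> pd.DataFrame:
    """Location of each dive (at its start time) along the track."""
    return interpolate_position(track, np.asarray(dive_times, dtype=float))


def horizontal_speed(lon1, lat1, t1, lon2, lat2, t2) -> float:
    """Great-circle distance over elapsed time, m/s."""
    if t2 - t1 <= 0:
        raise ValueError("non-positive time difference")
    return float(haversine(lon1, lat1, lon2, lat2) / (t2 - t1))


def turning_angle(prev, cur, nxt) -> float:
    """Absolute change in bearing at ``cur``, degrees in [0, 180].

    Arguments are (lon, lat) pairs. Coincident consecutive points give
    NaN (heading undefined).
    """
    if (prev[0] == cur[0] and prev[1] == cur[1]) or \
       (cur[0] == nxt[0] and cur[1] == nxt[1]):
        return np.nan
    # both bearings taken at the middle point, so the angle is exactly
    # symmetric under path reversal
    b_in = (initial_bearing(cur[0], cur[1], prev[0], prev[1]) + 180.0) % 360.0
    b_out = initial_bearing(cur[0], cur[1], nxt[0], nxt[1])
    return float(abs((b_out - b_in + 180.0) % 360.0 - 180.0))


def first_passage_time(track: pd.DataFrame, index: int,
                       radius: float = FPT_RADIUS) -> float:
    """Time for the path to pass through a circle centered at fix ``index``.

    Crossing times forward and backward are linearly interpolated in
    distance between fixes; NaN when the track never leaves the circle
    on either side.
    """
    tt = track["t"].to_numpy(float)
    lon = track["lon"].to_numpy(float)
    lat = track["lat"].to_numpy(float)
    if not 0 <= index < tt.size:
        raise IndexError("focal index outside track")
    d = haversine(lon[index], lat[index], lon, lat)

    def _crossing(direction: int) -> float:
        i = index
        while True:
            j = i + direction
            if j < 0 or j >= tt.size:
                return np.nan
            if d[j] >= radius:
                frac = (radius - d[i]) / (d[j] - d[i])
                return tt[i] + frac * (tt[j] - tt[i])
            i = j

    fwd = _crossing(+1)
    bwd = _crossing(-1)
    if np.isnan(fwd) or np.isnan(bwd):
        return np.nan
    return float(fwd - bwd)


def move_persistence(track: pd.DataFrame, dive_times: np.ndarray,
                     step: float = MP_STEP, window: int = 5,
                     smooth: int = 3) -> pd.DataFrame:
    """Move persistence per 4 h step, interpolated to dive times.

    Positions are resampled on the step grid; per step t the raw index
    is the regression-through-origin coefficient of displacement d_t on
    d_{t-1} pooled over a centered window, clipped to [0, 1], then
    smoothed with a short moving average. Near 1 on straight
    constant-speed tracks, near 0 on uncorrelated steps.
    """
    tt = track["t"].to_numpy(float)
    grid = np.arange(tt[0], tt[-1] + 1e-9, step)
    if grid.size < 4:
        return pd.DataFrame({"t": np.asarray(dive_times, float),
                             "move_persistence": np.nan})
    pos = interpolate_position(track, grid)
    lat0 = np.nanmean(pos["lat"].to_numpy())
    x = np.radians(pos["lon"].to_numpy()) * EARTH_RADIUS * np.cos(np.radians(lat0))
    y = np.radians(pos["lat"].to_numpy()) * EARTH_RADIUS
    dx = np.diff(x)
    dy = np.diff(y)
    n = dx.size  # displacement vectors, one per step
    dots = dx[1:] * dx[:-1] + dy[1:] * dy[:-1]
    norms = dx[:-1] ** 2 + dy[:-1] ** 2
    h = window // 2
    gamma = np.empty(n - 1)
    for i in range(n - 1):
        a, b = max(0, i - h), min(n - 1, i + h + 1)
        denom = norms[a:b].sum()
        gamma[i] = dots[a:b].sum() / denom if denom > 0 else 0.0
    gamma = np.clip(gamma, 0.0, 1.0)
    if smooth > 1 and gamma.size >= 1:
        kernel = np.ones(smooth)
        gamma = np.convolve(gamma, kernel, "same") / \
            np.convolve(np.ones_like(gamma), kernel, "same")
    # gamma[i] describes the transition between steps i and i+1 -> time grid[i+1]
    g_t = grid[1:-1]
    mp = np.interp(np.asarray(dive_times, float), g_t, gamma,
                   left=np.nan, right=np.nan)
    return pd.DataFrame({"t": np.asarray(dive_times, float),
                         "move_persistence": mp})


def track_metrics(track: pd.DataFrame, dive_times: np.ndarray,
                  dive_ids: np.ndarray | None = None,
                  fpt_radius: float = FPT_RADIUS) -> pd.DataFrame:
    """All four track metrics evaluated at each dive location."""
    dive_times = np.asarray(dive_times, dtype=float)
    locs = dive_locations(track, dive_times)
    n = dive_times.size
    speed = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    fpt = np.full(n, np.nan)
    lon = locs["lon"].to_numpy()
    lat = locs["lat"].to_numpy()
    for i in range(n):
        if np.isnan(lon[i]):
            continue
        if i > 0 and not np.isnan(lon[i - 1]) and dive_times[i] > dive_times[i - 1]:
            speed[i] = horizontal_speed(lon[i - 1], lat[i - 1], dive_times[i - 1],
                                        lon[i], lat[i], dive_times[i])
        if 0 < i < n - 1 and not (np.isnan(lon[i - 1]) or np.isnan(lon[i + 1])):
            angle[i] = turning_angle((lon[i - 1], lat[i - 1]),
                                     (lon[i], lat[i]),
                                     (lon[i + 1], lat[i + 1]))
    # FPT on the fix-level track, evaluated at the dive's bracketing fix
    dive_track = pd.concat([
        track[["t", "lon", "lat"]],
        locs.dropna().rename(columns={"t": "t"}),
    ]).sort_values("t").drop_duplicates("t").reset_index(drop=True)
    t_all = dive_track["t"].to_numpy()
    for i in range(n):
        if np.isnan(lon[i]):
            continue
        idx = int(np.searchsorted(t_all, dive_times[i]))
        idx = min(idx, t_all.size - 1)
        fpt[i] = first_passage_time(dive_track, idx, radius=fpt_radius)
    mp = move_persistence(track, dive_times)["move_persistence"].to_numpy()
    out = pd.DataFrame({
        "t": dive_times,
        "horizontal_speed": speed,
        "turning_angle": angle,
        "fpt": fpt,
        "move_persistence": mp,
    })
    if dive_ids is not None:
        out.insert(0, "dive_id", np.asarray(dive_ids))
    return out
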