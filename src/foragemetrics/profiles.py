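"""Broken-stick abstraction of dive profiles.

Two uses mirror field practice with time-depth recorders: (a) an
optimized segmentation (number of segments chosen by a summarization
quality index) feeding the hunting-time metric, and (b) a fixed
five-segment summary emulating the dive shapes transmitted by CTD-SRDL
satellite relay loggers, from which low-resolution metrics are computed.

The greedy algorithm starts from the dive endpoints and repeatedly adds
the sample with maximum absolute deviation from the current
piecewise-linear reconstruction (earliest sample on ties), so the fit is
fully deterministic and nested in the number of knots.
"""
from __future__ import annotations

from typing import Callable

import numpy as np

from .types import BrokenStickFit, DepthSeries

#: Vertical-rate threshold (m/s) below which a low-resolution segment is
#: classified as hunting rather than transit.
LOWRES_HUNTING_RATE = 0.4

#: Default tolerance on the summarization-quality index (max reconstruction
#: error normalized by max depth) used to choose the number of segments.
DZI_TOL = 0.05


def _greedy_knots(t: np.ndarray, depth: np.ndarray, n_interior: int) -> np.ndarray:
    """Indices of endpoint + interior knots after greedy refinement."""
    n = t.size
    knots = [0, n - 1]
    recon = np.interp(t, t[knots], depth[np.array(knots)])
    for _ in range(n_interior):
        dev = np.abs(depth - recon)
        dev[knots] = -1.0  # never re-select an existing knot
        i = int(np.argmax(dev))  # argmax takes the earliest on ties
        knots.append(i)
        order = np.argsort(knots, kind="stable")
        knots = [knots[j] for j in order]
        idx = np.array(knots)
        recon = np.interp(t, t[idx], depth[idx])
    return np.array(sorted(knots))


def broken_stick(profile: DepthSeries, n_knots: int) -> BrokenStickFit:
    """Greedy broken-stick fit with ``n_knots`` interior knots.

    Parameters
    ----------
    profile
        Dive profile; first and last samples are always knots.
    n_knots
        Number of interior inflection points to place.
    """
    t, depth = profile.t, profile.depth
    if t.size < n_knots + 2:
        raise ValueError(
            f"profile has {t.size} samples; need at least {n_knots + 2}")
    idx = _greedy_knots(t, depth, n_knots)
    recon = np.interp(t, t[idx], depth[idx])
    err = float(np.max(np.abs(depth - recon)))
    max_depth = float(np.max(depth))
    dzi = err / max_depth if max_depth > 0 else 0.0
    return BrokenStickFit(t[idx], depth[idx], err, dzi)


def select_k_dzi(profile: DepthSeries, tol: float = DZI_TOL,
                 k_max: int = 30,
                 criterion: Callable[[BrokenStickFit, DepthSeries], float] | None = None,
                 ) -> BrokenStickFit:
    """Smallest broken-stick fit whose quality index is within ``tol``.

    The index defaults to the maximum reconstruction error normalized by
    the dive's maximum depth; ``criterion`` may supply an alternative
    (e.g. an envelope-based dive-zone index) with the same
    smaller-is-better orientation.
    """
    best = None
    for k in range(1, k_max + 1):
        n_interior = k - 1
        if profile.t.size < n_interior + 2:
            break
        fit = broken_stick(profile, n_interior)
        score = criterion(fit, profile) if criterion is not None else fit.dzi
        best = fit
        if score <= tol:
            return fit
    if best is None:
        raise ValueError("profile too short for any broken-stick fit")
    return best


def abstract_to_five_segments(profile: DepthSeries) -> BrokenStickFit | None:
    """Five-segment (6-knot) summary, or ``None`` when two inflection
    points fall on the same timestamp (such dives are discarded, as done
    for transmitted dive profiles)."""
    fit = broken_stick(profile, 4)
    if np.any(np.diff(fit.knot_t) <= 0):
        return None
    return fit


def segment_sinuosity(t: np.ndarray, depth: np.ndarray) -> float:
    """Vertical sinuosity of one segment of samples: total vertical
    distance over net vertical distance (inf when the net is zero)."""
    total = float(np.sum(np.abs(np.diff(depth))))
    net = abs(float(depth[-1] - depth[0]))
    if net == 0.0:
        return np.inf if total > 0 else 1.0
    return total / net


def lowres_metrics(fit: BrokenStickFit, surface_duration: float) -> dict:
    """Metrics from a five-segment profile.

    descent/ascent rates are the absolute depth/time ratios of the first
    and last segments; bottom duration spans knots 2..5; hunting time is
    the total duration of segments with absolute vertical rate below
    0.4 m/s; efficiency = bottom / (dive + post-dive surface duration).
    """
    if fit.k != 5:
        raise ValueError("expected a five-segment profile")
    dt = np.diff(fit.knot_t)
    dz = np.diff(fit.knot_depth)
    rates = np.abs(dz / dt)
    dive_duration = float(fit.knot_t[-1] - fit.knot_t[0])
    bottom = float(fit.knot_t[4] - fit.knot_t[1])
    if np.isnan(surface_duration):
        eff = np.nan
    else:
        eff = bottom / (dive_duration + surface_duration)
    hunting = float(np.sum(dt[rates < LOWRES_HUNTING_RATE]))
    return {
        "descent_rate_lr": float(rates[0]),
        "ascent_rate_lr": float(rates[-1]),
        "bottom_duration_lr": bottom,
        "efficiency_lr": eff,
        "hunting_time_lr": hunting,
    }
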