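"""Synthetic biologging trips with known ground truth.

Generates multi-day at-sea trips of a deep-diving predator: V/U-shaped
dives hundreds of meters deep with bottom-phase wiggles, post-dive
surface intervals, tri-axial acceleration (gravity rotated by a slowly
varying pitch plus Gaussian baseline dynamics and high-amplitude
prey-capture bursts), and a two-mode (intensive/extensive) horizontal
track. Per-dive prey-encounter counts are drawn from a Poisson
log-link on a chosen standardized dive metric with correlated
per-individual random intercepts and slopes, so every downstream stage
— burst detection, dive metrics, mixed models — has a knowable truth.

The real study system is observational; no generative model exists for
it. Everything here is a stand-in with the statistical structure the
analysis assumes, not a biomechanical or ecological simulation.

Transit limbs include a slower sub-phase (a variable fraction of the
depth covered at a reduced rate) so that five-segment profile
abstraction degrades transit-rate estimates the way complex real dive
shapes do.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AccelSeries, DepthSeries, PeeEvent

GRAVITY = 9.81
_METERS_PER_DEG = 111_194.9  # spherical Earth, 6371 km radius

#: Drivers the generative Poisson rate can be linked to.
DRIVERS = ("ascent_rate", "hunting_time")


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic trips.

    Defaults mirror the field study the package emulates: ~21
    post-breeding females recorded for about ten weeks, depth at 1 Hz,
    acceleration at 16 Hz, dives of 200-800 m lasting 10-25 min, mean
    prey-encounter count of 9 per dive (``beta0 = ln 9``) with
    individual-specific intercepts and slopes on the driving metric.
    """

    n_individuals: int = 21
    days_per_individual: float = 71.0
    depth_hz: float = 1.0
    accel_hz: float = 16.0
    dive_depth_range: tuple = (200.0, 800.0)
    dive_duration_range: tuple = (600.0, 1500.0)
    surface_duration_range: tuple = (120.0, 280.0)
    bottom_wiggle_amplitude: float = 15.0
    mode_switch_prob: float = 0.1
    speed_by_mode: tuple = (0.3, 1.0)  # m/s: intensive, extensive
    beta0: float = float(np.log(9.0))
    beta_metric: float = 0.5
    tau_intercept: float = 0.5
    tau_slope: float = 0.3
    rho: float = 0.0
    burst_amplitude_snr: float = 5.0
    baseline_sd: float = 0.2  # m/s^2, per-axis dynamic baseline
    burst_duration: float = 1.5  # s
    driver_metric: str = "ascent_rate"
    surface_pee_fraction: float = 0.0
    fix_interval: float = 900.0  # s between track fixes
    origin: tuple = (70.33, -49.33)  # lon, lat
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dive_depth_range", "dive_duration_range",
                     "surface_duration_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be positive and ordered")
        if not 0.0 <= self.mode_switch_prob <= 1.0:
            raise ConfigError("mode_switch_prob must be in [0, 1]")
        if not -1.0 < self.rho < 1.0:
            raise ConfigError("rho must be in (-1, 1)")
        if self.accel_hz <= 2 * 0.33:
            raise ConfigError("accel_hz must exceed twice the 0.33 Hz cutoff")
        if self.tau_intercept < 0 or self.tau_slope < 0:
            raise ConfigError("random-effect SDs must be nonnegative")
        if self.driver_metric not in DRIVERS:
            raise ConfigError(f"driver_metric must be one of {DRIVERS}")

    def re_covariance(self) -> np.ndarray:
        """Covariance of the (intercept, slope) random effects."""
        t0, t1, r = self.tau_intercept, self.tau_slope, self.rho
        T = np.array([[t0 * t0, r * t0 * t1], [r * t0 * t1, t1 * t1]])
        if np.any(np.linalg.eigvalsh(T) < -1e-12):
            raise ConfigError("implied random-effect covariance not PSD")
        return T


@dataclass
class TripData:
    """One simulated individual: all sensor streams plus ground truth."""

    individual_id: int
    track: pd.DataFrame
    depth: DepthSeries
    accel: AccelSeries
    truth_pee: list
    truth_random_effects: tuple
    truth_dives: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def simulate_dive_profile(max_depth: float, duration: float, rng,
                          hz: float = 1.0,
                          descent_rate: float = 1.5,
                          ascent_rate: float = 1.5,
                          wiggle_amplitude: float = 0.0,
                          n_wiggles: int = 0,
                          slow_frac: float = 0.0,
                          slow_factor_descent: float = 1.0,
                          slow_factor_ascent: float = 1.0,
                          speed_cap: float = 4.0) -> DepthSeries:
    """One dive profile: descent, wiggly bottom, ascent; 0 m at both ends.

    Transit limbs optionally contain a slower sub-phase covering
    ``slow_frac`` of the depth at ``slow_factor * rate``. Bottom wiggles
    are triangular excursions of the given amplitude above the maximum
    depth, each adding twice the amplitude of vertical distance.
    """
    if max_depth < 15 or duration <= 300 or hz < 1:
        raise ConfigError("need max depth >= 15 m, duration > 300 s, hz >= 1")
    f = slow_frac
    wiggly = n_wiggles > 0 and wiggle_amplitude > 0
    # transit limbs run between the surface and a shoulder depth; wiggles
    # dip from the shoulder down to the true maximum depth
    shoulder = max_depth - wiggle_amplitude if wiggly else max_depth
    if shoulder <= 0:
        raise ConfigError("wiggle amplitude exceeds the dive depth")
    t_desc = (1 - f) * shoulder / descent_rate + \
        f * shoulder / (descent_rate * slow_factor_descent)
    t_asc = (1 - f) * shoulder / ascent_rate + \
        f * shoulder / (ascent_rate * slow_factor_ascent)
    t_bottom = duration - t_desc - t_asc
    if t_bottom < -1e-9 or (wiggly and t_bottom <= 0):
        raise ConfigError("duration too short for depth at these rates")
    t_bottom = max(t_bottom, 0.0)
    rates = [descent_rate, ascent_rate,
             descent_rate * slow_factor_descent,
             ascent_rate * slow_factor_ascent]
    if wiggly:
        rates.append(2 * wiggle_amplitude * n_wiggles / t_bottom)
    if max(rates) >= speed_cap:
        raise ConfigError("vertical speed would exceed the cap")

    bp_t = [0.0, (1 - f) * shoulder / descent_rate, t_desc]
    bp_z = [0.0, (1 - f) * shoulder, shoulder]
    if t_bottom > 0:
        if wiggly:
            tw = t_bottom / n_wiggles
            for i in range(n_wiggles):
                base = t_desc + i * tw
                bp_t += [base + tw / 2, base + tw]
                bp_z += [max_depth, shoulder]
        else:
            bp_t.append(t_desc + t_bottom)
            bp_z.append(shoulder)
    bp_t += [duration - f * shoulder / (ascent_rate * slow_factor_ascent),
             duration]
    bp_z += [f * shoulder, 0.0]
    bp_t = np.array(bp_t)
    bp_z = np.array(bp_z)
    keep = np.concatenate([[True], np.diff(bp_t) > 1e-12])
    bp_t, bp_z = bp_t[keep], bp_z[keep]
    t = np.arange(int(round(duration * hz)) + 1) / hz
    z = np.interp(t, bp_t, bp_z)
    z[0] = z[-1] = 0.0
    return DepthSeries(t, z)


def inject_pee_bursts(accel: AccelSeries, events: list[PeeEvent],
                      snr: float, baseline_sd: float, rng) -> AccelSeries:
    """Add band-limited burst noise inside each event window so the
    per-axis dynamic SD there is ``snr`` times the baseline SD."""
    out = accel.copy()
    extra = baseline_sd * np.sqrt(max(snr * snr - 1.0, 0.0))
    t_end = accel.t0 + accel.duration
    for ev in events:
        if ev.start < accel.t0 - 1e-9 or ev.end > t_end + 1e-9:
            raise ValueError("event outside the acceleration time span")
        i0 = int(np.ceil((ev.start - accel.t0) * accel.fs))
        i1 = int(np.floor((ev.end - accel.t0) * accel.fs))
        if i1 - i0 < 2:
            raise ValueError("burst shorter than two samples")
        n = i1 - i0
        for axis in (out.ax, out.ay, out.az):
            axis[i0:i1] += rng.normal(0.0, extra, n)
    return out


def _draw_dive_shape(cfg: SimConfig, x: float, rng) -> dict:
    """Shape parameters for one dive; the latent x drives the generative
    metric according to ``cfg.driver_metric``."""
    duration = round(rng.uniform(*cfg.dive_duration_range) * cfg.depth_hz) / cfg.depth_hz
    r_d = float(np.clip(rng.normal(1.6, 0.15), 1.2, 3.0))
    if cfg.driver_metric == "ascent_rate":
        r_a = float(np.clip(1.6 + 0.25 * x, 1.0, 3.2))
        n_wig = int(rng.integers(2, 6))
    else:  # hunting_time driver: x sets the wiggle load
        r_a = float(np.clip(rng.normal(1.6, 0.15), 1.2, 3.0))
        n_wig = int(np.clip(round(3 + 1.5 * x), 0, 8))
    u_d = rng.uniform(0.55, 0.9)
    u_a = rng.uniform(0.55, 0.9)
    f = 0.15
    d_max = 0.8 * duration / ((1 - f + f / u_d) / r_d + (1 - f + f / u_a) / r_a)
    depth = float(min(rng.uniform(*cfg.dive_depth_range), d_max))
    depth = max(depth, 20.0)
    return dict(max_depth=depth, duration=duration, descent_rate=r_d,
                ascent_rate=r_a, n_wiggles=n_wig,
                wiggle_amplitude=cfg.bottom_wiggle_amplitude,
                slow_frac=f, slow_factor_descent=u_d, slow_factor_ascent=u_a)


def _transit_times(shape: dict) -> tuple[float, float]:
    """Descent and ascent durations implied by a dive shape spec."""
    wiggly = shape["n_wiggles"] > 0 and shape["wiggle_amplitude"] > 0
    s = shape["max_depth"] - (shape["wiggle_amplitude"] if wiggly else 0.0)
    f = shape["slow_frac"]
    t_desc = (1 - f) * s / shape["descent_rate"] + \
        f * s / (shape["descent_rate"] * shape["slow_factor_descent"])
    t_asc = (1 - f) * s / shape["ascent_rate"] + \
        f * s / (shape["ascent_rate"] * shape["slow_factor_ascent"])
    return t_desc, t_asc


def _place_events(individual_id: int, t0: float, t1: float, n: int,
                  burst_dur: float, rng) -> list[PeeEvent]:
    """n non-overlapping bursts inside [t0, t1], >= 2 s apart."""
    slot = burst_dur + 2.5
    n_slots = int((t1 - t0) // slot)
    n = min(n, n_slots)
    if n <= 0:
        return []
    chosen = np.sort(rng.choice(n_slots, size=n, replace=False))
    jitter = rng.uniform(0.0, slot - burst_dur - 2.0, size=n)
    starts = t0 + chosen * slot + jitter
    return [PeeEvent(individual_id, float(s), float(s + burst_dur))
            for s in starts]


def simulate_trip(config: SimConfig, individual_id: int) -> TripData:
    """Simulate one individual's trip; pure function of (config, id)."""
    rng = np.random.default_rng([config.seed, individual_id])
    T = config.re_covariance()
    L = np.linalg.cholesky(T + 1e-12 * np.eye(2))
    b0, b1 = L @ rng.standard_normal(2)

    span = config.days_per_individual * 86400.0
    t = 60.0  # lead-in surface interval
    depth_chunks = [np.zeros(int(t * config.depth_hz))]
    dive_rows = []
    events: list[PeeEvent] = []
    mode = 0  # 0 intensive, 1 extensive
    dive_id = 0
    while True:
        x = rng.standard_normal()
        shape = _draw_dive_shape(config, x, rng)
        if t + shape["duration"] + config.surface_duration_range[1] > span:
            break
        if rng.uniform() < config.mode_switch_prob:
            mode = 1 - mode
        prof = simulate_dive_profile(rng=rng, hz=config.depth_hz, **shape)
        lam = float(np.exp(np.clip(
            config.beta0 + b0 + (config.beta_metric + b1) * x, -20, 10)))
        npee = int(rng.poisson(lam))
        # bottom window of the constructed profile
        t_desc, t_asc = _transit_times(shape)
        bt0 = t + t_desc
        bt1 = t + shape["duration"] - t_asc
        ev = _place_events(individual_id, bt0, bt1, npee,
                           config.burst_duration, rng)
        npee = len(ev)  # conservation: realized count is the truth
        events.extend(ev)
        surf = round(rng.uniform(*config.surface_duration_range)
                     * config.depth_hz) / config.depth_hz
        dive_rows.append({
            "individual_id": individual_id, "dive_id": dive_id,
            "start": t, "end": t + shape["duration"],
            "max_depth": shape["max_depth"], "x": x, "npee": npee,
            "lambda": lam, "mode": mode,
            "ascent_rate_true": shape["ascent_rate"],
            "n_wiggles": shape["n_wiggles"],
        })
        depth_chunks.append(prof.depth[1:])  # first sample shared with surface
        depth_chunks.append(np.zeros(int(round(surf * config.depth_hz)) - 1))
        t = t + shape["duration"] + surf
        dive_id += 1

    depth_vals = np.concatenate(depth_chunks)
    depth = DepthSeries(np.arange(depth_vals.size) / config.depth_hz,
                        depth_vals)

    n_acc = int(depth_vals.size / config.depth_hz * config.accel_hz)
    ta = np.arange(n_acc) / config.accel_hz
    pitch = 0.4 * np.sin(2 * np.pi * 0.005 * ta + rng.uniform(0, 2 * np.pi))
    accel = AccelSeries(
        0.0, config.accel_hz,
        GRAVITY * np.sin(pitch) + rng.normal(0, config.baseline_sd, n_acc),
        rng.normal(0, config.baseline_sd, n_acc),
        GRAVITY * np.cos(pitch) + rng.normal(0, config.baseline_sd, n_acc))
    accel = inject_pee_bursts(accel, events, config.burst_amplitude_snr,
                              config.baseline_sd, rng)

    truth_dives = pd.DataFrame(dive_rows)
    track = _simulate_track(config, truth_dives, depth.t[-1], rng)
    return TripData(individual_id, track, depth, accel, events,
                    (float(b0), float(b1)), truth_dives, config)


def _simulate_track(cfg: SimConfig, dives: pd.DataFrame, t_end: float,
                    rng) -> pd.DataFrame:
    """Two-mode correlated random walk sampled at the fix interval."""
    times = np.arange(0.0, t_end + 1e-9, cfg.fix_interval)
    heading = rng.uniform(0, 2 * np.pi)
    turn_sd = (1.0, 0.15)  # rad per step: intensive tortuous, extensive straight
    x = np.zeros(times.size)
    y = np.zeros(times.size)
    if len(dives):
        starts = dives["start"].to_numpy()
        modes = dives["mode"].to_numpy()
    for i in range(1, times.size):
        if len(dives):
            j = max(0, int(np.searchsorted(starts, times[i], "right")) - 1)
            mode = int(modes[j])
        else:
            mode = 1
        heading += rng.normal(0.0, turn_sd[mode])
        step = cfg.speed_by_mode[mode] * cfg.fix_interval
        x[i] = x[i - 1] + step * np.sin(heading)
        y[i] = y[i - 1] + step * np.cos(heading)
    lon0, lat0 = cfg.origin
    lat = lat0 + y / _METERS_PER_DEG
    lon = lon0 + x / (_METERS_PER_DEG * np.cos(np.radians(lat0)))
    return pd.DataFrame({"t": times, "lon": lon, "lat": lat})


def simulate_glmm_dataset(config: SimConfig, seed: int | None = None,
                          n_dives_per_individual: int = 500,
                          ) -> tuple[pd.DataFrame, dict]:
    """Records drawn directly from the generative mixed model.

    Bypasses the signal level: standard-normal predictor x, response
    Poisson(exp(b0_i + (b1_i) x)) around the population coefficients.
    Returns the table and the true parameters (including the realized
    per-individual effects).
    """
    if config.n_individuals < 2:
        raise ConfigError("need at least two individuals")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.re_covariance()
    L = np.linalg.cholesky(T + 1e-12 * np.eye(2))
    rows = []
    b_all = []
    for i in range(config.n_individuals):
        b = L @ rng.standard_normal(2)
        b_all.append(b)
        x = rng.standard_normal(n_dives_per_individual)
        eta = config.beta0 + b[0] + (config.beta_metric + b[1]) * x
        y = rng.poisson(np.exp(np.clip(eta, -20, 10)))
        for j in range(n_dives_per_individual):
            rows.append((i, j, x[j], y[j]))
    df = pd.DataFrame(rows, columns=["individual_id", "dive_id", "x", "npee"])
    truth = {"beta0": config.beta0, "beta1": config.beta_metric,
             "T": T, "b": np.array(b_all)}
    return df, truth


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict echo of a configuration (YAML-friendly)."""
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
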