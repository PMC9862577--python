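"""CSV schemas shared by the pipeline stages.

depth.csv: individual_id, t, depth_m
accel.csv: individual_id, t, ax, ay, az
track.csv: individual_id, t, lon, lat
pee_events.csv: individual_id, start_time, end_time
truth_*.csv / config.yaml: ground-truth companion files of a simulation
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SimConfig, TripData, config_to_dict
from .types import AccelSeries, DepthSeries, PeeEvent


def write_events(events: list[PeeEvent], path) -> None:
    pd.DataFrame([{"individual_id": e.individual_id, "start_time": e.start,
                   "end_time": e.end} for e in events]).to_csv(path, index=False)


def read_events(path) -> list[PeeEvent]:
    df = pd.read_csv(path)
    return [PeeEvent(int(r.individual_id), float(r.start_time),
                     float(r.end_time)) for r in df.itertuples()]


def read_depth(path) -> dict[int, DepthSeries]:
    df = pd.read_csv(path)
    return {int(g): DepthSeries(sub["t"].to_numpy(), sub["depth_m"].to_numpy())
            for g, sub in df.groupby("individual_id")}


def read_accel(path) -> dict[int, AccelSeries]:
    df = pd.read_csv(path)
    out = {}
    for g, sub in df.groupby("individual_id"):
        t = sub["t"].to_numpy(dtype=float)
        fs = 1.0 / np.median(np.diff(t))
        out[int(g)] = AccelSeries(float(t[0]), float(round(fs, 3)),
                                  sub["ax"].to_numpy(), sub["ay"].to_numpy(),
                                  sub["az"].to_numpy())
    return out


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trip(trip: TripData, outdir) -> None:
    """All sensor streams and truth files for one simulated individual."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    i = trip.individual_id
    pd.DataFrame({"individual_id": i, "t": trip.depth.t,
                  "depth_m": trip.depth.depth}).to_csv(
        out / f"depth_{i}.csv", index=False)
    pd.DataFrame({"individual_id": i, "t": trip.accel.t,
                  "ax": trip.accel.ax, "ay": trip.accel.ay,
                  "az": trip.accel.az}).to_csv(
        out / f"accel_{i}.csv", index=False)
    trip.track.assign(individual_id=i).to_csv(
        out / f"track_{i}.csv", index=False)
    write_events(trip.truth_pee, out / f"truth_events_{i}.csv")
    trip.truth_dives.to_csv(out / f"truth_dives_{i}.csv", index=False)
    b0, b1 = trip.truth_random_effects
    pd.DataFrame([{"individual_id": i, "b_intercept": b0, "b_slope": b1}]
                 ).to_csv(out / f"truth_random_effects_{i}.csv", index=False)
    if trip.config is not None:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config_to_dict(trip.config), fh)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for k in ("dive_depth_range", "dive_duration_range",
              "surface_duration_range", "speed_by_mode", "origin"):
        if k in d:
            d[k] = tuple(d[k])
    return SimConfig(**d)
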