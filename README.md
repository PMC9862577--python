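# foragemetrics

Do simple movement metrics predict how much a diving predator actually
eats? Deep divers such as southern elephant seals cannot be watched
while they forage, so ecologists infer feeding intensity from movement
proxies: transit rates and bottom time within dives, horizontal speed,
turning angles, first-passage time, move persistence along the track.
`foragemetrics` implements the full chain needed to *test* those
proxies against an accelerometry-derived reference — the number of prey
encounter events (nPEE), short high-amplitude bursts of head
acceleration produced during capture attempts.

The package provides, as composable library functions plus a thin
`foragemetrics` CLI:

- **Prey-encounter detection** from tri-axial acceleration: order-3
  high-pass Butterworth at 0.33 Hz (zero-phase), per-second SD followed
  by a 5 s running SD, exact 1-D 2-means clustering per axis, events
  where all three axes are in the high cluster, merged below 1 s
  separation.
- **Dive processing**: dives as submerged excursions >15 m lasting
  >5 min; six exclusion rules for outliers (missing/duplicated records,
  vertical speed >4 m s⁻¹, duration >2800 s, depth >1200 m, surface
  interval >300 s); descent/bottom/ascent segmentation at 0.75 m s⁻¹;
  the per-dive metric set — descent/ascent rate, bottom duration,
  surface duration, efficiency t_bottom/(t_dive+t_surface), bottom
  sinuosity d_bottom/ld_bottom, and hunting time (broken-stick segments
  with vertical sinuosity > 1/0.9).
- **Profile abstraction**: greedy broken-stick summarization, a
  summarization-quality stopping rule, and the five-segment
  low-resolution profile emulating CTD-SRDL satellite transmission,
  with its own rate/efficiency/hunting metrics (hunting = segments with
  vertical rate < 0.4 m s⁻¹).
- **Track metrics** at each dive: horizontal speed, absolute turning
  angle, first-passage time out of a fixed 25 km circle, and a move
  persistence index at 4 h steps interpolated to dives.
- **Evaluation**: Poisson mixed models (log link; correlated
  per-individual random intercepts and slopes; maximum marginal
  likelihood via a Laplace approximation written for this package and
  cross-checked against R's `glmmTMB`), variance partitioning into
  R²F/R²I/R²S fixed-slope / random-intercept / random-slope shares with
  the ln(1 + 1/λ̄) Poisson-specific variance, Tweedie-objective boosted
  regression trees (xgboost), and leave-one-individual-out
  cross-validation scored by RMSE, mRMSE = RMSE/ȳ, sdRMSE = RMSE/σ_y,
  and Pearson correlation.
- **A synthetic biologging generator** with known ground truth:
  multi-day trips, U/V dives with bottom wiggles, gravity + noise +
  injected capture bursts in the acceleration, a two-mode
  intensive/extensive track, and per-dive nPEE drawn from a generative
  Poisson mixed model on a chosen dive metric — so every stage of the
  chain can be validated against truth.

## Worked example

```python
import foragemetrics as fm
from foragemetrics.evaluation import evaluate_models

cfg = fm.SimConfig(n_individuals=6, days_per_individual=0.25, seed=11)
trips = [fm.simulate_trip(cfg, i) for i in range(cfg.n_individuals)]
data = fm.build_dataset(trips)            # detect bursts, dives, metrics
rec = data["dive_records"]
print(f"{len(rec)} dives, mean nPEE/dive = {rec['npee'].mean():.1f}")
perf = evaluate_models(rec, {"ascent_rate": ["ascent_rate"],
                             "hunting_time": ["hunting_time"]})
print(perf[["model", "r2_f", "r2_i", "r2_s",
            "rmse_mean", "corr_mean"]].round(2).to_string(index=False))
```

prints

```
97 dives, mean nPEE/dive = 8.1
       model  r2_f  r2_i  r2_s  rmse_mean  corr_mean
 ascent_rate 53.52 17.16  2.85       4.41       0.73
hunting_time  8.08 31.47  5.13       5.62       0.21
```

The generator links the encounter rate to the ascent rate, and the
evaluation recovers that: the ascent-rate model explains ~54% of the
nPEE variance through its fixed slope (`r2_f`, in percent) and predicts
held-out individuals well (mean correlation 0.73), while hunting time —
not part of the generative link here — explains little fixed-effect
variance and mostly absorbs among-individual differences (`r2_i`).

The same stages are available from the shell:

```bash
foragemetrics simulate --n-individuals 2 --days 0.1 --seed 1 --out sim/
foragemetrics pee   --accel sim/accel_0.csv --out events.csv
foragemetrics dives --depth sim/depth_0.csv --events events.csv --out dives.csv
foragemetrics track --track sim/track_0.csv --dives dives.csv --out trackm.csv
foragemetrics evaluate --records dives.csv --out results/
```

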