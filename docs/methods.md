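# Methods

This note documents the models and procedures implemented in
`foragemetrics`, the choices made where the design was genuinely open,
and what the synthetic validation does and does not demonstrate.

## Prey-encounter events from acceleration

Capture attempts by pinnipeds appear as brief high-amplitude head
jerks. The detector separates dynamic from static (gravitational)
acceleration with an order-3 high-pass Butterworth filter at 0.33 Hz.
Two reading notes:

- The filter is applied forward–backward (`sosfiltfilt`), i.e.
  zero-phase, so burst timing is not shifted; the effective magnitude
  response is the square of the order-3 response, which only sharpens
  the stopband.
- "0.33 Hz" is interpreted as an absolute cutoff in Hz (the sampling
  rate is known); it is configurable.

Each axis is then reduced to 1 Hz by the standard deviation within
each integer-second bin (sample SD, ddof 1; bins assumed aligned to
integer seconds) followed by a centered 5-sample running SD that
shrinks at the edges. The two-regime split per axis uses an exact 1-D
2-means: sort, scan all n−1 splits, minimize within-cluster sum of
squares. This is deterministic — no iterative seeding — and is a
threshold rule, so events are invariant to rescaling the accelerometer
units. If the two cluster means are separated by less than 0.1 of the
overall SD (or the signal is constant), the series is declared
degenerate and no high states are produced; this prevents hallucinated
events on flat records. Clustering is run per individual over the full
deployment by default (per-day scope is available).

Seconds where all three axes are simultaneously in their high-mean
cluster form candidate events; maximal runs closer than 1 s are merged.
Event counts are assigned to the dive whose closed [start, end]
interval contains the event start (ties to the earlier dive); events at
the surface count only toward daily totals, so per-day nPEE ≥ the sum
of that day's per-dive nPEE.

## Dives, phases, and high-resolution metrics

A dive is a maximal submerged interval (depth > 1 m; the surface
threshold is configurable, as the literature leaves it unstated) whose
maximum depth exceeds 15 m and whose duration exceeds 300 s. Six
exclusion rules remove recording errors and outlier behavior: missing
depth records, duplicated timestamps, |vertical speed| > 4 m s⁻¹,
duration > 2800 s, maximum depth > 1200 m, post-dive surface interval
> 300 s. 0.5 Hz depth records are linearly upsampled to 1 Hz first.
The last dive of a record has an undefined surface interval; it keeps
its metrics but drops out of any model requiring surface duration or
efficiency.

Phase segmentation thresholds the vertical speed (first difference of
depth, positive downward) at 0.75 m s⁻¹, after a centered 5 s moving
average that can be disabled. The published wording for the descent
("to the first time the vertical speed reached the threshold") would
end the descent at the first sample; we use the rule symmetric to the
ascent — descent ends the first time the smoothed descending speed
drops below the threshold, ascent begins the last time the ascending
speed is below it. Degenerate profiles collapse the bottom phase to the
deepest sample. Vertical distances for the rate and sinuosity metrics
use the raw (unsmoothed) depth.

Hunting time follows the vertical-sinuosity segmentation approach:
the profile is summarized by the broken stick with the number of
segments chosen by a quality index, and a segment is hunting when its
total vertical distance exceeds 1/0.9 times its net depth change (zero
net with nonzero travel counts as hunting). A consequence worth knowing:
wiggles larger than the summarization tolerance are resolved into
monotone half-oscillation segments with sinuosity 1, so hunting time
responds to *unresolved* bottom variability — which is the intended
regime of the method.

## Broken-stick abstraction

The greedy algorithm starts from the dive endpoints and repeatedly adds
the sample with the largest absolute deviation from the current
piecewise-linear reconstruction, earliest sample on ties. The
transmitted-profile emulation uses exactly 4 interior knots (five
segments); dives where two knots share a timestamp (possible only with
duplicated clock values) are discarded. Low-resolution metrics: first
and last segment rates, bottom duration between knots 2 and 5,
efficiency, and hunting time as the summed duration of segments with
absolute vertical rate below 0.4 m s⁻¹.

Two numerical caveats, verified empirically and covered by tests:

- The exact dive-zone index of the original hunting-time method is not
  restated in the accessible sources; we use the surrogate
  `dzi = max reconstruction error / max depth` with tolerance 0.05 and
  a pluggable criterion interface, and do not claim equivalence.
- The greedy max-error is *not* strictly monotone in the number of
  knots: splitting at the worst point can increase the deviation of a
  neighbor (provably at most 2× the previous maximum). It is monotone
  on ordinary descent–bottom–ascent shapes.

## Track metrics

All great-circle computations use a spherical Earth of radius 6371 km;
dive locations are slerp-interpolated along fixes. Turning angle takes
both bearings at the middle point (incoming bearing = reverse bearing
+ 180°), making it exactly symmetric under path reversal, and is
reported as an absolute angle in [0, 180°] since the models use a
single continuous covariate. First-passage time uses a fixed 25 km
radius; crossing times are linearly interpolated between fixes, and the
value is missing when the path never crosses the circle on one side.

Move persistence is a deliberate simplification of the state-space
formulation used with error-prone Argos tracks (out of scope here,
where tracks are pre-filtered or synthetic and error-free): positions
are resampled at 4 h steps, and the index at step t is the
regression-through-origin coefficient of the displacement vector on its
predecessor, pooled over a centered 5-step window, clipped to [0, 1],
lightly smoothed, and linearly interpolated to dive times. It shares
the range and the qualitative contract of the original — near 1 on
straight constant-speed tracks, near 0 under uncorrelated steps — but
is not a latent-state estimator.

## Poisson mixed models and variance partitioning

nPEE (per dive, or the daily total at day scale) is modeled as Poisson
with a log link; fixed effects are the standardized metrics, and every
individual gets a correlated random intercept and random slope per
metric. Fitting maximizes the marginal likelihood under a Laplace
approximation: per-individual random-effect modes by damped Newton
iterations (batched across individuals), a log-Cholesky
parameterization of the covariance T, and L-BFGS-B over (β, chol T)
started from the pooled Poisson regression with T = 0.1·I. Fixed-effect
standard errors come from the numerical Hessian of the marginal
likelihood. A full-covariance fit that fails to converge is refit with
diagonal T and flagged. On shared datasets the fit agrees with R's
`glmmTMB` (the reference implementation in this literature) to ~1e-3
in coefficients and log-likelihood; that cross-check is part of the
test suite.

The explained-variance decomposition on the latent (log) scale uses
σ²F = Var(X·β_slopes), σ²I = T[0,0], σ²S = trace(T_slopes·Σ_X), and the
Poisson-specific variance σ²d = ln(1 + 1/λ̄) from the lognormal
approximation, with λ̄ the observed mean response by default (a
model-based λ̄ is available). R² shares divide each component by the
total. Cross-terms between intercepts and slopes vanish because
predictors are mean-centered; this is the assumption under which the
intercept/slope attribution is clean.

Two consequences of this construction that the synthetic experiments
reproduce: aggregation to daily totals raises λ̄ and shrinks σ²d, so
among-individual shares (R²I, R²S) grow at the day scale; and with only
~20 individuals the realized random-effect variance of a single dataset
fluctuates widely, so share recovery is assessed on seed averages (the
estimator is unbiased; single-seed deviations up to ±0.15 are sampling
noise of the 20 realized individuals).

## Boosted trees and cross-validation

The nonparametric comparator is gradient-boosted trees with a Tweedie
deviance objective (variance power 1.5), suited to overdispersed,
zero-inflated counts. The default tuning grid — learning rate
{0.05, 0.1}, depth {2, 4, 6}, subsample {0.7, 1.0}, up to 2000 rounds
with early stopping 50 — is selected by inner grouped (by individual)
3-fold CV; fixed parameters can be passed instead, which the heavier
experiments do. All fits are single-threaded and seeded, hence
bit-reproducible.

Leave-one-individual-out cross-validation refits the model without each
individual and predicts it at the population level (random effects
zero — the left-out individual's effects are unknowable). Predictor
standardization is recomputed inside each training fold and applied to
the held-out individual, which avoids leakage; standardizing once on
the full data (as a field analysis would after pooling) is available as
an option, and the difference is negligible at these sizes. Scores per
individual: RMSE, mRMSE = RMSE/ȳ, sdRMSE = RMSE/σ_y (so
sdRMSE = mRMSE·ȳ/σ_y identically), and Pearson correlation, summarized
as mean ± SD across individuals. Individual retention mirrors field
practice: at least 30 recorded days for any model, and at least an
average of 15 locations per day additionally for track-metric models.

## The synthetic generator

The study system is observational — there is no true generative model —
so the generator is an explicit stand-in that reproduces the
*statistical structure* the analysis assumes, with every parameter
knowable:

- **Dives**: piecewise-linear descent–bottom–ascent profiles at 1 Hz;
  depths 200–800 m, durations 10–25 min, surface intervals 120–280 s.
  Transit limbs include a slower sub-phase (15% of the depth at
  0.55–0.9 of the main rate) emulating interrupted transits of real
  dives; bottom wiggles are triangular dips from a shoulder depth to
  the maximum depth, each adding twice the amplitude of vertical
  distance. All vertical speeds stay under the 4 m s⁻¹ cap, so clean
  generated dives pass the exclusion rules by construction.
- **Acceleration**: gravity rotated by a slowly varying pitch plus
  Gaussian baseline dynamics (SD 0.2 m s⁻²); capture bursts add noise
  scaled so the within-window dynamic SD is `burst_amplitude_snr`
  (default 5) times baseline. No biomechanics is implied — the detector
  only needs SD contrast above 0.33 Hz.
- **Counts**: per dive, a latent standard-normal x drives the chosen
  metric (ascent rate by default, wiggle load for the hunting-time
  driver) and the encounter rate
  λ = exp(β₀ + b₀ᵢ + (β₁ + b₁ᵢ)·x) with β₀ = ln 9 (matching a mean of
  ~9 encounters per dive), β₁ = 0.5, and correlated individual effects
  (τ₀ = 0.5, τ₁ = 0.3). Truth events are placed in the bottom phase
  with ≥2 s separation; the realized (placed) count is the recorded
  truth, so event lists and per-dive counts are exactly conserved.
- **Track**: a two-mode correlated random walk (intensive: 0.3 m s⁻¹,
  tortuous; extensive: 1.0 m s⁻¹, directed; mode switching between
  dives with probability 0.1) in a local planar frame around a
  configurable origin, sampled every 15 min, error-free.

Default configuration mirrors the emulated field study (21 individuals,
71 days); tests and the acceptance script run deliberately smaller
studies — e.g. 10–20 individuals at 0.1–0.35 days for signal-level
experiments and 20 × 500 dives for generative-model experiments — which
are ample for the properties they check. Everything is a pure function
of (config, seed, individual id).

What passing on synthetic data does **not** show: robustness to real
sensor artifacts (drift, dropouts, Argos location error), to dive
shapes outside the descent–bottom–ascent family, to non-Poisson
overdispersion in real counts, or to ecological confounding between
metrics. The package separates every stage behind a small interface
precisely so real data can replace the generator stream by stream.

## Numerical conventions

- Linear-predictor values are clipped at ±30 before exponentiation.
- Log-Cholesky diagonals are bounded in [e⁻⁷, e³] during optimization;
  a boundary fit (T → 0) is reported as-is, matching the usual
  singular-fit behavior of mixed-model software.
- Knot/cluster/threshold ties break toward the earliest time or lower
  value, so every algorithm is deterministic.
- Sample SDs use ddof 1 in the detector (matching R's `sd`);
  standardization and variance partitioning use population (ddof 0)
  moments on the fitting set.
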