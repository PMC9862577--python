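"""Analysis tables and the model comparison.

Assembles per-dive and per-day records from the sensor streams, applies
the individual retention filters, and evaluates how well each movement
metric predicts prey-encounter counts with (a) variance-partitioned
Poisson mixed models and (b) Tweedie-objective boosted regression
trees, both scored by leave-one-individual-out cross-validation with
RMSE, mean-normalized RMSE, SD-normalized RMSE, and Pearson
correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dives as dv
from . import pee as pe
from . import profiles as pr
from . import track as tr
from .glmm import fit_poisson_glmm, partition_variance, standardize
from .synthetic import TripData

HIGHRES_METRICS = ["descent_rate", "ascent_rate", "bottom_duration",
                   "surface_duration", "efficiency", "sinuosity",
                   "hunting_time"]
LOWRES_METRICS = ["descent_rate_lr", "ascent_rate_lr", "bottom_duration_lr",
                  "efficiency_lr", "hunting_time_lr"]
TRACK_METRICS = ["horizontal_speed", "turning_angle", "fpt",
                 "move_persistence"]

MIN_RECORDING_DAYS = 30.0
MIN_LOCATIONS_PER_DAY = 15.0


def process_trip(trip: TripData, detect_events: bool = True,
                 include_track: bool = True,
                 include_lowres: bool = True) -> dict:
    """Run the full per-individual pipeline on one trip.

    Returns a dict with ``dive_records`` (one row per retained dive with
    all metrics and the nPEE response), ``day_counts``, ``events``, and
    ``exclusions``.
    """
    cfg = trip.config
    depth = dv.upsample_depth(trip.depth)
    all_dives = dv.detect_dives(depth, individual_id=trip.individual_id)
    kept, excl = dv.filter_dives(all_dives)

    rows = []
    for d in kept:
        dv.segment_phases(d)
        m = dv.compute_dive_metrics(d)
        m["hunting_time"], _ = dv.hunting_time_highres(d)
        if include_lowres:
            fit = pr.abstract_to_five_segments(d.profile)
            if fit is None:
                m.update({k: np.nan for k in LOWRES_METRICS})
            else:
                m.update(pr.lowres_metrics(fit, d.surface_duration))
        m.update({"individual_id": trip.individual_id, "dive_id": d.dive_id,
                  "start": d.start, "end": d.end, "max_depth": d.max_depth,
                  "day": int(d.start // 86400)})
        rows.append(m)
    records = pd.DataFrame(rows)

    if detect_events:
        sd3 = pe.smoothed_dynamic_sd(trip.accel)
        events = pe.detect_pee(sd3, individual_id=trip.individual_id)
    else:
        events = list(trip.truth_pee)
    dive_counts, day_counts = pe.count_pee(events, kept)
    if len(records):
        records = records.merge(dive_counts, on="dive_id", how="left")
        records["npee"] = records["npee"].fillna(0).astype(int)

    if include_track and len(records):
        tm = tr.track_metrics(trip.track, records["start"].to_numpy(),
                              dive_ids=records["dive_id"].to_numpy())
        records = records.merge(tm.drop(columns=["t"]), on="dive_id",
                                how="left")
    return {"dive_records": records, "day_counts": day_counts,
            "events": events, "exclusions": excl, "n_dives_total": len(all_dives)}


def build_dataset(trips: list[TripData], **kwargs) -> dict:
    """Pipeline over several individuals; concatenated tables."""
    parts = [process_trip(t, **kwargs) for t in trips]
    records = pd.concat([p["dive_records"] for p in parts], ignore_index=True)
    day_counts = pd.concat(
        [p["day_counts"].assign(individual_id=t.individual_id)
         for p, t in zip(parts, trips)], ignore_index=True)
    events = [e for p in parts for e in p["events"]]
    return {"dive_records": records, "day_counts": day_counts,
            "events": events, "parts": parts}


def aggregate_daily(records: pd.DataFrame, day_counts: pd.DataFrame,
                    metrics: list[str] | None = None) -> pd.DataFrame:
    """Day-scale table: unweighted within-day means of the metrics and
    the day's total event count as the response (surface events count)."""
    if metrics is None:
        metrics = [c for c in records.columns
                   if c in HIGHRES_METRICS + LOWRES_METRICS + TRACK_METRICS]
    grouped = (records.groupby(["individual_id", "day"])[metrics]
               .mean().reset_index())
    n_dives = (records.groupby(["individual_id", "day"])
               .size().rename("n_dives").reset_index())
    out = grouped.merge(n_dives, on=["individual_id", "day"])
    out = out.merge(day_counts, on=["individual_id", "day"], how="left")
    out["npee_day"] = out["npee_day"].fillna(0).astype(int)
    return out.rename(columns={"npee_day": "npee"})


def filter_individuals(summary: pd.DataFrame,
                       min_days: float = MIN_RECORDING_DAYS,
                       min_locs: float = MIN_LOCATIONS_PER_DAY) -> pd.DataFrame:
    """Retention rules per individual.

    ``summary`` needs columns individual_id, n_days, locs_per_day.
    Individuals under ``min_days`` are dropped from every model; those
    under ``min_locs`` are additionally dropped from track-metric models.
    """
    out = summary.copy()
    out["keep_dive_models"] = out["n_days"] >= min_days
    out["keep_track_models"] = out["keep_dive_models"] & \
        (out["locs_per_day"] >= min_locs)
    out["reason"] = np.where(~out["keep_dive_models"], "recording_days",
                             np.where(~out["keep_track_models"],
                                      "locations_per_day", ""))
    return out


# ---------------------------------------------------------------------------
# Boosted regression trees (Tweedie objective)

DEFAULT_BRT_GRID = {
    "eta": [0.05, 0.1],
    "max_depth": [2, 4, 6],
    "subsample": [0.7, 1.0],
}
BRT_MAX_ROUNDS = 2000
BRT_EARLY_STOPPING = 50
TWEEDIE_POWER = 1.5


@dataclass
class BrtFit:
    booster: object
    params: dict
    n_rounds: int
    predictors: list
    cv_score: float = np.nan

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        import xgboost as xgb
        X = df[self.predictors].to_numpy(dtype=float)
        return self.booster.predict(xgb.DMatrix(X))


def _grid_iter(grid: dict):
    from itertools import product
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def fit_brt(df: pd.DataFrame, predictors: list[str], response: str = "npee",
            group: str = "individual_id", grid: dict | None = None,
            params: dict | None = None, seed: int = 0,
            n_rounds: int = BRT_MAX_ROUNDS,
            early_stopping: int = BRT_EARLY_STOPPING,
            n_inner_folds: int = 3) -> BrtFit:
    """Gradient-boosted trees minimizing Tweedie deviance.

    With ``params`` given, rounds are chosen by early stopping on one
    grouped validation split; otherwise hyperparameters come from an
    inner grouped CV over ``grid`` (the declared default grid). Fully
    deterministic given ``seed``.
    """
    import xgboost as xgb
    from sklearn.model_selection import GroupKFold

    X = df[predictors].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    g = df[group].to_numpy()
    base = {"objective": "reg:tweedie",
            "tweedie_variance_power": TWEEDIE_POWER,
            "nthread": 1, "seed": int(seed),
            "eval_metric": f"tweedie-nloglik@{TWEEDIE_POWER}"}
    if y.std() == 0:
        # degenerate constant response: one stump at the base score
        params_c = dict(base, eta=1.0, max_depth=1, base_score=max(y[0], 1e-6))
        bst = xgb.train(params_c, xgb.DMatrix(X, label=y), num_boost_round=1)
        return BrtFit(bst, params_c, 1, list(predictors))

    n_folds = min(n_inner_folds, len(np.unique(g)))
    gkf = GroupKFold(n_splits=max(2, n_folds))
    splits = list(gkf.split(X, y, g))

    def _cv(p: dict) -> tuple[float, int]:
        scores, iters = [], []
        for tr_idx, va_idx in splits:
            dtr = xgb.DMatrix(X[tr_idx], label=y[tr_idx])
            dva = xgb.DMatrix(X[va_idx], label=y[va_idx])
            bst = xgb.train(dict(base, **p), dtr, num_boost_round=n_rounds,
                            evals=[(dva, "val")],
                            early_stopping_rounds=early_stopping,
                            verbose_eval=False)
            scores.append(bst.best_score)
            iters.append(bst.best_iteration + 1)
        return float(np.mean(scores)), int(round(np.mean(iters)))

    if params is not None:
        score, best_rounds = _cv(params)
        best_params = dict(params)
    else:
        grid = DEFAULT_BRT_GRID if grid is None else grid
        best_params, best_rounds, score = None, None, np.inf
        for p in _grid_iter(grid):
            s, it = _cv(p)
            if s < score:
                score, best_params, best_rounds = s, dict(p), it
    bst = xgb.train(dict(base, **best_params), xgb.DMatrix(X, label=y),
                    num_boost_round=best_rounds)
    return BrtFit(bst, dict(base, **best_params), best_rounds,
                  list(predictors), cv_score=score)


# ---------------------------------------------------------------------------
# Leave-one-individual-out cross-validation

@dataclass
class ModelSpec:
    """What to fit in each CV fold."""

    kind: str  # "glmm" | "brt"
    predictors: list
    response: str = "npee"
    group: str = "individual_id"
    refit_standardization: bool = True
    glmm_kwargs: dict = field(default_factory=dict)
    brt_params: dict | None = None
    brt_grid: dict | None = None
    seed: int = 0


@dataclass
class CvResult:
    per_individual: pd.DataFrame
    predictions: pd.DataFrame

    def summary(self) -> dict:
        s = {}
        for c in ("rmse", "mrmse", "sdrmse", "corr"):
            vals = self.per_individual[c].to_numpy(dtype=float)
            s[f"{c}_mean"] = float(np.nanmean(vals))
            s[f"{c}_sd"] = float(np.nanstd(vals, ddof=1)) if vals.size > 1 else np.nan
        return s


def rmse(yhat: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error: sqrt(sum((yhat - y)^2) / n)."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def loio_cv(df: pd.DataFrame, spec: ModelSpec) -> CvResult:
    """Leave-one-individual-out evaluation of a model specification.

    Each individual is predicted by a model refitted without it
    (population-level prediction for the mixed model, since the left-out
    individual's effects are unknowable); predictors are re-standardized
    on each training fold and that standardization applied to the
    held-out individual.
    """
    ids = pd.unique(df[spec.group])
    if ids.size < 3:
        raise ValueError("need at least three individuals")
    rows, preds = [], []
    for gid in ids:
        test = df[df[spec.group] == gid]
        train = df[df[spec.group] != gid]
        if spec.refit_standardization:
            train_s, stats = standardize(train, spec.predictors)
            test_s, _ = standardize(test, spec.predictors, stats=stats)
        else:
            train_s, test_s = train, test
        train_s = train_s.dropna(subset=spec.predictors + [spec.response])
        test_s = test_s.dropna(subset=spec.predictors + [spec.response])
        if len(test_s) == 0 or len(train_s) == 0:
            continue
        y = test_s[spec.response].to_numpy(dtype=float)
        if spec.kind == "glmm":
            fit = fit_poisson_glmm(train_s, spec.predictors,
                                   response=spec.response, group=spec.group,
                                   compute_se=False, **spec.glmm_kwargs)
            yhat = fit.predict(test_s[spec.predictors].to_numpy(dtype=float))
        elif spec.kind == "brt":
            fit = fit_brt(train_s, spec.predictors, response=spec.response,
                          group=spec.group, params=spec.brt_params,
                          grid=spec.brt_grid, seed=spec.seed)
            yhat = fit.predict(test_s)
        else:
            raise ValueError(f"unknown model kind {spec.kind!r}")
        r = rmse(yhat, y)
        ybar = float(y.mean())
        ysd = float(y.std(ddof=0))
        if ysd > 0 and np.std(yhat) > 0:
            corr = float(np.corrcoef(yhat, y)[0, 1])
        else:
            corr = np.nan
        rows.append({"individual_id": gid, "n": y.size, "rmse": r,
                     "mrmse": r / ybar if ybar > 0 else np.nan,
                     "sdrmse": r / ysd if ysd > 0 else np.nan,
                     "corr": corr})
        preds.append(pd.DataFrame({spec.group: gid, "y": y, "yhat": yhat}))
    return CvResult(pd.DataFrame(rows),
                    pd.concat(preds, ignore_index=True))


def evaluate_models(df: pd.DataFrame, model_sets: dict[str, list[str]],
                    kinds: tuple = ("glmm",), response: str = "npee",
                    brt_params: dict | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Fit + partition + cross-validate a family of metric sets.

    ``model_sets`` maps a model name (e.g. ``"ascent_rate"`` or
    ``"dive"``) to its predictor list. Returns one row per (model,
    kind) mirroring a performance table: r2 components (GLMM only, %),
    CV RMSE/mRMSE/sdRMSE/correlation means and SDs.
    """
    out = []
    for name, predictors in model_sets.items():
        data = df.dropna(subset=predictors + [response])
        data_s, _ = standardize(data, predictors)
        for kind in kinds:
            row = {"model": name, "kind": kind,
                   "n": len(data_s),
                   "n_individuals": data_s["individual_id"].nunique()}
            if kind == "glmm":
                fit = fit_poisson_glmm(data_s, predictors, response=response,
                                       compute_se=False)
                part = partition_variance(fit, data_s, response=response)
                row.update({"r2_f": 100 * part["r2_f"],
                            "r2_i": 100 * part["r2_i"],
                            "r2_s": 100 * part["r2_s"],
                            "converged": fit.converged})
                cv = loio_cv(data, ModelSpec("glmm", predictors,
                                             response=response))
            else:
                cv = loio_cv(data, ModelSpec("brt", predictors,
                                             response=response,
                                             brt_params=brt_params,
                                             seed=seed))
            row.update(cv.summary())
            out.append(row)
    return pd.DataFrame(out)


def descriptive_stats(records: pd.DataFrame, day_records: pd.DataFrame
                      ) -> dict:
    """Headline descriptive numbers of an assembled dataset."""
    frac = (records.groupby("individual_id")["npee"]
            .apply(lambda s: (s > 0).mean()))
    return {
        "n_dives": int(len(records)),
        "npee_per_dive_mean": float(records["npee"].mean()),
        "npee_per_dive_sd": float(records["npee"].std(ddof=1)),
        "npee_per_dive_max": int(records["npee"].max()),
        "npee_per_day_mean": float(day_records["npee"].mean()),
        "npee_per_day_sd": float(day_records["npee"].std(ddof=1)),
        "npee_per_day_max": int(day_records["npee"].max()),
        "pct_dives_with_pee": float(100 * frac.mean()),
    }
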