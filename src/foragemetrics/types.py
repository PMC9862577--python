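"""Lightweight containers for biologging streams and derived objects.

Conventions: time in seconds from an arbitrary per-deployment origin,
depth in meters positive downward, locations in WGS84 decimal degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DepthSeries:
    """Uniformly sampled depth record (0.5 or 1 Hz), positive-down meters."""

    t: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.t.shape != self.depth.shape:
            raise ValueError("t and depth must have the same shape")

    def __len__(self) -> int:
        return self.t.size

    def slice(self, start: float, end: float) -> "DepthSeries":
        """Samples with start <= t <= end (closed interval)."""
        m = (self.t >= start) & (self.t <= end)
        return DepthSeries(self.t[m], self.depth[m])


@dataclass
class AccelSeries:
    """Uniform tri-axial acceleration block (12.5 or 16 Hz typical)."""

    t0: float
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (self.ax.shape == self.ay.shape == self.az.shape):
            raise ValueError("axes must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.ax.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.ax.size) / self.fs

    @property
    def duration(self) -> float:
        return self.ax.size / self.fs

    def copy(self) -> "AccelSeries":
        return AccelSeries(self.t0, self.fs, self.ax.copy(), self.ay.copy(),
                           self.az.copy())


@dataclass(frozen=True)
class PeeEvent:
    """One prey-encounter event: a burst of head acceleration."""

    individual_id: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end before start")


@dataclass
class Dive:
    """One dive cycle with phase boundaries.

    ``surface_duration`` is the post-dive surface interval to the next
    dive start; NaN for the last dive of a record.
    """

    individual_id: int
    dive_id: int
    start: float
    end: float
    profile: DepthSeries
    max_depth: float
    surface_duration: float = np.nan
    descent_end: float = np.nan
    ascent_start: float = np.nan

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BrokenStickFit:
    """Piecewise-linear abstraction of a dive profile."""

    knot_t: np.ndarray
    knot_depth: np.ndarray
    reconstruction_error: float
    dzi: float

    @property
    def k(self) -> int:
        """Number of linear segments."""
        return self.knot_t.size - 1

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.knot_t, self.knot_depth)


@dataclass
class GlmmFit:
    """Fitted Poisson mixed model with per-individual intercept+slopes."""

    predictors: list
    beta: np.ndarray
    beta_se: np.ndarray
    T: np.ndarray
    loglik: float
    converged: bool
    re_structure: str = "full"
    singular_fallback: bool = False
    ranef: dict = field(default_factory=dict)
    n_obs: int = 0
    n_groups: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Population-level prediction (random effects set to zero)."""
        X = np.asarray(X, dtype=float)
        eta = self.beta[0] + X @ self.beta[1:]
        return np.exp(np.clip(eta, -30.0, 30.0))
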