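"""LOWESS smoothing and slope-sign inflection detection.

Standard single-pass locally weighted running-line smoother: at each
observed x, a degree-1 weighted least-squares fit over the nearest
``frac * n`` neighbours with tricube weights (no robustness iterations).
Inflections are reported where the fitted curve's slope changes sign,
suppressing sub-noise-floor slopes and low-prominence micro-oscillations
of the pointwise-evaluated fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["SmoothCurve", "LowessSmoother", "lowess", "find_inflections"]

#: Default slope noise floor (outcome units per x unit) below which a
#: slope sign change is not reported as an inflection.
DEFAULT_NOISE_FLOOR = 1e-3


@dataclass
class SmoothCurve:
    """A fitted LOWESS curve evaluated at the observed x values."""

    x: np.ndarray          # sorted ascending, duplicates collapsed
    y_fitted: np.ndarray
    frac: float
    inflection_x: list[float] = field(default_factory=list)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def _local_linear(x: np.ndarray, y: np.ndarray, x0: float, k: int) -> float:
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h <= 0:
        # all k nearest neighbours share x0: fall back to their mean
        return float(y[d == 0].mean())
    w = _tricube(d / h)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        return float(ym)
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


class LowessSmoother(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper around the running-line smoother.

    ``fit`` computes the curve at each observed x; ``predict`` linearly
    interpolates on the fitted curve.
    """

    def __init__(self, frac: float = 0.8, noise_floor: float = DEFAULT_NOISE_FLOOR):
        self.frac = frac
        self.noise_floor = noise_floor

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        if len(x) < 10:
            raise ValueError(f"need >= 10 points, got {len(x)}")
        if not 0.0 < self.frac <= 1.0:
            raise ValueError("frac must be in (0, 1]")
        k = int(np.ceil(self.frac * len(x)))
        if k < 2:
            raise ValueError(
                f"frac={self.frac} selects {k} neighbour(s); a local line needs >= 2"
            )
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        fitted = np.array([_local_linear(xs, ys, x0, k) for x0 in xs])
        # collapse duplicate x (identical neighbourhoods give identical fits)
        xu, idx = np.unique(xs, return_index=True)
        yu = fitted[idx]
        if not np.all(np.isfinite(yu)):
            raise ValueError("LOWESS produced non-finite fitted values")
        curve = SmoothCurve(x=xu, y_fitted=yu, frac=self.frac)
        curve.inflection_x = find_inflections(curve, noise_floor=self.noise_floor)
        self.curve_ = curve
        self.x_grid_ = xu
        self.y_fitted_ = yu
        self.inflection_x_ = curve.inflection_x
        return self

    def predict(self, X):
        if not hasattr(self, "curve_"):
            raise AttributeError("smoother is not fitted")
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.interp(x, self.x_grid_, self.y_fitted_)


def lowess(x, y, frac: float = 0.8) -> SmoothCurve:
    """Fit the smoother and return the curve with detected inflections."""
    return LowessSmoother(frac=frac).fit(x, y).curve_


def find_inflections(
    curve: SmoothCurve,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    min_prominence: float | None = None,
) -> list[float]:
    """x positions where the fitted slope changes sign.

    An inflection is a local extremum of the fitted curve — the point
    where successive first-difference slopes on the x grid change sign.
    Two suppressions guard against numerical wiggle: a curve whose slope
    never reaches ``noise_floor`` in magnitude is treated as flat
    (no inflections), and each extremum must have a topographic
    prominence of at least ``min_prominence`` (default 2% of the fitted
    range), which merges the micro-oscillations a pointwise-evaluated
    smoother produces near a flat crest into the single underlying
    turn. An empty list means the curve is monotone up to these
    tolerances.
    """
    x, yf = curve.x, curve.y_fitted
    if len(x) < 3:
        return []
    slopes = np.diff(yf) / np.diff(x)
    if np.max(np.abs(slopes)) < noise_floor:
        return []
    if min_prominence is None:
        min_prominence = 0.02 * float(np.ptp(yf))
    peaks, _ = signal.find_peaks(yf, prominence=min_prominence)
    troughs, _ = signal.find_peaks(-yf, prominence=min_prominence)
    idx = np.sort(np.concatenate([peaks, troughs]))
    return [float(x[i]) for i in idx]
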