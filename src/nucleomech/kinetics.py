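"""Sigmoidal kinetics of expression and wrinkling time courses.

Live-imaging intensity curves (sampled every 20 min over 36 h in the
reference protocol) follow extended sigmoidal trajectories.  They are
modelled with the Richards (generalized logistic) family

    y(t) = lower + (upper - lower) / (1 + exp(-rate*(t - t_c)))^(1/nu)

whose inflection (maximum-slope) time is t_infl = t_c - ln(nu)/rate; the
plain logistic is the nu = 1 special case with t_infl = t_c.  The readout
of interest is the inflection time and, across two fitted curves (e.g.
progerin expression vs envelope wrinkling), the signed interval between
their inflection points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInputError, FitError

__all__ = [
    "TimeSeries",
    "SigmoidFit",
    "minmax_normalize",
    "richards",
    "fit_sigmoid",
    "inflection_interval",
]


@dataclass(frozen=True)
class TimeSeries:
    """Sampled intensity/percentage time course (times in hours)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values differ in length")
        if len(t) < 8:
            raise ValueError(f"need >= 8 points, got {len(t)}")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise ValueError("non-finite entries in time series")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted Richards curve parameters plus goodness of fit."""

    lower: float
    upper: float
    t_infl: float
    rate: float
    asymmetry: float
    rss: float
    t_c: float

    def __call__(self, t):
        return richards(np.asarray(t, dtype=float), self.lower, self.upper,
                        self.rate, self.t_c, self.asymmetry)


def minmax_normalize(series: TimeSeries) -> TimeSeries:
    """Map values through (x - x_min)/(x_max - x_min) onto [0, 1]."""
    v = np.asarray(series.values, dtype=float)
    rng = v.max() - v.min()
    if rng == 0:
        raise DegenerateInputError("constant series cannot be min-max normalized")
    return TimeSeries(times=series.times, values=(v - v.min()) / rng, label=series.label)


def richards(t, lower, upper, rate, t_c, nu):
    """Richards curve; numerically safe for large |rate*(t - t_c)|."""
    z = -rate * (t - t_c)
    # log1p(exp(z)) without overflow
    log_denom = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
    return lower + (upper - lower) * np.exp(-log_denom / nu)


def _inflection_time(rate: float, t_c: float, nu: float) -> float:
    return t_c - np.log(nu) / rate


def fit_sigmoid(series: TimeSeries, asymmetries=(0.5, 1.0, 2.0)) -> SigmoidFit:
    """Least-squares Richards fit with a deterministic multistart grid.

    Starts combine t_c at the observed-time quartiles, an initial rate
    from the steepest finite-difference slope, and the given asymmetry
    values; the best residual sum of squares wins.  Decreasing series are
    rejected (fit the reversed series instead if that is intended).
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant series")
    trend = np.polyfit(t, y, 1)[0]
    if trend < 0:
        raise FitError("series trend is decreasing; the model fits rising sigmoids",
                       diagnostics={"trend_slope": float(trend)})

    span = np.ptp(y)
    slopes = np.diff(y) / np.diff(t)
    rate0 = max(4.0 * slopes.max() / span, 1e-3)
    t_lo, t_hi = t[0], t[-1]
    half_span = 0.5 * (t_hi - t_lo)

    def resid(p):
        lower, upper, rate, t_c, nu = p
        return richards(t, lower, upper, rate, t_c, nu) - y

    best = None
    for t_c0 in np.quantile(t, [0.25, 0.5, 0.75]):
        for nu0 in asymmetries:
            p0 = [y.min(), y.max(), rate0, t_c0, nu0]
            try:
                sol = least_squares(
                    resid, p0,
                    bounds=([-np.inf, -np.inf, 1e-6, t_lo - half_span, 1e-3],
                            [np.inf, np.inf, np.inf, t_hi + half_span, 1e3]),
                    method="trf", max_nfev=2000)
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise FitError("no Richards fit converged from any start",
                       diagnostics={"n_starts": 3 * len(asymmetries)})
    rss, (lower, upper, rate, t_c, nu) = best
    if upper < lower:
        raise FitError("fit inverted (upper < lower)",
                       diagnostics={"lower": lower, "upper": upper})
    return SigmoidFit(lower=float(lower), upper=float(upper),
                      t_infl=float(_inflection_time(rate, t_c, nu)),
                      rate=float(rate), asymmetry=float(nu),
                      rss=rss, t_c=float(t_c))


def inflection_interval(fit_a: SigmoidFit, fit_b: SigmoidFit) -> float:
    """Signed interval t_infl(b) - t_infl(a) in hours."""
    return fit_b.t_infl - fit_a.t_infl
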