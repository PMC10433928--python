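"""Sap flux density response to vapour pressure deficit.

Per tree, the half-hourly morning record of sap flux density ``Js``
(cm h-1) against vapour pressure deficit ``D`` (kPa) is summarised by two
competing curve forms:

* a parabola ``Js = a D^2 + b D (+ c)`` whose vertex gives the deficit
  ``D_Jsmax`` at which sap flux peaks and the peak flux ``Jsmax``;
* a logarithmic response ``Js = Jsref + mJs ln(D)`` whose slope ``mJs``
  measures the sensitivity of sap flux to atmospheric drought and whose
  intercept ``Jsref`` is the flux at D = 1 kPa.

The better model is chosen by R^2; ties go to the parabola.  Data are
restricted to the dawn-to-midday window (rising limb of D) to avoid the
afternoon hysteresis between transpiration and D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParabolicFit",
    "LogFit",
    "filter_morning",
    "fit_parabolic",
    "fit_log",
    "select_model",
]

#: D threshold (kPa) that marks dawn for the morning window.
DAWN_D_THRESHOLD = 0.1

#: Hour of solar noon closing the morning window.
DEFAULT_NOON_HOUR = 13.0


@dataclass(frozen=True)
class ParabolicFit:
    """Least-squares parabola through the Js-D cloud.

    ``status`` is ``"ok"`` when the curvature is negative (vertex is a
    maximum inside a physically meaningful range) and ``"no-vertex"``
    when ``a >= 0``, in which case ``d_jsmax``/``jsmax`` are NaN.
    The vertex satisfies ``d_jsmax = -b/(2a)`` and
    ``jsmax = a d_jsmax^2 + b d_jsmax + c`` exactly.
    """

    a: float            # cm h-1 kPa-2
    b: float            # cm h-1 kPa-1
    c: float            # cm h-1; 0.0 when fit without intercept
    r2: float
    d_jsmax: float      # kPa
    jsmax: float        # cm h-1
    n: int
    status: str = "ok"
    with_intercept: bool = True


@dataclass(frozen=True)
class LogFit:
    """OLS fit of Js on ln(D): ``Js = jsref + m_js ln(D)``."""

    jsref: float        # cm h-1, predicted Js at D = 1 kPa
    m_js: float         # cm h-1 per ln(kPa)
    r2: float
    n: int


def filter_morning(df: pd.DataFrame, *, d_col: str = "D_kPa",
                   time_col: str = "timestamp",
                   threshold: float = DAWN_D_THRESHOLD,
                   noon_hour: float = DEFAULT_NOON_HOUR) -> pd.DataFrame:
    """Retain dawn-to-midday rows of a timestamped series.

    For each calendar day the window opens at the first timestamp whose D
    exceeds ``threshold`` and closes at solar noon (inclusive).  A day
    whose D never exceeds the threshold raises ``ValueError`` naming the
    day.  The retained row count is logged.
    """
    ts = pd.to_datetime(df[time_col])
    pieces = []
    for day, day_df in df.groupby(ts.dt.date, sort=True):
        day_ts = pd.to_datetime(day_df[time_col])
        hours = (day_ts.dt.hour + day_ts.dt.minute / 60.0
                 + day_ts.dt.second / 3600.0)
        above = day_df[d_col].to_numpy() > threshold
        if not above.any():
            raise ValueError(
                f"day {day}: D never exceeds {threshold} kPa; "
                "morning window is empty")
        start = int(np.argmax(above))
        in_window = np.zeros(len(day_df), dtype=bool)
        in_window[start:] = True
        in_window &= (hours <= noon_hour).to_numpy()
        pieces.append(day_df[in_window])
    out = pd.concat(pieces, axis=0)
    logger.info("filter_morning: retained %d of %d rows", len(out), len(df))
    return out


def fit_parabolic(d, js, *, intercept: bool = True) -> ParabolicFit:
    """Fit ``Js = a D^2 + b D (+ c)`` by least squares.

    The vertex location ``-b/(2a)`` and the flux obtained by inserting it
    back into the fitted curve are returned as ``d_jsmax`` and ``jsmax``.
    With ``intercept=False`` the curve is forced through the origin, the
    strict printed form of the response equation; the default keeps an
    intercept because the origin constraint biases the vertex location
    low when the flux saturates near the top of the observed D range.
    R^2 is computed against the mean-of-Js baseline in both modes so the
    two response models are comparable.
    """
    d = np.asarray(d, dtype=float)
    js = np.asarray(js, dtype=float)
    if d.size != js.size:
        raise ValueError("D and Js must have equal length")
    if d.size < 3:
        raise ValueError("parabolic fit needs at least 3 points")
    if np.any(d < 0):
        raise ValueError("D must be non-negative")
    if np.ptp(d) == 0:
        raise ValueError("all D values identical; design is rank deficient")
    cols = [d ** 2, d] + ([np.ones_like(d)] if intercept else [])
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, js, rcond=None)
    a, b = float(beta[0]), float(beta[1])
    c = float(beta[2]) if intercept else 0.0
    resid = js - design @ beta
    sst = float(np.sum((js - js.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else -np.inf
    if a < 0:
        d_jsmax = -b / (2.0 * a)
        jsmax = a * d_jsmax ** 2 + b * d_jsmax + c
        status = "ok"
    else:
        warnings.warn("parabola opens upward (a >= 0); vertex is not a "
                      "maximum — D_Jsmax undefined within range")
        d_jsmax = np.nan
        jsmax = np.nan
        status = "no-vertex"
    return ParabolicFit(a, b, c, r2, d_jsmax, jsmax, d.size, status,
                        intercept)


def fit_log(d, js) -> LogFit:
    """OLS of Js on ln(D); slope ``mJs``, intercept ``Jsref``."""
    d = np.asarray(d, dtype=float)
    js = np.asarray(js, dtype=float)
    if d.size != js.size:
        raise ValueError("D and Js must have equal length")
    if d.size < 3:
        raise ValueError("logarithmic fit needs at least 3 points")
    if np.any(d <= 0):
        raise ValueError("logarithmic fit requires strictly positive D")
    x = np.log(d)
    if np.ptp(x) == 0:
        raise ValueError("ln(D) has zero variance; regressor degenerate")
    design = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(design, js, rcond=None)
    m_js, jsref = float(beta[0]), float(beta[1])
    resid = js - design @ beta
    sst = float(np.sum((js - js.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else -np.inf
    return LogFit(jsref, m_js, r2, d.size)


def select_model(parabolic: ParabolicFit, log: LogFit) -> str:
    """Pick the response form with the higher R^2; ties -> parabolic."""
    if parabolic.n != log.n:
        raise ValueError(
            f"fits cover different point counts ({parabolic.n} vs {log.n})")
    return "parabolic" if parabolic.r2 >= log.r2 else "logarithmic"
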