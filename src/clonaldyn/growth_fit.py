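"""Logistic fitting and classification of tumor growth series.

Tumor-volume (mm^3) or cell-count time series are mapped onto normalized
time [0, 1] (first measurement -> 0, last -> 1) and fitted with the
closed-form logistic solution N(t) = C N0 / (N0 + (C - N0) e^{-r t}) by
bounded nonlinear least squares, multi-started over a grid of growth rates
spanning the range seen across model systems (r ~ 0.5 to 31 on normalized
time).  A series is classified logistic when the fit converged and explains
at least ``r2_threshold`` (default 0.9) of the variance.

Capacity bounds default to the experimental context: ethics-capped xenograft
volumes of 1500-5000 mm^3 in vivo, and roughly 150-200 million cells for
high-surface culture vessels in vitro; the bounds widen by x2 whenever the
observed maximum exceeds them, so an unusually large series is never
unfittable by construction.

Cohort summaries report the fraction of series classified logistic, the
fraction of fitted rates above the first period-doubling (r > 3), and
medians/within-variance of the rates — both over logistic fits only and over
all converged fits, since published summaries are ambiguous about which set
they pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .logistic_core import growth_regime

__all__ = [
    "GrowthSeries",
    "LogisticFit",
    "CapacityBounds",
    "default_capacity_bounds",
    "normalize_time",
    "fit_logistic",
    "cohort_summary",
    "read_growth_csv",
    "fits_to_frame",
]

DEFAULT_R_STARTS = (0.5, 1.0, 3.0, 10.0, 30.0)

#: Default carrying-capacity windows by measurement kind.
VOLUME_CAPACITY = (1500.0, 5000.0)  # mm^3, ethics-permit window
COUNT_CAPACITY = (1.5e8, 2.0e8)  # cells, high-yield flask ceiling


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate's measurements: strictly increasing times and
    non-negative values (volume in mm^3 or cell count)."""

    series_id: str
    group: str
    times: np.ndarray
    values: np.ndarray
    value_kind: str = "volume"  # "volume" | "count"
    raw_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.series_id}: times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError(f"{self.series_id}: values must be >= 0")
        if self.value_kind not in ("volume", "count"):
            raise ValueError(
                f"value_kind must be 'volume' or 'count', got {self.value_kind!r}"
            )

    @property
    def is_normalized(self) -> bool:
        return (
            self.times.size >= 2
            and self.times[0] == 0.0
            and self.times[-1] == 1.0
        )


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters on normalized time plus fit quality.

    ``is_logistic`` requires a converged fit with r2 >= threshold; ``regime``
    labels the fitted rate relative to the first map bifurcation (r = 3)."""

    series_id: str
    group: str
    r_hat: float
    c_hat: float
    n0_hat: float
    r2: float
    converged: bool
    is_logistic: bool

    @property
    def regime(self) -> str:
        return growth_regime(self.r_hat)


@dataclass(frozen=True)
class CapacityBounds:
    lower: float
    upper: float

    def widened_for(self, observed_max: float) -> "CapacityBounds":
        """Double the window (keeping the ratio) while the observed maximum
        exceeds the upper bound."""
        lo, hi = self.lower, self.upper
        while observed_max > hi:
            lo, hi = lo * 2, hi * 2
        return CapacityBounds(lo, hi)


def default_capacity_bounds(series: GrowthSeries) -> CapacityBounds:
    base = VOLUME_CAPACITY if series.value_kind == "volume" else COUNT_CAPACITY
    return CapacityBounds(*base).widened_for(float(series.values.max(initial=0.0)))


def normalize_time(series: GrowthSeries) -> GrowthSeries:
    """Affine map of measurement times onto [0, 1]; idempotent; the original
    times are retained in ``raw_times``."""
    if series.times.size < 2:
        raise ValueError("need at least 2 time points to normalize")
    t0, t1 = series.times[0], series.times[-1]
    if t1 == t0:
        raise ValueError("duplicate endpoints: cannot normalize time")
    if series.is_normalized:
        return series
    mapped = (series.times - t0) / (t1 - t0)
    return _dc_replace(
        series,
        times=mapped,
        raw_times=series.raw_times if series.raw_times is not None else series.times,
    )


def _logistic(t, n0, c, r):
    return c * n0 / (n0 + (c - n0) * np.exp(-r * t))


def fit_logistic(
    series: GrowthSeries,
    bounds: CapacityBounds | None = None,
    r2_threshold: float = 0.9,
    r_starts: tuple[float, ...] = DEFAULT_R_STARTS,
    r_max: float = 100.0,
) -> LogisticFit:
    """Bounded nonlinear least squares of the logistic solution in
    (N0, C, r) on a normalized series.

    Multi-started over ``r_starts``; the winner has the smallest residual sum
    of squares, ties toward the smaller rate.  Non-convergence from every
    start yields ``converged=False`` (never an exception).
    """
    if not series.is_normalized:
        raise ValueError(
            "series must be time-normalized before fitting; see normalize_time"
        )
    t, y = series.times, series.values
    if t.size < 4:
        raise ValueError(f"{series.series_id}: need >= 4 points to fit, got {t.size}")
    if bounds is None:
        bounds = default_capacity_bounds(series)
    else:
        bounds = bounds.widened_for(float(y.max(initial=0.0)))

    y0 = max(float(y[0]), 1e-9)
    lo = (1e-9, bounds.lower, 0.0)
    hi = (bounds.upper, bounds.upper, r_max)

    best = None  # (ssr, r_hat, popt)
    for r0 in r_starts:
        p0 = (
            min(max(y0, lo[0]), hi[0]),
            min(max(float(y.max()), bounds.lower), bounds.upper),
            min(r0, r_max),
        )
        try:
            popt, _ = curve_fit(_logistic, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((_logistic(t, *popt) - y) ** 2))
        if (
            best is None
            or ssr < best[0] - 1e-12
            or (abs(ssr - best[0]) <= 1e-12 and popt[2] < best[1])
        ):
            best = (ssr, popt[2], popt)

    if best is None:
        return LogisticFit(
            series.series_id, series.group,
            math.nan, math.nan, math.nan, 0.0, False, False,
        )
    ssr, _, (n0_hat, c_hat, r_hat) = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    return LogisticFit(
        series_id=series.series_id,
        group=series.group,
        r_hat=float(r_hat),
        c_hat=float(c_hat),
        n0_hat=float(min(n0_hat, c_hat)),
        r2=float(r2),
        converged=True,
        is_logistic=bool(r2 >= r2_threshold),
    )


def cohort_summary(fits: list[LogisticFit]) -> pd.DataFrame:
    """Per-cohort statistics of a list of fits.

    Columns: n, n_logistic, fraction_logistic, fraction_gt3 (share of
    logistic fits with rate above 3), median_r_logistic, median_r_all
    (converged fits), var_r_logistic (within-cohort variance of the rate
    among logistic fits).  Statistics over empty sets are NaN.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    df = pd.DataFrame(
        {
            "group": [f.group for f in fits],
            "r_hat": [f.r_hat for f in fits],
            "converged": [f.converged for f in fits],
            "is_logistic": [f.is_logistic for f in fits],
        }
    )
    for group, sub in df.groupby("group", sort=True):
        log = sub[sub.is_logistic]
        conv = sub[sub.converged]
        r_log = log.r_hat.to_numpy()
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "n_logistic": len(log),
                "fraction_logistic": len(log) / len(sub),
                "fraction_gt3": float(np.mean(r_log > 3.0)) if len(log) else math.nan,
                "median_r_logistic": float(np.median(r_log)) if len(log) else math.nan,
                "median_r_all": float(conv.r_hat.median()) if len(conv) else math.nan,
                "var_r_logistic": float(np.var(r_log, ddof=1))
                if len(r_log) > 1
                else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def read_growth_csv(path) -> list[GrowthSeries]:
    """Read a growth CSV (columns series_id, group, time, value, value_kind)
    into one GrowthSeries per series_id."""
    df = pd.read_csv(path)
    required = {"series_id", "group", "time", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV missing column(s) {sorted(missing)}")
    out = []
    for sid, sub in df.groupby("series_id", sort=True):
        sub = sub.sort_values("time")
        kind = (
            str(sub["value_kind"].iloc[0]) if "value_kind" in sub.columns else "volume"
        )
        out.append(
            GrowthSeries(
                series_id=str(sid),
                group=str(sub["group"].iloc[0]),
                times=sub["time"].to_numpy(dtype=float),
                values=sub["value"].to_numpy(dtype=float),
                value_kind=kind,
            )
        )
    return out


def fits_to_frame(fits: list[LogisticFit]) -> pd.DataFrame:
    """One row per fitted series, including the regime label."""
    return pd.DataFrame(
        {
            "series_id": [f.series_id for f in fits],
            "group": [f.group for f in fits],
            "r_hat": [f.r_hat for f in fits],
            "c_hat": [f.c_hat for f in fits],
            "n0_hat": [f.n0_hat for f in fits],
            "r2": [f.r2 for f in fits],
            "converged": [f.converged for f in fits],
            "is_logistic": [f.is_logistic for f in fits],
            "regime": [f.regime for f in fits],
        }
    )
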