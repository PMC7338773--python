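"""Litter-specific environmental covariates from raw weather records.

Each farrowing record is mapped to 19 week-long intervals tiling the sow's
reproductive cycle from three weeks before conception through farrowing
(day -21 up to day +112 relative to conception, half-open 7-day windows).
Within each interval, five climate variables are averaged — daily mean
temperature, relative humidity, maximum and minimum temperature, and the
temperature-humidity index (THI) — giving 19 x 5 = 95 candidate
environmental covariates per record.

Covariates are standardized to [-1, 1] between their observed (or
user-supplied) minimum and maximum, and each record is assigned to one of
five residual-variance classes using the first four quintiles of the
chosen covariate as discriminants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The five climate variables, in column order.
VARIABLES = ("MeanT", "RH", "MaxT", "MinT", "THI")

N_INTERVALS = 19
INTERVAL_DAYS = 7
CYCLE_START = -21  # days relative to conception
GESTATION_DAYS = 114


@dataclass(frozen=True)
class IntervalSpec:
    """One weekly interval of the reproductive cycle.

    ``start_day``/``end_day`` are day offsets relative to the conception
    date, half-open ``[start_day, end_day)``.  Interval 1 starts 21 days
    before conception; interval 19 ends at day 112 (farrowing minus the
    final two gestation days falls inside it: 114 = 21 + 133 days total,
    of which the last tiled day is 111).
    """

    index: int
    start_day: int
    end_day: int


def interval_specs() -> list[IntervalSpec]:
    """The 19 half-open weekly intervals tiling [-21, 112)."""
    return [
        IntervalSpec(i + 1, CYCLE_START + 7 * i, CYCLE_START + 7 * (i + 1))
        for i in range(N_INTERVALS)
    ]


def covariate_name(variable: str, interval: int) -> str:
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; choose from {VARIABLES}")
    if not 1 <= interval <= N_INTERVALS:
        raise ValueError(f"interval must be 1..{N_INTERVALS}")
    return f"{variable}_i{interval:02d}"


def compute_thi(t_mean, rh):
    """Temperature-humidity index (NRC 1971 dry-bulb/relative-humidity form).

    .. math::

        THI = T_F - (0.55 - 0.0055\\,RH)\\,(T_F - 58),
        \\qquad T_F = 1.8\\,T_C + 32

    At ``RH = 100`` the index equals the Fahrenheit temperature exactly,
    and at ``T_F = 58`` (about 14.4 C) the humidity correction vanishes.

    Parameters
    ----------
    t_mean : float or array_like
        Dry-bulb temperature in degrees Celsius.
    rh : float or array_like
        Relative humidity in percent, within [0, 100].
    """
    t_mean = np.asarray(t_mean, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100]")
    t_f = 1.8 * t_mean + 32.0
    thi = t_f - (0.55 - 0.0055 * rh) * (t_f - 58.0)
    if thi.ndim == 0:
        return float(thi)
    return thi


@dataclass
class EnvCovariateTable:
    """The 95-column covariate table keyed by (sow, parity).

    Attributes
    ----------
    data : DataFrame
        One row per phenotype record, ``sow``/``parity`` key columns plus
        one column per (variable, interval) combination.
    """

    data: pd.DataFrame

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("sow", "parity")]

    def column(self, variable: str, interval: int) -> pd.Series:
        return self.data[covariate_name(variable, interval)]


def _daily_frame(weather: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "t_mean", "t_min", "t_max", "rh"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.sort_values("date").reset_index(drop=True)
    return w


def build_interval_covariates(
    weather: pd.DataFrame,
    records: pd.DataFrame,
    variables=VARIABLES,
    intervals: list[IntervalSpec] | None = None,
) -> EnvCovariateTable:
    """Average each climate variable over each weekly interval per record.

    Parameters
    ----------
    weather : DataFrame
        Daily series with columns ``date, t_mean, t_min, t_max, rh``.
        Dates must be contiguous and cover every record's window from 21
        days before conception through farrowing.
    records : DataFrame
        Phenotype records with at least ``sow, parity, conception`` columns.

    Raises
    ------
    ValueError
        If any record's window falls outside the weather series (missing
        days are reported explicitly, never imputed).
    """
    if intervals is None:
        intervals = interval_specs()
    w = _daily_frame(weather)
    dates = w["date"].to_numpy()
    day_gaps = np.diff(dates) != np.timedelta64(1, "D")
    if day_gaps.any():
        gap_at = pd.to_datetime(dates[:-1][day_gaps])
        raise ValueError(f"weather series has gaps after: {list(gap_at[:5])}")

    daily = {
        "MeanT": w["t_mean"].to_numpy(float),
        "RH": w["rh"].to_numpy(float),
        "MaxT": w["t_max"].to_numpy(float),
        "MinT": w["t_min"].to_numpy(float),
        "THI": compute_thi(w["t_mean"].to_numpy(float), w["rh"].to_numpy(float)),
    }

    start = dates[0]
    conception = pd.to_datetime(records["conception"]).to_numpy()
    day0 = ((conception - start) / np.timedelta64(1, "D")).astype(int)

    lo = day0 + CYCLE_START
    hi = day0 + intervals[-1].end_day
    out_of_range = (lo < 0) | (hi > len(dates))
    if out_of_range.any():
        bad = records.loc[out_of_range, ["sow", "parity"]].head(5)
        raise ValueError(
            "weather series does not cover the reproductive window of "
            f"{int(out_of_range.sum())} record(s); first offenders:\n{bad}"
        )

    cols: dict[str, np.ndarray] = {
        "sow": records["sow"].to_numpy(),
        "parity": records["parity"].to_numpy(),
    }
    for var in variables:
        series = daily[var]
        csum = np.concatenate([[0.0], np.cumsum(series)])
        for spec in intervals:
            a = day0 + spec.start_day
            b = day0 + spec.end_day
            cols[covariate_name(var, spec.index)] = (csum[b] - csum[a]) / (b - a)
    return EnvCovariateTable(pd.DataFrame(cols))


def standardize_env(values, vmin: float | None = None, vmax: float | None = None):
    """Affine map of a covariate column onto [-1, 1].

    ``x = 2 (v - min) / (max - min) - 1``; the reported midpoint
    ``(min + max) / 2`` is the raw value that maps to 0 (the environment
    at which the model intercept is expressed).

    Returns
    -------
    (x, stats)
        ``x`` standardized values, ``stats`` a dict with keys
        ``min, max, midpoint``.
    """
    v = np.asarray(values, dtype=float)
    lo = float(np.min(v)) if vmin is None else float(vmin)
    hi = float(np.max(v)) if vmax is None else float(vmax)
    if not hi > lo:
        raise ValueError(f"degenerate covariate: min {lo} >= max {hi}")
    x = 2.0 * (v - lo) / (hi - lo) - 1.0
    return x, {"min": lo, "max": hi, "midpoint": 0.5 * (lo + hi)}


def quintile_boundaries(x) -> np.ndarray:
    """The first four quintiles (20/40/60/80th percentiles, linear interpolation)."""
    x = np.asarray(x, dtype=float)
    return np.percentile(x, [20, 40, 60, 80])


def assign_residual_class(x, boundaries=None) -> np.ndarray:
    """Allocate records to 5 residual classes by covariate quintile.

    Class boundaries are the first four quintiles of the covariate so
    class sizes are balanced up to ties; a value equal to a boundary goes
    to the lower class.  Returns integer classes 1..5.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 records to form quintile classes")
    if boundaries is None:
        boundaries = quintile_boundaries(x)
    boundaries = np.asarray(boundaries, dtype=float)
    return np.searchsorted(boundaries, x, side="left") + 1


def edit_phenotypes(records: pd.DataFrame, traits=("tnb", "nba", "abw"), k_sd: float = 3.5):
    """Drop records deviating more than ``k_sd`` SD from the trait mean.

    A single-pass edit per trait with a strict inequality at the boundary
    (a record sitting exactly at 3.5 SD is retained).  A record is removed
    if it is an outlier for any of the listed traits.

    Returns
    -------
    (filtered, report)
        The filtered DataFrame and a per-trait dict of removal counts.
    """
    traits = [t for t in traits if t in records.columns]
    if not traits:
        raise ValueError("no trait columns present to edit")
    drop = np.zeros(len(records), dtype=bool)
    report: dict[str, int] = {}
    for trait in traits:
        y = records[trait].to_numpy(float)
        if len(y) < 2:
            raise ValueError(f"need at least 2 records to edit trait {trait!r}")
        sd = float(np.std(y, ddof=1))
        if sd == 0.0:
            report[trait] = 0
            continue
        mask = np.abs(y - float(np.mean(y))) > k_sd * sd
        report[trait] = int(mask.sum())
        drop |= mask
    if drop.all():
        warnings.warn("phenotype edit removed every record", stacklevel=2)
    return records.loc[~drop].reset_index(drop=True), report
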