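"""Descriptors of incubation curves.

Cumulative-product time series from batch incubations (methane, acetate,
Fe(II); mmol/L vs days) are summarized by three descriptors: the maximum
cumulative concentration, the production rate over a stated window, and the
lag time. Replicates are kept separate for rate estimation and aggregated as
mean +/- sample SD.

Lag is operationalized as the tangent-intercept of the maximum-slope line
with the baseline (the definition implicit in the modified-Gompertz
parameterization, standard in anaerobic biodegradability work); the method
tag is recorded in the output so alternative definitions can be added
without breaking results.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeseriesError",
    "COLUMNS",
    "IncubationSeries",
    "RateEstimate",
    "LagEstimate",
    "max_cumulative",
    "window_rate",
    "lag_time",
    "replicate_stats",
    "format_stats",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "series_from_frame",
]

#: canonical tidy layout of incubation data
COLUMNS = ("treatment", "analyte", "replicate", "day", "conc_mmol_L")


class TimeseriesError(ValueError):
    """Invalid incubation series or descriptor request."""


@dataclass
class IncubationSeries:
    """Replicate time series of one analyte in one treatment.

    ``data`` holds columns replicate, day, conc_mmol_L; times must be
    strictly increasing within each replicate and concentrations >= 0
    (negative readings are clamped at load time and counted in
    ``n_clamped``).
    """

    treatment: str
    analyte: str
    data: pd.DataFrame
    n_clamped: int = 0

    def __post_init__(self) -> None:
        need = {"replicate", "day", "conc_mmol_L"}
        if not need.issubset(self.data.columns):
            raise TimeseriesError(f"series frame needs columns {sorted(need)}")
        if self.data.empty:
            raise TimeseriesError(
                f"empty series for {self.treatment}/{self.analyte}"
            )
        df = self.data.sort_values(["replicate", "day"]).reset_index(drop=True)
        for rep, grp in df.groupby("replicate"):
            days = grp["day"].to_numpy(float)
            if np.any(np.diff(days) <= 0):
                raise TimeseriesError(
                    f"times not strictly increasing in replicate {rep!r} of "
                    f"{self.treatment}/{self.analyte}"
                )
        neg = df["conc_mmol_L"] < 0
        if neg.any():
            df.loc[neg, "conc_mmol_L"] = 0.0
            self.n_clamped += int(neg.sum())
        self.data = df

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    def replicate_mean(self) -> pd.DataFrame:
        """Per-day mean across replicates, columns day, conc_mmol_L."""
        return (
            self.data.groupby("day", as_index=False)["conc_mmol_L"]
            .mean()
            .sort_values("day")
            .reset_index(drop=True)
        )


@dataclass(frozen=True)
class RateEstimate:
    """Least-squares production rate over a time window (mmol/L/d)."""

    window: tuple[float, float]
    per_replicate: dict
    mean: float
    sd: float | None

    @property
    def slope(self) -> float:
        return self.mean


@dataclass(frozen=True)
class LagEstimate:
    """Tangent-intercept lag of a cumulative production curve (days)."""

    lag_days: float | None
    defined: bool
    method: str
    max_rate: float | None = None
    asymptote: float | None = None


def max_cumulative(series: IncubationSeries) -> float:
    """Maximum over time of the replicate-mean concentration (mmol/L)."""
    return float(series.replicate_mean()["conc_mmol_L"].max())


def window_rate(
    series: IncubationSeries, start_day: float, end_day: float
) -> RateEstimate:
    """Per-replicate least-squares slope over [start_day, end_day].

    Each replicate needs at least two samples inside the window; replicate
    slopes are aggregated as mean +/- sample SD (SD omitted for a single
    replicate).
    """
    if end_day <= start_day:
        raise TimeseriesError("window end must exceed window start")
    slopes: dict = {}
    for rep, grp in series.data.groupby("replicate"):
        sub = grp[(grp["day"] >= start_day) & (grp["day"] <= end_day)]
        if len(sub) < 2:
            raise TimeseriesError(
                f"replicate {rep!r} has fewer than 2 samples in window "
                f"[{start_day}, {end_day}]"
            )
        slope = np.polyfit(
            sub["day"].to_numpy(float), sub["conc_mmol_L"].to_numpy(float), 1
        )[0]
        slopes[rep] = float(slope)
    mean, sd = replicate_stats(list(slopes.values()))
    return RateEstimate(
        window=(float(start_day), float(end_day)),
        per_replicate=slopes,
        mean=mean,
        sd=sd,
    )


def _window_slopes(
    days: np.ndarray, conc: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding least-squares slopes; returns (slopes, centers, center values).

    ``center values`` are the fitted values at the window-center time, which
    smooths the tangent anchor against single-sample noise.
    """
    n = len(days)
    width = max(2, min(width, n))
    slopes = np.empty(n - width + 1)
    centers = np.empty(n - width + 1)
    values = np.empty(n - width + 1)
    for i in range(n - width + 1):
        t = days[i : i + width]
        y = conc[i : i + width]
        b, a = np.polyfit(t, y, 1)
        tc = t.mean()
        slopes[i] = b
        centers[i] = tc
        values[i] = a + b * tc
    return slopes, centers, values


def lag_time(
    series: IncubationSeries,
    window: int = 5,
    noise_floor: float = 0.5,
) -> LagEstimate:
    """Tangent-intercept lag of the replicate-mean curve.

    The maximum slope over sliding ``window``-sample least-squares fits is
    taken as the maximum production rate; the lag is where its tangent
    crosses the baseline (initial value). Curves that never rise above
    baseline + ``noise_floor`` get an undefined-lag flag instead of a
    number. The result is clamped to the observed time range.
    """
    mean = series.replicate_mean()
    days = mean["day"].to_numpy(float)
    conc = mean["conc_mmol_L"].to_numpy(float)
    if len(days) < 2:
        raise TimeseriesError("need at least 2 time points for a lag estimate")
    baseline = float(conc[0])
    peak = float(conc.max())
    if peak <= baseline + noise_floor:
        return LagEstimate(
            lag_days=None,
            defined=False,
            method="tangent-intercept",
            asymptote=peak,
        )
    slopes, centers, values = _window_slopes(days, conc, window)
    k = int(np.argmax(slopes))
    smax = float(slopes[k])
    if smax <= 0:
        return LagEstimate(
            lag_days=None,
            defined=False,
            method="tangent-intercept",
            asymptote=peak,
        )
    lag = centers[k] - (values[k] - baseline) / smax
    lag = float(min(max(lag, 0.0), days[-1]))
    return LagEstimate(
        lag_days=lag,
        defined=True,
        method="tangent-intercept",
        max_rate=smax,
        asymptote=peak,
    )


def replicate_stats(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample SD (ddof=1); SD is None for n = 1."""
    if len(values) == 0:
        raise TimeseriesError("no values")
    arr = np.asarray(values, float)
    mean = float(arr.mean())
    if len(arr) == 1:
        return mean, None
    return mean, float(arr.std(ddof=1))


def format_stats(values: Sequence[float], ndigits: int = 1) -> str:
    """Render replicate values as the conventional ``m +/- s`` string."""
    mean, sd = replicate_stats(values)
    if sd is None:
        return f"{mean:.{ndigits}f}"
    return f"{mean:.{ndigits}f} ± {sd:.{ndigits}f}"


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_timeseries_tsv(path) -> pd.DataFrame:
    """Read a tidy incubation TSV and validate its layout.

    Columns: treatment, analyte, replicate, day, conc_mmol_L. Monotone-time
    and non-negativity checks happen when a series is extracted.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise TimeseriesError(f"timeseries TSV missing columns {sorted(missing)}")
    return df


def write_timeseries_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def series_from_frame(
    df: pd.DataFrame, treatment: str, analyte: str
) -> IncubationSeries:
    """Extract one treatment x analyte series from a tidy frame."""
    sub = df[(df["treatment"] == treatment) & (df["analyte"] == analyte)]
    if sub.empty:
        raise TimeseriesError(
            f"no rows for treatment {treatment!r}, analyte {analyte!r}"
        )
    return IncubationSeries(
        treatment=treatment,
        analyte=analyte,
        data=sub[["replicate", "day", "conc_mmol_L"]].copy(),
    )
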