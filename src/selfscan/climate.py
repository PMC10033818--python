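"""Climate-anomaly analysis (standardised Lamb index against a reference
period, growth-season aggregation, period contrasts) and the temporal
days-to-heading contrast."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Crop growth season: June through October.
GROWTH_SEASON = (6, 7, 8, 9, 10)

#: WMO-recommended climatological normal.
REFERENCE_PERIOD = (1961, 1990)


@dataclass
class ClimateSeries:
    """Monthly values of one climate variable at one station.

    ``values`` is a year-indexed DataFrame with columns 1..12 (mm for rain,
    degrees C for temperatures); NaN marks a missing month.
    """

    station: str
    variable: str  # rain | tmin | tmax
    values: pd.DataFrame

    def __post_init__(self):
        if list(self.values.columns) != list(range(1, 13)):
            raise ValueError("columns must be the months 1..12")

    @classmethod
    def from_table(cls, path, station: str = "", variable: str = "rain", sep: str = "\t"):
        """Read a delimited year x month table (first column = year, then 12
        monthly columns)."""
        df = pd.read_csv(path, sep=sep)
        df = df.set_index(df.columns[0])
        df.index.name = "year"
        df.columns = range(1, 13)
        return cls(station=station, variable=variable, values=df)


@dataclass
class AnomalySeries:
    """Standardised anomalies I = (X_i - Xbar) / sigma relative to a reference
    period; the reference years have mean 0 and (by the chosen sd convention)
    sd 1."""

    index: pd.Series  # anomalies by year
    ref_mean: float
    ref_sd: float
    ref_period: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.index.index, "anomaly": self.index.to_numpy()})


def season_aggregate(series: ClimateSeries, months=GROWTH_SEASON) -> pd.Series:
    """Per-year growth-season total (rain) or mean (temperature) over the given
    months. Years with any requested month missing are NaN."""
    months = list(months)
    missing_cols = [m for m in months if m not in series.values.columns]
    if missing_cols:
        raise ValueError(f"months {missing_cols} absent from the series")
    sub = series.values[months]
    out = sub.sum(axis=1) if series.variable == "rain" else sub.mean(axis=1)
    out[sub.isna().any(axis=1)] = np.nan
    out.name = f"{series.variable}_season"
    return out


def annual_aggregate(series: ClimateSeries) -> pd.Series:
    """Per-year total (rain) or mean of the 12 monthly values (temperature)."""
    sub = series.values
    out = sub.sum(axis=1) if series.variable == "rain" else sub.mean(axis=1)
    out[sub.isna().any(axis=1)] = np.nan
    out.name = f"{series.variable}_annual"
    return out


def lamb_index(
    yearly: pd.Series, ref_period=REFERENCE_PERIOD, ddof: int = 1
) -> AnomalySeries:
    """Standardised anomaly of a yearly series against the reference period.

    ``ddof=1`` (sample sd) is the default convention; set 0 for population sd.
    """
    ref = yearly.loc[(yearly.index >= ref_period[0]) & (yearly.index <= ref_period[1])].dropna()
    if len(ref) < 2:
        raise ValueError("need at least two reference years with data")
    mu = float(ref.mean())
    sd = float(ref.std(ddof=ddof))
    if sd == 0:
        raise ValueError("reference standard deviation is zero")
    return AnomalySeries(index=(yearly - mu) / sd, ref_mean=mu, ref_sd=sd, ref_period=tuple(ref_period))


def period_contrast(yearly: pd.Series, period_a, period_b) -> dict:
    """Difference of period means, mean(period_b) - mean(period_a).

    Periods are (start, end) year pairs, inclusive. Returns a dict with the
    difference and per-period means and year counts.
    """
    def mean_of(period):
        sel = yearly.loc[(yearly.index >= period[0]) & (yearly.index <= period[1])].dropna()
        if len(sel) == 0:
            raise ValueError(f"period {period} contains no data")
        return float(sel.mean()), len(sel)

    ma, na = mean_of(period_a)
    mb, nb = mean_of(period_b)
    return {"difference": mb - ma, "mean_a": ma, "mean_b": mb, "n_a": na, "n_b": nb}


def dthd_contrast(pheno: pd.DataFrame, group: str) -> dict:
    """Collect-wise days-to-heading contrast for one genetic group.

    Returns collect means, the advance (mean collect-1 minus mean collect-2;
    positive = earlier heading in the later collect), a Welch two-sample t
    p-value and per-collect Shapiro-Wilk normality flags (True = normality not
    rejected at 5%), reported as a caveat only.
    """
    sub = pheno[pheno["group"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    d1 = sub.loc[sub["collect"] == 1, "dthd"].to_numpy(dtype=float)
    d2 = sub.loc[sub["collect"] == 2, "dthd"].to_numpy(dtype=float)
    if len(d1) < 2 or len(d2) < 2:
        raise ValueError("need at least two records per collect")
    t, p = stats.ttest_ind(d1, d2, equal_var=False)
    return {
        "mean_1": float(d1.mean()),
        "mean_2": float(d2.mean()),
        "difference": float(d1.mean() - d2.mean()),
        "welch_t": float(t),
        "p_value": float(p),
        "n_1": len(d1),
        "n_2": len(d2),
        "normal_1": bool(stats.shapiro(d1).pvalue > 0.05),
        "normal_2": bool(stats.shapiro(d2).pvalue > 0.05),
    }


def plot_anomalies(anom: AnomalySeries, ax=None, title: str = ""):
    """Bar plot of standardised anomalies by year."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    years = anom.index.index.to_numpy()
    vals = anom.index.to_numpy()
    colors = np.where(vals >= 0, "tab:blue", "tab:red")
    ax.bar(years, vals, color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("standardised anomaly")
    if title:
        ax.set_title(title)
    return ax
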