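"""Monthly climate summaries and the soil-water-deficit drought model.

Works on per-plot monthly series (year, month, tmax, tmin, tmean, rain,
solar, vp, wind[, et]) and derives the quantities a plot-climate table
reports:

* long-term annual means, computed monthly → annual → long-term;
* day-night temperature range DTR = mean(tmax) − mean(tmin);
* vapour-pressure deficit VPD = mean(SVP(tmax), SVP(tmean)) − vp, using the
  FAO-56 saturation-vapour-pressure curve;
* the Malhi–Wright monthly soil-water-deficit bookkeeping: the monthly
  deficit SWD_t = max(0, ET_t − rain_t) and its running cumulation
  CSWD_t = max(0, CSWD_{t−1} + ET_t − rain_t), drawn down to zero by wet
  months and never negative.  ET defaults to the model's canonical fixed
  100 mm month⁻¹ unless a per-month ``et`` column is supplied;
* drought indices SWD_max and CSWD_max: per-calendar-month means across the
  years of the reference period, then the maximum over the twelve months;
* the two-criterion 'dry month' classification: a calendar month is dry iff
  (1) rain < ET in strictly more than half the years, and (2) its mean SWD
  exceeds 20 mm month⁻¹ (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ET_MM", "SWD_DRY_THRESHOLD_MM",
    "svp", "monthly_vpd", "dtr", "swd_series", "swd_summary", "dry_months",
    "climate_summary", "ClimateSummary",
]

#: Fixed monthly evapotranspiration (mm) when no per-month ET is given.
DEFAULT_ET_MM = 100.0

#: Mean-SWD threshold (mm month⁻¹) of the dry-month magnitude criterion.
SWD_DRY_THRESHOLD_MM = 20.0

MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def svp(t_celsius):
    """Saturation vapour pressure (kPa) at air temperature t (°C), FAO-56:
    0.6108·exp(17.27·t/(t+237.3))."""
    t = np.asarray(t_celsius, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if np.isscalar(t_celsius) else out


def monthly_vpd(tmax, tmean, vp):
    """Monthly VPD (kPa): mean of SVP at tmax and tmean, minus actual vapour
    pressure, floored at zero."""
    sat = (svp(tmax) + svp(tmean)) / 2.0
    out = np.maximum(np.asarray(sat) - np.asarray(vp, dtype=float), 0.0)
    return float(out) if np.isscalar(vp) else out


def dtr(tmax, tmin):
    """Day-night temperature range tmax − tmin (°C); inversion is an error."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    out = tmax - tmin
    return float(out) if out.ndim == 0 else out


def swd_series(rain, et=DEFAULT_ET_MM, *, signed_swd: bool = False,
               initial_cswd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Monthly soil water deficit and its running cumulation.

    ``rain`` and ``et`` are month-ordered series (et may be a scalar).
    Returns ``(swd, cswd)``: swd_t = max(0, et_t − rain_t) (or the signed
    balance et_t − rain_t with ``signed_swd=True``), and
    cswd_t = max(0, cswd_{t−1} + et_t − rain_t).  ``initial_cswd`` carries
    state across concatenated series.
    """
    rain = np.asarray(rain, dtype=float)
    et = np.broadcast_to(np.asarray(et, dtype=float), rain.shape)
    if rain.ndim != 1:
        raise ValueError("rain must be 1-d")
    if np.any(rain < 0) or np.any(et < 0):
        raise ValueError("rain and et must be non-negative")
    deficit = et - rain
    swd = deficit if signed_swd else np.maximum(deficit, 0.0)
    # max(0, ·) running recursion has no vectorised closed form; loop is O(n)
    cswd = np.empty_like(rain)
    c = float(initial_cswd)
    for t in range(rain.size):
        c = max(0.0, c + deficit[t])
        cswd[t] = c
    return swd, cswd


def _monthly_means(values: np.ndarray, months: np.ndarray) -> pd.Series:
    return pd.Series(values).groupby(pd.Series(months)).mean()


def swd_summary(swd, cswd, months) -> tuple[float, float]:
    """SWD_max and CSWD_max: per-calendar-month means across years, then the
    maximum over the twelve calendar months."""
    months = np.asarray(months)
    if months.size == 0:
        raise ValueError("empty period")
    return (
        float(_monthly_means(np.asarray(swd, dtype=float), months).max()),
        float(_monthly_means(np.asarray(cswd, dtype=float), months).max()),
    )


def dry_months(rain, et, swd, months,
               threshold_mm: float = SWD_DRY_THRESHOLD_MM) -> list[str]:
    """Calendar months satisfying both dry-month criteria.

    Criterion 1 (frequency): rain < et in strictly more than 50% of years.
    Criterion 2 (magnitude): mean SWD over the period strictly above
    ``threshold_mm``.  Returns month abbreviations in calendar order.
    """
    rain = np.asarray(rain, dtype=float)
    et = np.broadcast_to(np.asarray(et, dtype=float), rain.shape)
    swd = np.asarray(swd, dtype=float)
    months = np.asarray(months)
    deficit_years = _monthly_means((rain < et).astype(float), months)
    mean_swd = _monthly_means(swd, months)
    out = []
    for m in range(1, 13):
        if m in deficit_years.index and deficit_years[m] > 0.5 \
                and mean_swd[m] > threshold_mm:
            out.append(MONTH_NAMES[m - 1])
    return out


@dataclass(frozen=True)
class ClimateSummary:
    """Long-term climate of one plot (one row of a plot-climate table)."""

    plot_id: object
    tmean_c: float
    tmax_c: float
    tmin_c: float
    dtr_c: float
    rain_mm_y: float
    solar_mj_m2_d: float
    vp_kpa: float
    vpd_kpa: float
    wind_m_s: float
    swd_max_mm: float
    cswd_max_mm: float
    dry_months: tuple


def _validate_series(df: pd.DataFrame) -> pd.DataFrame:
    required = {"plot_id", "year", "month", "tmax", "tmin", "tmean",
                "rain", "solar", "vp", "wind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate series missing columns: {sorted(missing)}")
    if ((df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])).any():
        raise ValueError("need tmin ≤ tmean ≤ tmax in every month")
    if (df["rain"] < 0).any():
        raise ValueError("negative rainfall")
    return df.sort_values(["plot_id", "year", "month"])


def climate_summary(series: pd.DataFrame,
                    swd_period: tuple[int, int] | None = (1990, 2018),
                    *, signed_swd: bool = False) -> pd.DataFrame:
    """Long-term climate summary per plot from a monthly series table.

    Annual means are taken monthly → annual → long-term; rainfall is the
    long-term mean of annual totals.  The drought indices and dry-month
    classification are restricted to ``swd_period`` (inclusive year bounds;
    None uses all years).  A per-month ``et`` column overrides the fixed
    100 mm month⁻¹ evapotranspiration.
    """
    series = _validate_series(series)
    rows = []
    for plot_id, g in series.groupby("plot_id", sort=False):
        g = g.copy()
        g["dtr"] = dtr(g["tmax"].to_numpy(), g["tmin"].to_numpy())
        g["vpd"] = monthly_vpd(g["tmax"].to_numpy(), g["tmean"].to_numpy(),
                               g["vp"].to_numpy())
        annual = g.groupby("year").agg(
            tmean=("tmean", "mean"), tmax=("tmax", "mean"),
            tmin=("tmin", "mean"), dtr=("dtr", "mean"),
            rain=("rain", "sum"), solar=("solar", "mean"),
            vp=("vp", "mean"), vpd=("vpd", "mean"), wind=("wind", "mean"),
        )
        lt = annual.mean()

        sub = g
        if swd_period is not None:
            y0, y1 = swd_period
            sub = g[(g["year"] >= y0) & (g["year"] <= y1)]
            if sub.empty:
                raise ValueError(f"no data for plot {plot_id} in {swd_period}")
        et = sub["et"].to_numpy() if "et" in sub.columns else DEFAULT_ET_MM
        swd, cswd = swd_series(sub["rain"].to_numpy(), et,
                               signed_swd=signed_swd)
        months = sub["month"].to_numpy()
        swd_max, cswd_max = swd_summary(swd, cswd, months)
        dm = dry_months(sub["rain"].to_numpy(), et, swd, months)

        rows.append(ClimateSummary(
            plot_id=plot_id, tmean_c=lt["tmean"], tmax_c=lt["tmax"],
            tmin_c=lt["tmin"], dtr_c=lt["dtr"], rain_mm_y=lt["rain"],
            solar_mj_m2_d=lt["solar"], vp_kpa=lt["vp"], vpd_kpa=lt["vpd"],
            wind_m_s=lt["wind"], swd_max_mm=swd_max, cswd_max_mm=cswd_max,
            dry_months=tuple(dm),
        ))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("plot_id")
    return out
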