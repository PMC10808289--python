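"""Synthetic census, species-attribute and monthly-climate generators.

The generator emulates the statistical structure of a ten-plot tropical
rainforest gradient spanning roughly 100–2150 m asl:

* species richness per plot declines linearly with altitude;
* each species has an altitudinal optimum and only occurs within a window
  around it, so adjacent plots share species and distant plots do not
  (strong zonation — most species end up in three or fewer plots);
* abundances follow a log-series, the classical community abundance
  distribution, parameterised so roughly 40–50% of species muster ten or
  fewer individuals;
* the probability that a species is endemic declines linearly with its
  optimum altitude; a small exotic fraction occurs at low altitude only;
* the probability of an endangered-or-above Red-List category is a convex
  quadratic in altitude (high at both ends, minimal at low-mid altitude);
* DBH is lognormal, truncated at the 10 cm census threshold;
* monthly climate (1990–2018) has sinusoidal temperature seasonality, a
  linear lapse with altitude, a rainfall total declining with altitude with
  a pronounced February–March low (so high plots develop 'dry' months), and
  Gaussian noise.

Everything is drawn from a single ``numpy.random.default_rng(seed)``, so a
fixed seed gives byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "simulate_census", "simulate_climate"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic gradient.  Defaults describe a ten-plot,
    117–2132 m census with realistic richness, endemism and climate trends."""

    seed: int = 0
    altitudes_m: tuple = (117, 174, 509, 618, 1042, 1065, 1668, 1804, 2080, 2132)
    area_ha: float = 1.085          # nominal 1-ha plots, true surveyed area
    disturbance: tuple = ("high", "high", "low", "low", "medium",
                          "medium", "low", "medium", "low", "high")

    # richness model: E[S | altitude] = intercept + slope·alt (species/plot)
    richness_intercept: float = 130.0
    richness_slope: float = -0.045
    richness_sd: float = 6.0

    # regional pool and zonation; optima extend past the physical gradient so
    # the candidate pool does not thin out (and cap richness) at the ends
    n_pool_species: int = 700
    pool_altitude_range: tuple = (-400.0, 2600.0)
    niche_halfwidth_m: float = 350.0

    # log-series abundance shape (P(n) ∝ p^n / n); tuned so a ten-plot census
    # holds ~8000 stems with 40-50% of species at ≤ 10 individuals
    logseries_p: float = 0.96

    # endemism: P(endemic | optimum altitude) = intercept + slope·alt
    endemic_intercept: float = 0.70
    endemic_slope: float = -1.2e-4
    exotic_prob_lowland: float = 0.04   # below 400 m only

    # conservation status: P(GE_END | alt) = a + b·alt + c·alt² (convex)
    ge_end_quadratic: tuple = (0.20, -2.4e-4, 1.6e-7)
    vu_prob: float = 0.30

    # stem size: ln DBH ~ Normal(mu, sigma), truncated at 10 cm
    dbh_meanlog: float = 3.0
    dbh_sdlog: float = 0.5

    # climate
    years: tuple = (1990, 2018)
    tmean_sea_level_c: float = 27.2
    lapse_c_per_km: float = 5.8
    temp_seasonal_amp_c: float = 0.9
    dtr_intercept_c: float = 5.9
    dtr_slope_c_per_m: float = 5.0e-4
    rain_sea_level_mm_y: float = 3900.0
    rain_slope_mm_y_per_m: float = -0.9
    rain_month_fractions: tuple = (0.065, 0.030, 0.035, 0.09, 0.11, 0.10,
                                   0.09, 0.08, 0.10, 0.12, 0.10, 0.08)
    solar_sea_level: float = 19.0
    solar_slope_per_m: float = -7.0e-4
    wind_m_s: float = 2.0
    temp_noise_sd_c: float = 0.3
    rain_noise_frac: float = 0.20

    def __post_init__(self):
        if len(self.disturbance) != len(self.altitudes_m):
            raise ValueError("one disturbance level per plot required")
        if abs(sum(self.rain_month_fractions) - 1.0) > 1e-9:
            raise ValueError("rain_month_fractions must sum to 1")
        lo = self.richness_intercept + self.richness_slope * max(self.altitudes_m)
        if lo < 1:
            raise ValueError("richness model goes below 1 species at the top plot")

    @property
    def plot_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(len(self.altitudes_m))]


def _truncated_lognormal(rng, meanlog, sdlog, lower, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(meanlog, sdlog, size=2 * (size - filled))
        draw = draw[draw >= lower]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _species_pool(cfg: SynthConfig, rng) -> pd.DataFrame:
    """Regional pool: optimum altitude, endemism class and Red-List status."""
    lo, hi = cfg.pool_altitude_range
    opt = rng.uniform(lo, hi, size=cfg.n_pool_species)
    p_end = np.clip(cfg.endemic_intercept + cfg.endemic_slope * opt, 0.0, 1.0)
    p_exo = np.where(opt < 400.0, cfg.exotic_prob_lowland, 0.0)
    u = rng.uniform(size=cfg.n_pool_species)
    endemism = np.where(u < p_exo, "exotic",
                        np.where(u < p_exo + p_end, "endemic", "native"))

    a, b, c = cfg.ge_end_quadratic
    p_ge = np.clip(a + b * opt + c * opt ** 2, 0.0, 1.0)
    u2 = rng.uniform(size=cfg.n_pool_species)
    status = np.full(cfg.n_pool_species, "LC", dtype=object)
    ge_split = rng.uniform(size=cfg.n_pool_species)
    status[u2 < p_ge] = "EN"
    status[(u2 < p_ge) & (ge_split < 0.10)] = "CR"
    status[(u2 < p_ge) & (ge_split < 0.02)] = "CR_PE"
    vu_band = (u2 >= p_ge) & (u2 < p_ge + cfg.vu_prob)
    status[vu_band] = "VU"
    nt_band = (u2 >= p_ge + cfg.vu_prob) & (u2 < p_ge + cfg.vu_prob + 0.15)
    status[nt_band] = "NT"
    ne_band = u2 >= 0.97
    status[ne_band] = "NE"

    return pd.DataFrame({
        "species_id": [f"sp{i + 1:04d}" for i in range(cfg.n_pool_species)],
        "family": [f"fam{i % 60 + 1:02d}" for i in range(cfg.n_pool_species)],
        "genus": [f"gen{i % 140 + 1:03d}" for i in range(cfg.n_pool_species)],
        "optimum_alt_m": opt,
        "endemism": endemism,
        "status": status,
    })


def simulate_census(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (census, species, plots) tables for the configured gradient.

    The census has one row per stem (plot_id, species_id, dbh_cm); the
    species table carries family/genus/endemism/status for every pool species
    that occurs; the plot table carries altitude, area and disturbance.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _species_pool(cfg, rng)

    plot_rows = pd.DataFrame({
        "plot_id": cfg.plot_ids,
        "altitude_m": cfg.altitudes_m,
        "area_ha": cfg.area_ha,
        "disturbance": cfg.disturbance,
    })

    census_parts = []
    for pid, alt in zip(cfg.plot_ids, cfg.altitudes_m):
        mean_s = cfg.richness_intercept + cfg.richness_slope * alt
        s = max(1, int(round(rng.normal(mean_s, cfg.richness_sd))))
        window = np.abs(pool["optimum_alt_m"] - alt) <= cfg.niche_halfwidth_m
        candidates = pool.loc[window, "species_id"].to_numpy()
        if candidates.size == 0:
            raise ValueError(f"no pool species within the niche window at {alt} m")
        s = min(s, candidates.size)
        chosen = rng.choice(candidates, size=s, replace=False)
        counts = rng.logseries(cfg.logseries_p, size=s)
        for sp, n in zip(chosen, counts):
            dbh = _truncated_lognormal(rng, cfg.dbh_meanlog, cfg.dbh_sdlog,
                                       10.0, int(n))
            census_parts.append(pd.DataFrame({
                "plot_id": pid, "species_id": sp, "dbh_cm": np.round(dbh, 1),
            }))
    census = pd.concat(census_parts, ignore_index=True)

    present = census["species_id"].unique()
    species = (
        pool[pool["species_id"].isin(present)]
        .drop(columns="optimum_alt_m")
        .reset_index(drop=True)
    )
    return census, species, plot_rows


def simulate_climate(cfg: SynthConfig) -> pd.DataFrame:
    """Monthly climate series for every plot over the configured years.

    Columns: plot_id, year, month, tmax, tmin, tmean, rain, solar, vp, wind.
    tmin ≤ tmean ≤ tmax is guaranteed by construction (half-DTR offsets).
    """
    from .climate import svp

    rng = np.random.default_rng(cfg.seed + 1)
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    season = cfg.temp_seasonal_amp_c * np.sin(2 * np.pi * (months - 4) / 12.0)

    rows = []
    for pid, alt in zip(cfg.plot_ids, cfg.altitudes_m):
        t_base = cfg.tmean_sea_level_c - cfg.lapse_c_per_km * alt / 1000.0
        dtr_plot = cfg.dtr_intercept_c + cfg.dtr_slope_c_per_m * alt
        annual_rain = max(cfg.rain_sea_level_mm_y
                          + cfg.rain_slope_mm_y_per_m * alt, 100.0)
        rain_normals = annual_rain * np.asarray(cfg.rain_month_fractions)
        solar = max(cfg.solar_sea_level + cfg.solar_slope_per_m * alt, 1.0)
        for year in years:
            noise_t = rng.normal(0.0, cfg.temp_noise_sd_c, size=12)
            tmean = t_base + season + noise_t
            rain = np.maximum(
                rain_normals * (1.0 + rng.normal(0.0, cfg.rain_noise_frac,
                                                 size=12)),
                0.0,
            )
            tmax = tmean + dtr_plot / 2.0
            tmin = tmean - dtr_plot / 2.0
            vp = 0.75 * svp(tmean)  # ~75% relative humidity at tmean
            rows.append(pd.DataFrame({
                "plot_id": pid, "year": year, "month": months,
                "tmax": np.round(tmax, 2), "tmin": np.round(tmin, 2),
                "tmean": np.round(tmean, 2), "rain": np.round(rain, 1),
                "solar": np.round(solar, 3), "vp": np.round(vp, 3),
                "wind": cfg.wind_m_s,
            }))
    return pd.concat(rows, ignore_index=True)
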