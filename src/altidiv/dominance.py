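"""Species dominance: relative density, frequency, dominance and the
Importance Value Index (IVI).

For a group of plots (a single plot, an altitude class, or the whole
gradient):

* relative density   RDen_i = (area-normalised stem density of species i)
                              / (total density) × 100
* relative frequency RFreq_i = f_i / Σ_j f_j × 100, where f_i is the number
                              of plots of the group occupied by species i
* relative dominance RDom_i = basal area of species i / total basal area × 100
* IVI_i = RDen_i + RFreq_i + RDom_i

Each relative column sums to 100 and IVI to 300 within a group.  Note the
frequency component is normalised over all species' occupancies (so the
column sums to 100); the raw occupancy percentage f_i/n_plots × 100 is also
exposed since field studies quote both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census_io import AbundanceMatrix

__all__ = [
    "ALTITUDE_CLASS_EDGES", "altitude_classes",
    "relative_density", "relative_frequency", "relative_dominance",
    "ivi", "dominance_table",
]

#: Default altitude-class edges (m asl), half-open bins [low, high).
ALTITUDE_CLASS_EDGES = (0, 400, 800, 1200, 1800)

#: Labels for the default bins; the last is open-ended.
ALTITUDE_CLASS_LABELS = ("0-400", "400-800", "800-1200", "1200-1800", "above-1800")


def altitude_classes(
    plots: pd.DataFrame,
    edges=ALTITUDE_CLASS_EDGES,
    labels=ALTITUDE_CLASS_LABELS,
    overrides: dict | None = None,
) -> pd.Series:
    """Assign each plot to an altitude class.

    Half-open bins [low, high) from ``edges`` plus an open-ended top bin.
    ``overrides`` maps plot_id → label for explicit manual assignments (e.g.
    a ridge-top plot grouped with the class below its nominal altitude).
    """
    if len(labels) != len(edges):
        raise ValueError("need one label per bin (last bin is open-ended)")
    alt = plots["altitude_m"]
    idx = np.searchsorted(edges, alt.to_numpy(), side="right") - 1
    if np.any(idx < 0):
        raise ValueError("altitude below the lowest class edge")
    out = pd.Series([labels[i] for i in idx], index=alt.index, name="altitude_class")
    if overrides:
        for pid, lab in overrides.items():
            if lab not in labels:
                raise ValueError(f"override label {lab!r} not among {labels}")
            out.loc[pid] = lab
    return out


def relative_density(counts_by_species: pd.Series, densities=None) -> pd.Series:
    """Percent of total (area-normalised) stem density per species.

    ``counts_by_species`` may already be area-normalised densities; if raw
    counts are passed, pass the per-species density via ``densities`` instead.
    """
    d = counts_by_species if densities is None else densities
    total = d.sum()
    if total <= 0:
        raise ValueError("group holds no individuals")
    return d / total * 100.0


def relative_frequency(occupancy: pd.Series, n_plots: int) -> pd.DataFrame:
    """Normalised relative frequency plus raw plot-occupancy percent.

    Returns columns ``rfreq_pct`` (f_i/Σf_j × 100; the IVI component) and
    ``occupancy_pct`` (f_i/n_plots × 100).
    """
    if ((occupancy < 0) | (occupancy > n_plots)).any():
        raise ValueError("occupancy must lie in 0..n_plots")
    total = occupancy.sum()
    if total == 0:
        raise ValueError("no species occupies any plot")
    return pd.DataFrame(
        {
            "rfreq_pct": occupancy / total * 100.0,
            "occupancy_pct": occupancy / n_plots * 100.0,
        }
    )


def relative_dominance(basal_by_species: pd.Series) -> pd.Series:
    """Percent of total basal area per species."""
    if (basal_by_species < 0).any():
        raise ValueError("basal areas must be non-negative")
    total = basal_by_species.sum()
    if total <= 0:
        raise ValueError("zero total basal area")
    return basal_by_species / total * 100.0


def ivi(rden: pd.Series, rfreq: pd.Series, rdom: pd.Series) -> pd.Series:
    """Importance Value Index: row-wise sum of the three relative components."""
    return rden + rfreq + rdom


def _group_table(
    counts: pd.DataFrame,
    ba: pd.DataFrame,
    areas: pd.Series,
    density_mode: str,
) -> pd.DataFrame:
    present = counts.sum(axis=0) > 0
    counts = counts.loc[:, present]
    ba = ba.loc[:, present]

    if density_mode == "area":
        dens = counts.div(areas, axis=0).sum(axis=0)
    elif density_mode == "pooled":
        dens = counts.sum(axis=0).astype(float)
    else:
        raise ValueError("density_mode must be 'area' or 'pooled'")

    rden = relative_density(dens)
    rfreq = relative_frequency((counts > 0).sum(axis=0), n_plots=len(counts))
    rdom = relative_dominance(ba.sum(axis=0))
    out = pd.DataFrame(
        {
            "rden_pct": rden,
            "rfreq_pct": rfreq["rfreq_pct"],
            "occupancy_pct": rfreq["occupancy_pct"],
            "rdom_pct": rdom,
        }
    )
    out["ivi"] = ivi(out["rden_pct"], out["rfreq_pct"], out["rdom_pct"])
    return out.sort_values("ivi", ascending=False)


def dominance_table(
    matrix: AbundanceMatrix,
    group_by: str = "all",
    *,
    density_mode: str = "area",
    class_overrides: dict | None = None,
    class_edges=ALTITUDE_CLASS_EDGES,
    class_labels=ALTITUDE_CLASS_LABELS,
) -> pd.DataFrame:
    """Per-species dominance table within each group of plots.

    ``group_by`` is ``"all"`` (one community), ``"plot"`` (each plot its own
    group) or ``"altitude-class"`` (default bins, with explicit per-plot
    overrides).  Relative frequency always uses the plots of the group as its
    universe.  ``density_mode="area"`` divides counts by each plot's surveyed
    area before pooling (the default); ``"pooled"`` sums raw counts.
    Rows are sorted by descending IVI within each group.
    """
    plots = matrix.plots
    if group_by == "all":
        groups = pd.Series("all", index=matrix.counts.index)
    elif group_by == "plot":
        groups = pd.Series(matrix.counts.index, index=matrix.counts.index)
    elif group_by == "altitude-class":
        groups = altitude_classes(plots, class_edges, class_labels, class_overrides)
    else:
        raise ValueError("group_by must be 'all', 'plot' or 'altitude-class'")

    pieces = []
    for gid, plot_ids in groups.groupby(groups).groups.items():
        sub = _group_table(
            matrix.counts.loc[plot_ids],
            matrix.basal_area.loc[plot_ids],
            plots.loc[plot_ids, "area_ha"],
            density_mode,
        )
        sub.insert(0, "group", gid)
        pieces.append(sub)
    out = pd.concat(pieces)
    out.index.name = "species_id"
    return out
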