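"""Endemism and Red-List (conservation-status) summaries.

Red-List categories are consumed as input labels and pooled into the classes
conservation planning actually uses:

* ``GE_END`` ("endangered and above"): CR(PE), CR, EN — the most urgent tier;
* ``VU``: vulnerable;
* ``NT_LC``: near-threatened + least-concern, no present conservation need;
* ``OTHER``: everything else (DD, NE, EX, EW, unknown).

Percentages can be computed per species or per individual.  Unidentified
species are retained in abundance-based analyses but excluded from endemism
and conservation denominators; where it matters, summaries report both the
evaluated-species denominator (excluding NE/unknown as well) and the
identified-species denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census_io import AbundanceMatrix
from .dominance import (
    ALTITUDE_CLASS_EDGES,
    ALTITUDE_CLASS_LABELS,
    altitude_classes,
)

__all__ = [
    "pool_status", "endemism_percentages", "conservation_percentages",
    "occupancy_table", "altitude_range_table", "abundance_classes",
    "DEFAULT_OCCUPANCY_BINS", "DEFAULT_ABUNDANCE_BREAKS",
]

_POOL = {
    "CR_PE": "GE_END", "CR": "GE_END", "EN": "GE_END",
    "VU": "VU",
    "NT": "NT_LC", "LC": "NT_LC",
    "DD": "OTHER", "NE": "OTHER", "EX": "OTHER", "EW": "OTHER",
    "unknown": "OTHER",
}

POOLED_CLASSES = ("GE_END", "VU", "NT_LC", "OTHER")

#: Occupancy bins: (label, lowest plot count, highest plot count or None=open).
DEFAULT_OCCUPANCY_BINS = (
    ("one_plot", 1, 1),
    ("plots_2_3", 2, 3),
    ("plots_4_5", 4, 5),
    ("plots_6", 6, None),
)

#: Total-abundance class breaks: singletons, 2-10, 11-50, 51-200, >200.
DEFAULT_ABUNDANCE_BREAKS = (1, 10, 50, 200)


def pool_status(status: str) -> str:
    """Pool a Red-List category into {GE_END, VU, NT_LC, OTHER}."""
    try:
        return _POOL[status]
    except KeyError:
        raise ValueError(
            f"unknown Red-List category {status!r}; permitted: {sorted(_POOL)}"
        ) from None


def _presence(matrix: AbundanceMatrix) -> pd.DataFrame:
    return matrix.counts > 0


def _species_attr(matrix: AbundanceMatrix, attributes: pd.DataFrame, col: str) -> pd.Series:
    missing = [s for s in matrix.species_ids if s not in attributes.index]
    if missing:
        raise KeyError(f"species missing from attribute table: {missing[:5]}...")
    return attributes.loc[matrix.species_ids, col]


def endemism_percentages(
    matrix: AbundanceMatrix,
    attributes: pd.DataFrame,
    by: str = "species",
) -> pd.DataFrame:
    """Per-plot percentage of endemic / native / exotic species or individuals.

    The denominator is identified species (or their individuals) only;
    unidentified species never enter.  Percentages therefore sum to 100 per
    plot.  A plot with no identified species yields NaNs.
    """
    if by not in ("species", "individuals"):
        raise ValueError("by must be 'species' or 'individuals'")
    end = _species_attr(matrix, attributes, "endemism")
    identified = end != "unidentified"
    if by == "species":
        weights = _presence(matrix).astype(int)
    else:
        weights = matrix.counts
    weights = weights.loc[:, identified]
    end = end[identified]

    out = {}
    for cls in ("endemic", "native", "exotic"):
        out[cls] = weights.loc[:, (end == cls).to_numpy()].sum(axis=1)
    out = pd.DataFrame(out)
    denom = out.sum(axis=1)
    pct = out.div(denom, axis=0) * 100.0
    pct[denom == 0] = np.nan
    pct.columns = [f"{c}_pct_{by}" for c in pct.columns]
    return pct


def conservation_percentages(
    matrix: AbundanceMatrix,
    attributes: pd.DataFrame,
    by: str = "species",
    denominator: str = "evaluated",
) -> pd.DataFrame:
    """Per-plot counts and percentages of the pooled Red-List classes.

    ``denominator="evaluated"`` divides by species carrying one of the nine
    assessed categories (OTHER excluded); ``"identified"`` divides by all
    identified species.  Returns count columns ``n_<class>`` and percentage
    columns ``<class>_pct``.
    """
    if by not in ("species", "individuals"):
        raise ValueError("by must be 'species' or 'individuals'")
    if denominator not in ("evaluated", "identified"):
        raise ValueError("denominator must be 'evaluated' or 'identified'")
    end = _species_attr(matrix, attributes, "endemism")
    pooled = _species_attr(matrix, attributes, "status").map(pool_status)
    identified = (end != "unidentified").to_numpy()

    weights = _presence(matrix).astype(int) if by == "species" else matrix.counts
    counts = {
        cls: weights.loc[:, ((pooled == cls).to_numpy()) & identified].sum(axis=1)
        for cls in POOLED_CLASSES
    }
    counts = pd.DataFrame(counts)
    if denominator == "evaluated":
        denom = counts[["GE_END", "VU", "NT_LC"]].sum(axis=1)
        pct_classes = ("GE_END", "VU", "NT_LC")
    else:
        denom = counts.sum(axis=1)
        pct_classes = POOLED_CLASSES
    out = counts.rename(columns=lambda c: f"n_{c}")
    for cls in pct_classes:
        out[f"{cls}_pct"] = np.where(denom > 0, counts[cls] / denom * 100.0, np.nan)
    return out


def occupancy_table(
    matrix: AbundanceMatrix,
    attributes: pd.DataFrame,
    bins=DEFAULT_OCCUPANCY_BINS,
) -> pd.DataFrame:
    """Species counts by plot-occupancy bin, split by endemism class.

    Rows are the endemism classes plus an ``all`` total row; columns the
    occupancy bins plus ``total``.  Row percentages (of the row total) and the
    class share of all species are added as ``*_pct`` columns.  Bins must
    partition 1..n_plots.
    """
    n_plots = len(matrix.plot_ids)
    covered = []
    for label, lo, hi in bins:
        hi = n_plots if hi is None else hi
        if lo > hi:
            raise ValueError(f"bin {label} is empty")
        covered.extend(range(lo, hi + 1))
    if sorted(covered) != list(range(1, n_plots + 1)):
        raise ValueError("occupancy bins must partition 1..n_plots without overlap")

    occ = _presence(matrix).sum(axis=0)
    occ = occ[occ > 0]
    end = attributes.loc[occ.index, "endemism"]

    classes = ["all", "endemic", "native", "exotic", "unidentified"]
    rows = {}
    for cls in classes:
        sel = occ if cls == "all" else occ[(end == cls).to_numpy()]
        row = {}
        for label, lo, hi in bins:
            hi_eff = n_plots if hi is None else hi
            row[label] = int(((sel >= lo) & (sel <= hi_eff)).sum())
        row["total"] = int(len(sel))
        rows[cls] = row
    out = pd.DataFrame(rows).T
    out.index.name = "endemism_class"

    grand = out.loc["all", "total"]
    for label, _, _ in bins:
        out[f"{label}_pct"] = out[label] / out["total"].replace(0, np.nan) * 100.0
    out["total_pct"] = out["total"] / grand * 100.0
    return out


def altitude_range_table(
    matrix: AbundanceMatrix,
    attributes: pd.DataFrame,
    *,
    class_edges=ALTITUDE_CLASS_EDGES,
    class_labels=ALTITUDE_CLASS_LABELS,
    class_overrides: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Which altitude classes each species occupies, and how many.

    Returns ``(incidence, summary)``: ``incidence`` is species × class boolean
    occupancy with the occupied-class count and the endemism class appended;
    ``summary`` tabulates, per endemism class, how many species occupy
    k = 1..n classes (species in disjoint classes count the classes they
    actually occupy, not the span).
    """
    classes = altitude_classes(matrix.plots, class_edges, class_labels,
                               class_overrides)
    pres = _presence(matrix)
    incidence = pres.groupby(classes).any().T  # species × altitude class
    incidence = incidence.reindex(columns=[l for l in class_labels
                                           if l in incidence.columns])
    keep = incidence.any(axis=1)
    incidence = incidence.loc[keep]
    incidence["n_classes"] = incidence.sum(axis=1).astype(int)
    incidence["endemism"] = attributes.loc[incidence.index, "endemism"]

    summary = (
        incidence.groupby("endemism")["n_classes"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(1, len(class_labels) + 1), fill_value=0)
    )
    summary.loc["all"] = summary.sum(axis=0)
    summary.columns.name = "n_classes_occupied"
    return incidence, summary


def abundance_classes(
    matrix: AbundanceMatrix,
    attributes: pd.DataFrame,
    breaks=DEFAULT_ABUNDANCE_BREAKS,
) -> pd.DataFrame:
    """Species tallied by total abundance class × endemism class.

    ``breaks`` are ascending upper edges; classes are (≤b1), (b1, b2], ...,
    (>b_last).  With the defaults that is 1, 2-10, 11-50, 51-200, >200
    individuals summed across all plots.
    """
    breaks = tuple(breaks)
    if list(breaks) != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise ValueError("breaks must be strictly ascending")
    totals = matrix.counts.sum(axis=0)
    totals = totals[totals > 0]
    edges = [0, *breaks, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo1 = int(lo) + 1
        labels.append(f"{lo1}" if lo1 == hi else
                      (f">{int(lo)}" if np.isinf(hi) else f"{lo1}-{int(hi)}"))
    binned = pd.cut(totals, bins=edges, labels=labels)
    end = attributes.loc[totals.index, "endemism"]
    out = (
        pd.crosstab(end, binned)
        .reindex(columns=labels, fill_value=0)
    )
    out.loc["all"] = out.sum(axis=0)
    out["total"] = out.sum(axis=1)
    for lab in labels:
        out[f"{lab}_pct"] = out[lab] / out["total"].replace(0, np.nan) * 100.0
    out.index.name = "endemism_class"
    return out
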