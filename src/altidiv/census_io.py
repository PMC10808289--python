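"""Reading, validation and aggregation of tree-census tables.

A census is a stem-level table (one row per measured stem ≥ 10 cm DBH),
accompanied by a species-attribute table (family, genus, endemism class,
national Red-List category) and a plot-metadata table (altitude, surveyed
area, anthropogenic-disturbance class).  This module validates those tables,
applies the DBH ≥ 10 cm census filter, and pivots records into the
plot × species abundance and basal-area matrices every downstream analysis
operates on.

Each census row is treated as one individual; multi-stemmed trees are not
merged.  Per-area quantities always divide by the plot's surveyed ``area_ha``
(plots are nominally 1 ha but true areas may differ).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Census inclusion threshold: stems with DBH (at 1.3 m) below this are excluded.
MIN_DBH_CM = 10.0

#: Permitted anthropogenic-disturbance classes.
DISTURBANCE_LEVELS = ("low", "medium", "high")

#: Permitted endemism classes.
ENDEMISM_CLASSES = ("endemic", "native", "exotic", "unidentified")

#: National Red-List categories: the nine IUCN categories plus the
#: "Possibly Extinct" tag on CR, plus a catch-all for unassessed species.
STATUS_CATEGORIES = (
    "EX", "EW", "CR_PE", "CR", "EN", "VU", "NT", "LC", "DD", "NE", "unknown",
)

#: Sentinel species id given to stems whose species is not in the attribute table.
UNIDENTIFIED = "unidentified"

CENSUS_COLUMNS = ("plot_id", "species_id", "dbh_cm")
SPECIES_COLUMNS = ("species_id", "family", "genus", "endemism", "status")
PLOT_COLUMNS = ("plot_id", "altitude_m", "area_ha", "disturbance")

#: Darwin-Core-style header aliases accepted on input.
DEFAULT_ALIASES = {
    "scientificName": "species_id",
    "locationID": "plot_id",
    "diameter": "dbh_cm",
}


class SchemaError(ValueError):
    """A required column is missing or a categorical value is not permitted."""


@dataclass(frozen=True)
class CensusData:
    """Validated census: stem records plus species and plot metadata.

    ``records`` has columns plot_id, species_id, dbh_cm (and tag when given);
    ``species`` is indexed by species_id; ``plots`` by plot_id.
    ``n_excluded`` counts stems rejected by the DBH filter.
    """

    records: pd.DataFrame
    species: pd.DataFrame
    plots: pd.DataFrame
    n_excluded: int = 0


@dataclass(frozen=True)
class AbundanceMatrix:
    """Plot × species counts and basal areas (m²), aligned row/column-wise."""

    counts: pd.DataFrame
    basal_area: pd.DataFrame
    plots: pd.DataFrame = field(repr=False, default=None)

    @property
    def plot_ids(self) -> list:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_stems(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_basal_area_m2(self) -> float:
        return float(self.basal_area.to_numpy().sum())


def basal_area(dbh_cm) -> float | np.ndarray:
    """Cross-sectional stem area at breast height, in m², from DBH in cm.

    ``π·(dbh/200)²`` — the standard forestry conversion (dbh/2 cm radius,
    divided by 100 to metres).
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("DBH must be positive")
    out = np.pi * (dbh / 200.0) ** 2
    return float(out) if np.isscalar(dbh_cm) else out


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def _apply_aliases(df: pd.DataFrame, aliases: dict | None) -> pd.DataFrame:
    mapping = dict(DEFAULT_ALIASES)
    if aliases:
        mapping.update(aliases)
    return df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})


def read_census(
    census: pd.DataFrame | str,
    species: pd.DataFrame | str,
    plots: pd.DataFrame | str,
    *,
    min_dbh_cm: float = MIN_DBH_CM,
    aliases: dict | None = None,
) -> CensusData:
    """Validate the three input tables and apply the census DBH filter.

    Accepts DataFrames or CSV paths.  Stems below ``min_dbh_cm`` are dropped
    (their count is logged and recorded on the result); non-positive DBH is an
    error; species ids absent from the attribute table are reattributed to the
    ``"unidentified"`` pseudo-species with a warning.
    """
    census = pd.read_csv(census) if isinstance(census, str) else census.copy()
    species = pd.read_csv(species) if isinstance(species, str) else species.copy()
    plots = pd.read_csv(plots) if isinstance(plots, str) else plots.copy()

    census = _apply_aliases(census, aliases)
    _require_columns(census, CENSUS_COLUMNS, "census")
    _require_columns(species, SPECIES_COLUMNS, "species")
    _require_columns(plots, PLOT_COLUMNS, "plot")

    census["dbh_cm"] = pd.to_numeric(census["dbh_cm"])
    if (census["dbh_cm"] <= 0).any():
        bad = census.loc[census["dbh_cm"] <= 0]
        raise ValueError(f"{len(bad)} census rows have non-positive DBH")

    keep = census["dbh_cm"] >= min_dbh_cm
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d stems with DBH < %g cm", n_excluded, min_dbh_cm)
    census = census.loc[keep].reset_index(drop=True)

    bad_dist = set(plots["disturbance"]) - set(DISTURBANCE_LEVELS)
    if bad_dist:
        raise SchemaError(
            f"unknown disturbance levels {sorted(bad_dist)}; "
            f"expected one of {DISTURBANCE_LEVELS}"
        )
    if (plots["area_ha"] <= 0).any():
        raise ValueError("plot areas must be positive")

    bad_end = set(species["endemism"]) - set(ENDEMISM_CLASSES)
    if bad_end:
        raise SchemaError(
            f"unknown endemism classes {sorted(bad_end)}; "
            f"expected one of {ENDEMISM_CLASSES}"
        )
    bad_status = set(species["status"]) - set(STATUS_CATEGORIES)
    if bad_status:
        raise SchemaError(
            f"unknown Red-List categories {sorted(bad_status)}; "
            f"expected one of {STATUS_CATEGORIES}"
        )

    species = species.set_index("species_id")
    unknown = ~census["species_id"].isin(species.index)
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} stems with species ids not in the attribute "
            f"table were attributed to '{UNIDENTIFIED}'",
            stacklevel=2,
        )
        census.loc[unknown, "species_id"] = UNIDENTIFIED
        if UNIDENTIFIED not in species.index:
            species.loc[UNIDENTIFIED] = {
                "family": UNIDENTIFIED,
                "genus": UNIDENTIFIED,
                "endemism": "unidentified",
                "status": "unknown",
            }

    plots = plots.set_index("plot_id")
    return CensusData(records=census, species=species, plots=plots,
                      n_excluded=n_excluded)


def build_matrix(data: CensusData) -> AbundanceMatrix:
    """Pivot stem records into plot × species count and basal-area matrices.

    Stem count and summed basal area are conserved exactly.  Every record's
    plot must appear in the plot-metadata table.
    """
    records = data.records
    orphans = set(records["plot_id"]) - set(data.plots.index)
    if orphans:
        raise ValueError(f"census rows reference unknown plots: {sorted(orphans)}")

    records = records.assign(ba_m2=basal_area(records["dbh_cm"].to_numpy()))
    counts = (
        records.pivot_table(index="plot_id", columns="species_id",
                            values="dbh_cm", aggfunc="size", fill_value=0)
        .reindex(index=data.plots.index, fill_value=0)
        .astype(int)
    )
    ba = (
        records.pivot_table(index="plot_id", columns="species_id",
                            values="ba_m2", aggfunc="sum", fill_value=0.0)
        .reindex(index=data.plots.index, fill_value=0.0)
        .reindex(columns=counts.columns, fill_value=0.0)
    )
    counts.columns.name = ba.columns.name = "species_id"
    return AbundanceMatrix(counts=counts, basal_area=ba, plots=data.plots)
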