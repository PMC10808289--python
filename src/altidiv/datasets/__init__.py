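"""Bundled reference tables from a published tree-census study of Sri Lankan
rainforest permanent sampling plots (PSPs) along a 117-2132 m altitudinal
gradient.

Three small CSVs are shipped with the package:

``psp_climate_summary``
    Long-term (1970-2018) climate of the ten PSPs: annual means of
    temperature, day-night temperature range (DTR), rainfall, solar
    irradiance, vapour pressure (deficit), wind, and the drought indices
    SWD_max / CSWD_max with the months classified as 'dry'.
``psp_dominant_species``
    The three most dominant species per altitude class with their relative
    density, relative frequency, relative basal area and Importance Value
    Index (IVI).
``psp_species_occupancy``
    Species counts by plot-occupancy class (1, 2-3, 4-5, 6 plots), split by
    endemism class.

These are used as arithmetic cross-checks (DTR = Tmax - Tmin, IVI additivity,
occupancy percentages), not as raw inputs to the pipeline — the underlying
stem-level census is not public.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_psp_climate_summary",
    "load_psp_dominant_species",
    "load_psp_species_occupancy",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_psp_climate_summary() -> pd.DataFrame:
    """Long-term climate summary, one row per PSP (ten plots)."""
    df = _read("psp_climate_summary.csv")
    df["dry_months"] = df["dry_months"].fillna("").map(
        lambda s: tuple(s.split(";")) if s else ()
    )
    return df


def load_psp_dominant_species() -> pd.DataFrame:
    """Dominant species per altitude class with IVI components."""
    return _read("psp_dominant_species.csv")


def load_psp_species_occupancy() -> pd.DataFrame:
    """Species occupancy distribution by endemism class."""
    return _read("psp_species_occupancy.csv").set_index("endemism_class")
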