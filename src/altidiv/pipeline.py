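"""End-to-end convenience layer: census tables → per-plot floristic metrics
and environment matrix, ready for trend regression and ordination."""

from __future__ import annotations

import pandas as pd

from .census_io import AbundanceMatrix, CensusData, build_matrix
from .conservation import conservation_percentages, endemism_percentages
from .diversity import diversity_table
from .ordination import encode_disturbance

__all__ = ["floristic_metrics", "environment_table"]


def floristic_metrics(matrix: AbundanceMatrix, attributes: pd.DataFrame) -> pd.DataFrame:
    """Per-plot floristic summary used as the ordination response.

    Columns: TBApha (total basal area, m² ha⁻¹), R (Menhinick richness),
    H (Shannon–Wiener), EH (Shannon evenness), endemic_pct_species and
    ge_end_pct_species (evaluated-species denominator).
    """
    div = diversity_table(matrix)
    tba = matrix.basal_area.sum(axis=1) / matrix.plots["area_ha"]
    end = endemism_percentages(matrix, attributes, by="species")
    cons = conservation_percentages(matrix, attributes, by="species")
    return pd.DataFrame({
        "TBApha": tba,
        "R": div["R"],
        "H": div["H"],
        "EH": div["EH"],
        "endemic_pct": end["endemic_pct_species"],
        "ge_end_pct": cons["GE_END_pct"],
    })


def environment_table(climate: pd.DataFrame, plots: pd.DataFrame,
                      variables=("tmax_c", "dtr_c", "rain_mm_y",
                                 "cswd_max_mm", "solar_mj_m2_d")) -> pd.DataFrame:
    """Constraint matrix: selected climate columns plus disturbance dummies
    (low level dropped), aligned on plot id."""
    env = climate.loc[plots.index, list(variables)].copy()
    dummies = encode_disturbance(plots["disturbance"])
    return pd.concat([env, dummies], axis=1)
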