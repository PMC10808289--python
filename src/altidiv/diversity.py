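"""Per-plot diversity, evenness and richness indices.

All indices operate on a vector of species abundances (individual counts)
within one plot:

* Shannon–Wiener ``H' = -Σ (n_i/N)·ln(n_i/N)`` in natural-log units (nats);
* Simpson's diversity in two forms — the finite-sample (unbiased)
  ``D = 1 - Σ n_i(n_i-1) / [N(N-1)]`` reported as the headline "D1", and the
  plug-in ``D = 1 - Σ p_i²``;
* Menhinick's richness ``R = S/√N``;
* Shannon evenness ``E_H = H'/ln S`` and Simpson evenness
  ``E_D = (1-SI)/(1-SI_even)`` where ``SI_even`` is the finite-sample
  Simpson concentration under the most even integer allocation of the
  observed N individuals among the observed S species.

Zero-count species never enter any sum.  Summation runs over counts sorted
descending for a stable accumulation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census_io import AbundanceMatrix

__all__ = [
    "shannon", "simpson", "menhinick", "evenness",
    "diversity_table", "DiversityResult",
]


@dataclass(frozen=True)
class DiversityResult:
    plot_id: object
    S: int
    N: int
    shannon_H: float
    simpson_D_unbiased: float
    simpson_D_pi2: float
    menhinick_R: float
    evenness_EH: float
    evenness_ED: float


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-d vector")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    # descending order: largest terms first for a stable accumulation
    return np.sort(c)[::-1]


def shannon(counts) -> float:
    """Shannon–Wiener index H' in nats; ln S for equal abundances."""
    c = _clean(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def _simpson_concentration(counts) -> float:
    """Finite-sample Simpson concentration SI = Σ n_i(n_i-1)/[N(N-1)]."""
    c = _clean(counts)
    n = c.sum()
    if n < 2:
        raise ValueError("unbiased Simpson needs at least 2 individuals")
    return float((c * (c - 1)).sum() / (n * (n - 1)))


def simpson(counts, form: str = "unbiased") -> float:
    """Simpson's diversity D = 1 - concentration.

    ``form="unbiased"`` uses the finite-sample concentration
    Σ n_i(n_i-1)/[N(N-1)]; ``form="pi2"`` the plug-in Σ p_i².
    """
    if form == "unbiased":
        return 1.0 - _simpson_concentration(counts)
    if form == "pi2":
        c = _clean(counts)
        p = c / c.sum()
        return float(1.0 - (p * p).sum())
    raise ValueError(f"unknown Simpson form {form!r}; use 'unbiased' or 'pi2'")


def menhinick(S: int, N: int) -> float:
    """Menhinick's richness R = S/√N."""
    if S < 1 or N < 1:
        raise ValueError("S and N must be positive")
    if S > N:
        raise ValueError("cannot have more species than individuals")
    return S / math.sqrt(N)


def _even_allocation(N: int, S: int) -> np.ndarray:
    """Most even integer split of N individuals among S species."""
    base, extra = divmod(N, S)
    return np.array([base + 1] * extra + [base] * (S - extra), dtype=float)


def evenness(counts) -> tuple[float, float]:
    """Shannon evenness E_H = H'/ln S and Simpson evenness E_D.

    E_D divides the observed finite-sample Simpson diversity (1 - SI) by its
    value under the most even integer allocation of the same N among the same
    S species, so E_D ∈ (0, 1] and equals 1 for perfectly even communities.
    Undefined for S < 2 (returns NaNs).
    """
    c = _clean(counts)
    S, N = c.size, int(c.sum())
    if S < 2:
        return (float("nan"), float("nan"))
    eh = shannon(c) / math.log(S)
    si = _simpson_concentration(c)
    si_even = _simpson_concentration(_even_allocation(N, S))
    ed = (1.0 - si) / (1.0 - si_even)
    return (eh, ed)


def diversity_table(matrix: AbundanceMatrix) -> pd.DataFrame:
    """All indices for every plot of an abundance matrix.

    Returns one row per plot with columns S, N, H, D1 (unbiased Simpson),
    D_pi2, R, EH, ED; single-species plots get NaN evenness.
    """
    rows = []
    for plot_id, counts in matrix.counts.iterrows():
        c = counts.to_numpy()
        c = c[c > 0]
        S, N = int(c.size), int(c.sum())
        eh, ed = evenness(c) if S >= 2 else (float("nan"), float("nan"))
        rows.append(
            DiversityResult(
                plot_id=plot_id, S=S, N=N,
                shannon_H=shannon(c),
                simpson_D_unbiased=simpson(c, "unbiased") if N >= 2 else 0.0,
                simpson_D_pi2=simpson(c, "pi2"),
                menhinick_R=menhinick(S, N),
                evenness_EH=eh, evenness_ED=ed,
            )
        )
    df = pd.DataFrame(
        [
            {
                "plot_id": r.plot_id, "S": r.S, "N": r.N,
                "H": r.shannon_H, "D1": r.simpson_D_unbiased,
                "D_pi2": r.simpson_D_pi2, "R": r.menhinick_R,
                "EH": r.evenness_EH, "ED": r.evenness_ED,
            }
            for r in rows
        ]
    ).set_index("plot_id")
    if matrix.plots is not None and "altitude_m" in matrix.plots:
        df.insert(0, "altitude_m", matrix.plots["altitude_m"])
    return df
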