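"""Constrained ordination: canonical correspondence analysis (CCA) written
from first principles, with permutation inference and forward selection.

CCA relates a non-negative response matrix Y (plots × species, or plots ×
floristic metrics) to an environment matrix X (climate variables plus
disturbance indicators).  The algorithm is the classical one:

1. scale Y to proportions P = Y/y₊₊ with row masses r and column masses c;
2. form the chi-square-standardised residuals
   Q̄ᵢⱼ = (Pᵢⱼ − rᵢcⱼ)/√(rᵢcⱼ); total inertia = ΣQ̄² (the matrix's χ²
   statistic divided by its grand total);
3. project Q̄ onto the environment: weighted least squares with row-mass
   weights, i.e. ordinary projection of Q̄ onto B = D_r^{1/2}·X_centred;
4. SVD of the fitted matrix; squared singular values are the constrained
   eigenvalues, their sum the constrained inertia.

Score convention (stated in output metadata): species scores are the
column-standardised right singular vectors scaled by the singular values
(scaling-2 style); site scores are weighted averages of the unit species
axes; biplot scores are weighted correlations of each constraint with the
linear-combination site axes.

An RDA variant (covariance rather than chi-square weighting) is provided for
response matrices of derived floristic metrics, where chi-square weighting of
percentages and index values is hard to justify; metrics are range-scaled to
[0, 1] first so no variable dominates through its units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CCAResult", "cca", "rda", "floristic_ordination",
    "permutation_test", "forward_select", "encode_disturbance",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CCAResult:
    """Result of a constrained ordination.

    ``eigenvalues`` are per constrained axis; ``proportion_explained`` is each
    axis's share of the constrained inertia (sums to 1).  ``site_scores`` are
    weighted-average (WA) scores, ``site_scores_lc`` the linear-combination
    scores, ``species_scores`` eigenvalue-scaled, ``biplot_scores`` the
    constraint-axis correlations.
    """

    method: str
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    site_scores_lc: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    scaling: str = "species scores scaled by eigenvalues; site scores as weighted averages"

    @property
    def constrained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia

    @property
    def proportion_explained(self) -> np.ndarray:
        s = self.eigenvalues.sum()
        return self.eigenvalues / s if s > 0 else self.eigenvalues


def _as_frame(a, prefix: str) -> tuple[np.ndarray, list]:
    if isinstance(a, pd.DataFrame):
        return a.to_numpy(dtype=float), list(a.index), list(a.columns)
    a = np.asarray(a, dtype=float)
    return a, [f"{prefix}{i}" for i in range(a.shape[0])], \
        [f"{prefix}_var{j}" for j in range(a.shape[1])]


def _check_yx(Y, X):
    Yv, row_ids, col_ids = _as_frame(Y, "site")
    Xv, xrow, xcols = _as_frame(X, "env")
    if Yv.shape[0] != Xv.shape[0]:
        raise ValueError("Y and X must have the same number of rows")
    return Yv, Xv, row_ids, col_ids, xcols


def _chi_square_pieces(Yv: np.ndarray):
    if np.any(Yv < 0):
        raise ValueError("response matrix must be non-negative")
    total = Yv.sum()
    if total <= 0:
        raise ValueError("response matrix sums to zero")
    P = Yv / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r <= 0):
        raise ValueError("zero-sum row in response matrix")
    if np.any(c <= 0):
        raise ValueError("zero-sum column in response matrix")
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    return Qbar, r, c


def _weighted_projector_basis(Xv: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(D_w^{1/2}·(X − weighted column means))."""
    mean = w @ Xv
    Xc = Xv - mean
    B = np.sqrt(w)[:, None] * Xc
    # orthonormalise, dropping numerically null directions (collinearity)
    u, s, _ = np.linalg.svd(B, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return u[:, :rank]


def cca(Y, X) -> CCAResult:
    """Canonical correspondence analysis of Y (plots × species) on X.

    X may mix continuous columns (standardised internally via the weighted
    projection) and 0/1 indicator columns.  Raises if X carries more
    effective constraints than the response rank supports.
    """
    Yv, Xv, row_ids, col_ids, xcols = _check_yx(Y, X)
    Qbar, r, c = _chi_square_pieces(Yv)
    total_inertia = float((Qbar ** 2).sum())

    U_basis = _weighted_projector_basis(Xv, r)
    q = U_basis.shape[1]
    max_rank = min(Yv.shape[0] - 1, Yv.shape[1] - 1)
    if q == 0:
        raise ValueError("constraint matrix has rank zero after centring")
    if q > max_rank:
        raise ValueError(
            f"{q} effective constraints exceed the response rank {max_rank}"
        )
    Qfit = U_basis @ (U_basis.T @ Qbar)
    u, s, vt = np.linalg.svd(Qfit, full_matrices=False)
    eig = s ** 2
    n_axes = int((eig > max(_EPS, eig[0] * 1e-12 if eig.size else 0)).sum())
    n_axes = min(n_axes, q)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eig = eig[:n_axes]

    axes = [f"CCA{k + 1}" for k in range(n_axes)]
    # unit species axes, then eigenvalue scaling (scaling-2 style)
    v_std = vt.T / np.sqrt(c)[:, None]
    species = v_std * s
    P = Yv / Yv.sum()
    site_wa = (P / r[:, None]) @ v_std
    site_lc = u / np.sqrt(r)[:, None]
    biplot = _weighted_corr(Xv, site_lc, r)

    return CCAResult(
        method="cca",
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        site_scores=pd.DataFrame(site_wa, index=row_ids, columns=axes),
        site_scores_lc=pd.DataFrame(site_lc, index=row_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=col_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=xcols, columns=axes),
    )


def _weighted_corr(Xv: np.ndarray, axes: np.ndarray, w: np.ndarray) -> np.ndarray:
    xm = w @ Xv
    am = w @ axes
    xc = Xv - xm
    ac = axes - am
    cov = (w[:, None] * xc).T @ ac
    sx = np.sqrt((w[:, None] * xc ** 2).sum(axis=0))
    sa = np.sqrt((w[:, None] * ac ** 2).sum(axis=0))
    denom = np.outer(sx, sa)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, cov / denom, 0.0)
    return out


def rda(Y, X, *, scale: bool = False) -> CCAResult:
    """Redundancy analysis: covariance-based constrained ordination.

    Y columns are centred (and optionally scaled to unit variance); inertia
    is variance.  Used for response matrices of derived metrics where
    chi-square weighting is inappropriate.
    """
    Yv, Xv, row_ids, col_ids, xcols = _check_yx(Y, X)
    n = Yv.shape[0]
    Yc = Yv - Yv.mean(axis=0)
    if scale:
        sd = Yc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot scale a constant response column")
        Yc = Yc / sd
    total_inertia = float((Yc ** 2).sum() / (n - 1))

    w = np.full(n, 1.0 / n)
    U_basis = _weighted_projector_basis(Xv, w)
    q = U_basis.shape[1]
    if q == 0:
        raise ValueError("constraint matrix has rank zero after centring")
    if q > n - 1:
        raise ValueError(f"{q} effective constraints exceed the site rank {n - 1}")
    Yfit = U_basis @ (U_basis.T @ Yc)
    u, s, vt = np.linalg.svd(Yfit, full_matrices=False)
    eig = s ** 2 / (n - 1)
    n_axes = int((eig > max(_EPS, eig[0] * 1e-12 if eig.size else 0)).sum())
    n_axes = min(n_axes, q)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eig = eig[:n_axes]

    axes = [f"RDA{k + 1}" for k in range(n_axes)]
    species = vt.T * np.sqrt(eig)
    site_wa = Yc @ vt.T / np.sqrt(n - 1)
    site_lc = u * s / np.sqrt(n - 1)
    biplot = _weighted_corr(Xv, site_lc, w)
    return CCAResult(
        method="rda",
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        site_scores=pd.DataFrame(site_wa, index=row_ids, columns=axes),
        site_scores_lc=pd.DataFrame(site_lc, index=row_ids, columns=axes),
        species_scores=pd.DataFrame(species, index=col_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=xcols, columns=axes),
        scaling="species scores scaled by sqrt(eigenvalues); sites as LC scores",
    )


def floristic_ordination(metrics: pd.DataFrame, X, method: str = "rda") -> CCAResult:
    """Constrained ordination of a plots × floristic-metrics table.

    Metrics are range-scaled to [0, 1] so percentages, index values and basal
    areas are commensurable.  ``method="rda"`` (default) uses covariance
    weighting; ``"cca"`` treats the range-scaled non-negative matrix as
    abundance-like and applies chi-square weighting.
    """
    rng = metrics.max() - metrics.min()
    if (rng == 0).any():
        raise ValueError("constant metric column cannot be range-scaled")
    scaled = (metrics - metrics.min()) / rng
    if method == "rda":
        return rda(scaled, X)
    if method == "cca":
        return cca(scaled, X)
    raise ValueError("method must be 'rda' or 'cca'")


def _constrained_inertia(Yv, Xv, method: str, pieces=None) -> tuple[float, float, int]:
    """(constrained, total, rank) for the permutation machinery."""
    if method == "cca":
        Qbar, r, _ = pieces if pieces is not None else _chi_square_pieces(Yv)
        w = r
        A = Qbar
    else:
        n = Yv.shape[0]
        A = Yv - Yv.mean(axis=0)
        w = np.full(n, 1.0 / n)
    U_basis = _weighted_projector_basis(Xv, w)
    fitted = U_basis.T @ A
    return float((fitted ** 2).sum()), float((A ** 2).sum()), U_basis.shape[1]


def _pseudo_f(ci: float, total: float, q: int, n: int) -> float:
    resid = max(total - ci, _EPS)
    df_resid = n - q - 1
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the pseudo-F")
    return (ci / q) / (resid / df_resid)


def permutation_test(Y, X, n_perm: int = 999, seed: int | None = None,
                     method: str = "cca") -> tuple[float, float]:
    """Permutation significance of the constrained model.

    Rows of X are permuted; the statistic is the pseudo-F
    (constrained/q) / (residual/(n−q−1)).  Returns ``(p, observed_F)`` with
    p = (1 + #{F* ≥ F}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    Yv, Xv, *_ = _check_yx(Y, X)
    n = Yv.shape[0]
    rng = np.random.default_rng(seed)
    pieces = _chi_square_pieces(Yv) if method == "cca" else None
    ci, total, q = _constrained_inertia(Yv, Xv, method, pieces)
    f_obs = _pseudo_f(ci, total, q, n)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ci_p, _, q_p = _constrained_inertia(Yv, Xv[perm], method, pieces)
        if _pseudo_f(ci_p, total, q_p, n) >= f_obs:
            hits += 1
    return (1 + hits) / (1 + n_perm), f_obs


def forward_select(Y, X_candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 199, seed: int | None = None,
                   method: str = "cca") -> list[str]:
    """Greedy forward selection of constraint columns.

    At each step the candidate with the largest conditional constrained-
    inertia gain is tried; it is admitted while its permutation p-value
    (candidate column permuted, selected columns fixed; statistic = the
    conditional gain) is ≤ alpha.  Collinear candidates (no rank gain) are
    skipped.  Returns the selected column names in order of admission.
    """
    if not isinstance(X_candidates, pd.DataFrame):
        X_candidates = pd.DataFrame(np.asarray(X_candidates, dtype=float))
    if X_candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    Yv, Xall, *_ = _check_yx(Y, X_candidates)
    n = Yv.shape[0]
    pieces = _chi_square_pieces(Yv) if method == "cca" else None
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    remaining = list(X_candidates.columns)
    cols = {name: Xall[:, j] for j, name in enumerate(X_candidates.columns)}

    def inertia(names) -> tuple[float, int]:
        M = np.column_stack([cols[nm] for nm in names])
        ci, _, q = _constrained_inertia(Yv, M, method, pieces)
        return ci, q

    ci_sel, q_sel = 0.0, 0
    while remaining:
        gains = []
        for name in remaining:
            ci_new, q_new = inertia(selected + [name])
            if q_new <= q_sel:  # collinear with already-selected constraints
                continue
            gains.append((ci_new - ci_sel, name, ci_new, q_new))
        if not gains:
            break
        gain, best, ci_best, q_best = max(gains)
        # conditional permutation test: permute the candidate column only
        hits = 0
        col = cols[best]
        for _ in range(n_perm):
            cols_p = dict(cols)
            cols_p[best] = col[rng.permutation(n)]
            M = np.column_stack([cols_p[nm] for nm in selected + [best]])
            ci_p, _, q_p = _constrained_inertia(Yv, M, method, pieces)
            if q_p > q_sel and (ci_p - ci_sel) >= gain:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        ci_sel, q_sel = ci_best, q_best
    return selected


def encode_disturbance(levels: pd.Series, drop: str = "low") -> pd.DataFrame:
    """0/1 indicator columns for the disturbance classes, dropping one
    redundant level (recorded in the column ordering) to avoid exact
    collinearity with the implicit intercept."""
    levels = levels.astype(str)
    keep = [l for l in ("low", "medium", "high") if l != drop]
    unknown = set(levels) - {"low", "medium", "high"}
    if unknown:
        raise ValueError(f"unknown disturbance levels: {sorted(unknown)}")
    return pd.DataFrame(
        {f"disturbance_{l}": (levels == l).astype(float) for l in keep},
        index=levels.index,
    )
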