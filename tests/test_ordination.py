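import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.stats

from altidiv.ordination import (
    cca,
    encode_disturbance,
    floristic_ordination,
    forward_select,
    permutation_test,
    rda,
)


def random_community(rng, n_sites=10, n_species=8):
    Y = rng.poisson(6.0, size=(n_sites, n_species)).astype(float)
    Y[Y.sum(axis=1) == 0, 0] = 1  # avoid zero rows
    Y[:, Y.sum(axis=0) == 0] += 1
    return Y


def brute_force_cca_eigenvalues(Y, X):
    """Independent oracle: generalized-eigenproblem route.

    Eigenvalues of Q̄ᵀ B (BᵀB)⁻¹ Bᵀ Q̄ with B the row-mass-weighted centred
    constraints — solved via scipy's symmetric eigensolver rather than the
    SVD-of-projection path the implementation uses.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    P = Y / Y.sum()
    r, c = P.sum(1), P.sum(0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - r @ X
    B = np.sqrt(r)[:, None] * Xc
    M = Qbar.T @ B @ scipy.linalg.pinv(B.T @ B) @ B.T @ Qbar
    vals = scipy.linalg.eigh(M, eigvals_only=True)[::-1]
    return vals[vals > 1e-10]


class TestCcaCore:
    def test_total_inertia_is_chi_square_over_grand_total(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            Y = random_community(rng)
            X = rng.normal(size=(10, 2))
            res = cca(Y, X)
            chi2 = scipy.stats.chi2_contingency(Y, correction=False)[0]
            assert res.total_inertia == pytest.approx(chi2 / Y.sum(), rel=1e-10)

    def test_eigenvalues_match_generalized_eigenproblem_oracle(self):
        rng = np.random.default_rng(1)
        for n, m, q in [(3, 3, 1), (3, 3, 2), (5, 4, 2), (8, 6, 3)]:
            Y = rng.poisson(5.0, size=(n, m)) + 1.0
            X = rng.normal(size=(n, q))
            res = cca(Y, X)
            oracle = brute_force_cca_eigenvalues(Y, X)
            assert np.allclose(res.eigenvalues, oracle[: len(res.eigenvalues)],
                               atol=1e-10)

    def test_full_rank_constraints_reproduce_plain_ca(self):
        rng = np.random.default_rng(2)
        Y = random_community(rng, n_sites=6, n_species=9)
        X = np.eye(6)[:, :5]  # site indicators span the full centred site space
        res = cca(Y, X)
        # plain CA eigenvalues: SVD of the chi-square residual matrix itself
        P = Y / Y.sum()
        r, c = P.sum(1), P.sum(0)
        Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        ca_eig = np.linalg.svd(Qbar, compute_uv=False) ** 2
        ca_eig = ca_eig[ca_eig > 1e-10]
        assert np.allclose(res.eigenvalues, ca_eig, atol=1e-10)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalue_bounds_and_axis_percentages(self):
        rng = np.random.default_rng(3)
        Y = random_community(rng)
        X = rng.normal(size=(10, 3))
        res = cca(Y, X)
        assert np.all(res.eigenvalues >= 0) and np.all(res.eigenvalues < 1)
        assert res.constrained_inertia <= res.total_inertia + 1e-12
        assert 0 <= res.constrained_fraction <= 1
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_matched_row_and_column_permutation(self):
        rng = np.random.default_rng(4)
        Y = random_community(rng)
        X = rng.normal(size=(10, 2))
        rows = rng.permutation(10)
        cols = rng.permutation(8)
        base = cca(Y, X)
        perm = cca(Y[np.ix_(rows, cols)], X[rows])
        assert np.allclose(base.eigenvalues, perm.eigenvalues, atol=1e-10)

    def test_constrained_inertia_monotone_in_added_columns(self):
        rng = np.random.default_rng(5)
        Y = random_community(rng)
        X = rng.normal(size=(10, 4))
        prev = 0.0
        for q in range(1, 5):
            ci = cca(Y, X[:, :q]).constrained_inertia
            assert ci >= prev - 1e-12
            prev = ci

    def test_matches_reference_library(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(random_community(rng),
                         index=[f"s{i}" for i in range(10)],
                         columns=[f"sp{j}" for j in range(8)])
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=Y.index,
                         columns=list("abc"))
        mine = cca(Y, X)
        theirs = skbio_ord.cca(Y, X)
        ref = np.asarray(theirs.eigvals)[: len(mine.eigenvalues)]
        assert np.allclose(mine.eigenvalues, ref, atol=1e-10)

    def test_planted_gradient_dominates_first_axis(self):
        # species optima ordered along one synthetic climate variable
        n_sites, n_species = 20, 12
        gradient = np.linspace(-2, 2, n_sites)
        optima = np.linspace(-2, 2, n_species)
        lam = 20 * np.exp(-((gradient[:, None] - optima[None, :]) ** 2))
        rng = np.random.default_rng(7)
        Y = rng.poisson(lam) + (lam.sum(1) == 0)[:, None]
        X = np.column_stack([gradient, rng.normal(size=n_sites)])
        res = cca(pd.DataFrame(Y), pd.DataFrame(X, columns=["grad", "noise"]))
        assert res.proportion_explained[0] > 0.90
        biplot1 = res.biplot_scores["CCA1"].abs()
        assert biplot1["grad"] > biplot1["noise"]
        assert biplot1["grad"] > 0.9

    def test_too_many_constraints_rejected(self):
        rng = np.random.default_rng(8)
        Y = random_community(rng, n_sites=4, n_species=3)
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="constraints"):
            cca(Y, X)

    def test_zero_sum_column_rejected(self):
        Y = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="zero-sum column"):
            cca(Y, np.array([[1.0], [2.0]]))


class TestRda:
    def test_matches_reference_library(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(9)
        Y = pd.DataFrame(rng.normal(size=(12, 5)),
                         index=[f"s{i}" for i in range(12)],
                         columns=[f"v{j}" for j in range(5)])
        X = pd.DataFrame(rng.normal(size=(12, 2)), index=Y.index,
                         columns=list("ab"))
        mine = rda(Y, X)
        theirs = skbio_ord.rda(Y, X)
        # reference library reports singular values; variance eigenvalues
        # are their squares over n-1
        ref = np.asarray(theirs.eigvals)[: len(mine.eigenvalues)] ** 2 / (12 - 1)
        assert np.allclose(mine.eigenvalues, ref, atol=1e-10)

    def test_floristic_mode_range_scales(self):
        rng = np.random.default_rng(10)
        metrics = pd.DataFrame({
            "TBApha": rng.uniform(10, 60, 10),
            "H": rng.uniform(2, 4, 10),
            "pct": rng.uniform(0, 100, 10),
        })
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        res = floristic_ordination(metrics, X)
        assert res.method == "rda"
        assert res.constrained_inertia <= res.total_inertia + 1e-12
        with pytest.raises(ValueError, match="constant"):
            floristic_ordination(metrics.assign(flat=1.0), X)


class TestPermutationTest:
    def test_guards(self):
        rng = np.random.default_rng(11)
        Y = random_community(rng)
        with pytest.raises(ValueError, match="99"):
            permutation_test(Y, rng.normal(size=(10, 2)), n_perm=10)

    def test_strong_association_is_significant(self):
        n_sites, n_species = 20, 12
        gradient = np.linspace(-2, 2, n_sites)
        optima = np.linspace(-2, 2, n_species)
        lam = 25 * np.exp(-((gradient[:, None] - optima[None, :]) ** 2))
        rng = np.random.default_rng(12)
        Y = rng.poisson(lam) + (lam.sum(1) == 0)[:, None]
        p, f = permutation_test(Y, gradient[:, None], n_perm=999, seed=1)
        assert p <= 0.01
        assert f > 1

    def test_null_p_is_not_extreme(self):
        rng = np.random.default_rng(13)
        Y = random_community(rng, n_sites=15)
        X = rng.normal(size=(15, 2))
        p, _ = permutation_test(Y, X, n_perm=199, seed=2)
        assert 0 < p <= 1

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(14)
        Y = random_community(rng)
        X = rng.normal(size=(10, 2))
        p1, _ = permutation_test(Y, X, n_perm=199, seed=5)
        p2, _ = permutation_test(Y, X, n_perm=199, seed=5)
        assert p1 == p2


class TestForwardSelect:
    def _planted(self, rng, n_sites=20, n_species=12):
        gradient = np.linspace(-2, 2, n_sites)
        optima = np.linspace(-2, 2, n_species)
        lam = 25 * np.exp(-((gradient[:, None] - optima[None, :]) ** 2))
        Y = rng.poisson(lam) + (lam.sum(1) == 0)[:, None]
        return Y, gradient

    def test_informative_variable_selected_first(self):
        rng = np.random.default_rng(15)
        Y, gradient = self._planted(rng)
        X = pd.DataFrame({
            "signal": gradient,
            "noise1": rng.normal(size=20),
            "noise2": rng.normal(size=20),
        })
        selected = forward_select(Y, X, alpha=0.05, n_perm=199, seed=3)
        assert selected and selected[0] == "signal"

    def test_all_noise_selects_nearly_nothing(self):
        rng = np.random.default_rng(16)
        Y = random_community(rng, n_sites=15)
        X = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        selected = forward_select(Y, X, alpha=0.05, n_perm=199, seed=4)
        assert len(selected) <= 1

    def test_duplicated_column_never_selected_twice(self):
        rng = np.random.default_rng(17)
        Y, gradient = self._planted(rng)
        X = pd.DataFrame({"signal": gradient, "copy": gradient.copy()})
        selected = forward_select(Y, X, alpha=0.05, n_perm=199, seed=5)
        assert sorted(selected) != ["copy", "signal"]  # collinear twin skipped
        assert len(selected) == 1


class TestEncodeDisturbance:
    def test_drops_one_level(self):
        levels = pd.Series(["low", "medium", "high", "medium"])
        dummies = encode_disturbance(levels)
        assert list(dummies.columns) == ["disturbance_medium", "disturbance_high"]
        assert dummies.sum().tolist() == [2.0, 1.0]

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            encode_disturbance(pd.Series(["severe"]))
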