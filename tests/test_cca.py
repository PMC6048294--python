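import logging

import numpy as np
import pandas as pd
import pytest

from sc4a import (
    ExplanatoryMatrix,
    activation_score,
    cca,
    compute_masses,
    partition_gene_space,
    project_constrained,
    standardize,
    validate_expression,
)
from conftest import fullrank_Z, random_expression


def brute_inertia(X):
    """Element-wise chi-square inertia: sum (X/n - r c)^2 / (r c)."""
    m = compute_masses(X)
    E = np.outer(m.r, m.c)
    return float(np.sum((X.values / m.n - E) ** 2 / E))


class TestStandardize:
    def test_toy_diagonal(self, toy_diag):
        res = standardize(toy_diag)
        np.testing.assert_allclose(res.S, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)
        assert res.total_inertia == pytest.approx(1.0, abs=1e-10)

    def test_independence_table_has_zero_inertia(self, rng):
        r = rng.dirichlet(np.ones(6))
        c = rng.dirichlet(np.ones(4))
        X = validate_expression(100 * np.outer(r, c), [f"g{i}" for i in range(6)],
                                [f"s{j}" for j in range(4)])
        res = standardize(X)
        np.testing.assert_allclose(res.P, 0, atol=1e-14)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_matches_brute_force(self, rng):
        X = random_expression(rng, 6, 5)
        assert standardize(X).total_inertia == pytest.approx(brute_inertia(X), rel=1e-10)

    def test_residuals_have_zero_margins(self, rng):
        X = random_expression(rng, 9, 4)
        res = standardize(X)
        np.testing.assert_allclose(res.P.sum(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(res.P.sum(axis=1), 0, atol=1e-12)


class TestProjection:
    def test_full_span_recovers_S(self, rng):
        X = random_expression(rng, 6, 4)
        masses = compute_masses(X)
        res = standardize(X, masses)
        sp = project_constrained(res, fullrank_Z(rng, 6), masses)
        np.testing.assert_allclose(sp.S_star, res.S, atol=1e-10)

    def test_idempotency(self, rng):
        X = random_expression(rng, 8, 6)
        masses = compute_masses(X)
        res = standardize(X, masses)
        Z = ExplanatoryMatrix(rng.normal(size=(8, 2)), ["a", "b"]).standardize()
        sp = project_constrained(res, Z, masses)
        assert (np.linalg.norm(sp.apply_Q(sp.S_star) - sp.S_star)
                <= 1e-10 * np.linalg.norm(res.S))

    def test_constrained_at_most_total(self, rng):
        for _ in range(10):
            X = random_expression(rng, 10, 5)
            masses = compute_masses(X)
            res = standardize(X, masses)
            Z = ExplanatoryMatrix(rng.normal(size=(10, 3)), list("abc")).standardize()
            sp = project_constrained(res, Z, masses)
            assert sp.constrained_inertia <= res.total_inertia + 1e-10

    def test_collinear_columns_warn(self, rng, caplog):
        X = random_expression(rng, 8, 5)
        masses = compute_masses(X)
        res = standardize(X, masses)
        z = rng.normal(size=8)
        Z = ExplanatoryMatrix(np.column_stack([z, 2 * z]), ["a", "b"]).standardize()
        with caplog.at_level(logging.WARNING, logger="sc4a"):
            project_constrained(res, Z, masses)
        assert any("rank deficient" in r.message for r in caplog.records)


class TestDecomposition:
    def test_toy_single_eigenvalue_one(self, toy_diag, rng):
        sol = cca(toy_diag, fullrank_Z(rng, 2))
        assert sol.J == 1
        assert sol.lam[0] == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_sum_to_constrained_inertia(self, rng):
        for _ in range(10):
            X = random_expression(rng, 9, 6)
            k = int(rng.integers(1, 5))
            Z = ExplanatoryMatrix(rng.normal(size=(9, k)),
                                  [f"z{i}" for i in range(k)]).standardize()
            sol = cca(X, Z)
            assert sol.lam.sum() == pytest.approx(sol.constrained_inertia, abs=1e-10)
            np.testing.assert_allclose(sol.lam, sol.alpha**2)

    def test_rank_rule(self, rng):
        X = random_expression(rng, 10, 5)
        for k in (1, 3, 7):
            Z = ExplanatoryMatrix(rng.normal(size=(10, k)),
                                  [f"z{i}" for i in range(k)]).standardize()
            sol = cca(X, Z)
            assert sol.J == min(10 - 1, 5 - 1, k)

    def test_orthonormal_axes(self, rng):
        X = random_expression(rng, 12, 7)
        Z = ExplanatoryMatrix(rng.normal(size=(12, 3)), list("abc")).standardize()
        sol = cca(X, Z)
        np.testing.assert_allclose(sol.U.T @ sol.U, np.eye(sol.J), atol=1e-8)
        np.testing.assert_allclose(sol.V.T @ sol.V, np.eye(sol.J), atol=1e-8)
        assert np.all(np.diff(sol.alpha) <= 1e-12)

    def test_oracle_direct_svd_of_S(self, rng):
        """Full-rank-constrained CCA equals plain CA by independent SVD."""
        for _ in range(20):
            p, m = int(rng.integers(4, 21)), int(rng.integers(3, 11))
            X = random_expression(rng, p, m)
            sol = cca(X, fullrank_Z(rng, p))
            sv = np.linalg.svd(standardize(X).S, compute_uv=False)
            np.testing.assert_allclose(sol.alpha, sv[: sol.J], atol=1e-8)

    def test_chi_square_distances(self, rng):
        """Column principal coordinates reproduce chi-square profile distances."""
        for _ in range(5):
            X = random_expression(rng, 8, 5)
            sol = cca(X, fullrank_Z(rng, 8))
            masses = compute_masses(X)
            prof = X.values / X.values.sum(axis=0)
            for j in range(5):
                for k in range(j):
                    chi = np.sqrt(np.sum((prof[:, j] - prof[:, k]) ** 2 / masses.r))
                    d = np.linalg.norm(sol.sample_scores[j] - sol.sample_scores[k])
                    assert d == pytest.approx(chi, abs=1e-8)

    def test_skbio_cross_check(self, rng):
        """Independent reference: scikit-bio's vegan-style constrained CA."""
        from skbio.stats.ordination import cca as skbio_cca

        X = random_expression(rng, 12, 6)
        Z = ExplanatoryMatrix(rng.normal(size=(12, 2)), ["z1", "z2"]).standardize()
        sol = cca(X, Z)
        ref = skbio_cca(pd.DataFrame(X.values), pd.DataFrame(Z.Z))
        np.testing.assert_allclose(sol.lam, ref.eigvals.values[: sol.J], atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        X = random_expression(rng, 10, 6)
        Z = ExplanatoryMatrix(rng.normal(size=(10, 2)), ["a", "b"]).standardize()
        s1, s2 = cca(X, Z), cca(X, Z)
        np.testing.assert_array_equal(s1.U, s2.U)
        np.testing.assert_array_equal(s1.sample_scores, s2.sample_scores)

    def test_joint_row_permutation_invariance(self, rng):
        X = random_expression(rng, 10, 5)
        Z = ExplanatoryMatrix(rng.normal(size=(10, 2)), ["a", "b"]).standardize()
        sol = cca(X, Z)
        perm = rng.permutation(10)
        Xp = validate_expression(X.values[perm], [X.row_ids[i] for i in perm], X.col_ids)
        Zp = ExplanatoryMatrix(Z.Z[perm], Z.names, standardized=True)
        solp = cca(Xp, Zp)
        np.testing.assert_allclose(solp.lam, sol.lam, atol=1e-10)
        np.testing.assert_allclose(solp.sample_scores, sol.sample_scores, atol=1e-8)
        np.testing.assert_allclose(solp.gene_scores_wa, sol.gene_scores_wa[perm], atol=1e-8)


class TestBiplot:
    def test_1d_biplot_is_plus_minus_one(self, rng):
        for _ in range(20):
            X = random_expression(rng, int(rng.integers(4, 15)), int(rng.integers(3, 8)))
            Z = ExplanatoryMatrix(rng.normal(size=(X.p, 1)), ["v"]).standardize()
            sol = cca(X, Z)
            if sol.constrained_inertia > 1e-12:
                assert abs(abs(sol.biplot[0, 0]) - 1.0) < 1e-6

    def test_negating_covariate_negates_biplot_row(self, rng):
        X = random_expression(rng, 9, 5)
        Z = ExplanatoryMatrix(rng.normal(size=(9, 2)), ["a", "b"]).standardize()
        sol = cca(X, Z)
        Zn = ExplanatoryMatrix(Z.Z * np.array([-1.0, 1.0]), Z.names, standardized=True)
        soln = cca(X, Zn)
        np.testing.assert_allclose(soln.biplot[0], -sol.biplot[0], atol=1e-8)
        np.testing.assert_allclose(soln.biplot[1], sol.biplot[1], atol=1e-8)


class TestActivationScore:
    def make_loaded_fixture(self):
        """Samples A,B: A loaded on high-z genes, B on low-z genes."""
        vals = np.ones((10, 4))
        vals[:5, 0] = 9.0  # sample A rich in the first 5 genes
        vals[5:, 1] = 9.0  # sample B rich in the last 5
        vals[:, 2:] = 2.0
        X = validate_expression(vals, [f"g{i}" for i in range(10)], list("ABCD"))
        z = np.array([3.0] * 5 + [-3.0] * 5)  # high-z = the genes A is loaded on
        Z = ExplanatoryMatrix(z[:, None], ["act"]).standardize()
        return X, Z

    def test_loaded_sample_scores_higher(self):
        X, Z = self.make_loaded_fixture()
        s = pd.Series(activation_score(cca(X, Z)), index=X.col_ids)
        assert s["A"] > s["B"]

    def test_negating_covariate_negates_score(self):
        X, Z = self.make_loaded_fixture()
        s1 = activation_score(cca(X, Z))
        s2 = activation_score(cca(X, ExplanatoryMatrix(-Z.Z, ["act"], standardized=True)))
        np.testing.assert_allclose(s1, -s2, atol=1e-10)

    def test_identical_profiles_score_zero(self, rng):
        col = rng.uniform(1, 5, 8)
        X = validate_expression(np.tile(col[:, None], (1, 4)),
                                [f"g{i}" for i in range(8)], list("ABCD"))
        Z = ExplanatoryMatrix(rng.normal(size=(8, 1)), ["v"]).standardize()
        np.testing.assert_allclose(activation_score(cca(X, Z)), 0, atol=1e-10)

    def test_requires_single_variable(self, rng):
        X = random_expression(rng, 8, 4)
        Z = ExplanatoryMatrix(rng.normal(size=(8, 2)), ["a", "b"]).standardize()
        with pytest.raises(ValueError, match="k=1"):
            activation_score(cca(X, Z))


class TestGenePartition:
    def test_cardinality_and_nesting(self, rng):
        X = random_expression(rng, 100, 8)
        Z = ExplanatoryMatrix(rng.normal(size=(100, 3)), list("abc")).standardize()
        parts = partition_gene_space(cca(X, Z), axis1_quantile=0.25)
        assert len(parts["tact"]) >= 25  # boundary ties included
        assert parts["tact_foxp3"].members | parts["tact_runx1"].members == parts["tact"].members
        assert not (parts["tact_foxp3"].members & parts["tact_runx1"].members)

    def test_axis2_split_follows_sign(self, rng):
        X = random_expression(rng, 40, 6)
        Z = ExplanatoryMatrix(rng.normal(size=(40, 2)), ["a", "b"]).standardize()
        sol = cca(X, Z)
        parts = partition_gene_space(sol)
        g2 = dict(zip(sol.row_ids, sol.gene_scores_wa[:, 1]))
        assert all(g2[g] >= 0 for g in parts["tact_foxp3"].members)
        assert all(g2[g] < 0 for g in parts["tact_runx1"].members)

    def test_requires_two_axes(self, rng):
        X = random_expression(rng, 20, 5)
        Z = ExplanatoryMatrix(rng.normal(size=(20, 1)), ["v"]).standardize()
        with pytest.raises(ValueError):
            partition_gene_space(cca(X, Z))
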