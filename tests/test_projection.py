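import numpy as np
import pandas as pd
import pytest

from covproj import (
    DataTable,
    UsageError,
    ValidationConfig,
    cp_multivariate,
    cp_sequence,
    cp_single,
    fit_pls1,
    make_decomposition,
    pseudoinverse_adjust,
    standardize_vector,
    variance_partition,
)

from .conftest import centered


def table_from_matrix(y, X, Z, z_groups=None):
    """Assemble a centered DataTable from raw arrays (one covariate per column)."""
    n = len(y)
    cols = {"y": y}
    roles = {"y": "outcome"}
    groups = {}
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    for j in range(Z.shape[1]):
        name = f"z{j + 1}"
        cols[name] = Z[:, j]
        roles[name] = "covariate"
        groups[name] = z_groups[j] if z_groups else name
    for j in range(X.shape[1]):
        name = f"x{j + 1}"
        cols[name] = X[:, j]
        roles[name] = "explanatory"
    frame = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    order = []
    for g in groups.values():
        if g not in order:
            order.append(g)
    return DataTable(frame=frame, roles=roles, groups=groups, group_order=order)


def random_table(rng, n=30, m=4, k=1, z_groups=None):
    X = centered(rng, n, m)
    Z = centered(rng, n, k)
    y = X @ rng.standard_normal(m) + Z @ rng.standard_normal(k) + rng.standard_normal(n)
    y -= y.mean()
    return table_from_matrix(y, X, Z, z_groups)


class TestCPSingle:
    def test_projected_column_is_exactly_zero(self, rng):
        t = random_table(rng)
        d = cp_single(make_decomposition(t), "z1")
        assert (d.residual["z1"].to_numpy() == 0.0).all()

    def test_outcome_residual_equals_ols_residual(self, rng):
        for _ in range(5):
            t = random_table(rng)
            d = cp_single(make_decomposition(t), "z1")
            z = t.column("z1")
            y = t.column("y")
            e_oracle = y - z * (z @ y) / (z @ z)  # normal-equations residual
            np.testing.assert_allclose(
                d.residual["y"].to_numpy(), e_oracle, atol=1e-10
            )

    def test_orthogonal_covariate_leaves_columns_unchanged(self, rng):
        n = 40
        X = centered(rng, n, 3)
        y = X @ np.ones(3)
        z = rng.standard_normal(n)
        z -= z.mean()
        # orthogonalize z against y and X
        B = np.column_stack([y, X])
        z = pseudoinverse_adjust(B, z)
        t = table_from_matrix(y - y.mean(), X, z)
        d = cp_single(make_decomposition(t), "z1")
        np.testing.assert_allclose(d.residual["y"].to_numpy(), t.column("y"), atol=1e-8)
        for c in ("x1", "x2", "x3"):
            np.testing.assert_allclose(d.residual[c].to_numpy(), t.column(c), atol=1e-8)

    def test_residual_orthogonal_to_step_score(self, rng):
        t = random_table(rng, k=2)
        d = make_decomposition(t)
        cp_single(d, "z1")
        cp_single(d, "z2")
        E = d.residual.to_numpy()
        for step in d.steps:
            assert np.abs(step.score @ E).max() < 1e-8 * np.abs(E).max()

    def test_ss_conservation_per_column(self, rng):
        t = random_table(rng, k=2)
        d = make_decomposition(t)
        cp_single(d, "z1")
        cp_single(d, "z2")
        removed = sum(s.removed_ss for s in d.steps)
        total = removed + d.residual_ss()
        np.testing.assert_allclose(total.to_numpy(), d.original_ss.to_numpy(), rtol=1e-8)

    def test_double_projection_rejected(self, rng):
        t = random_table(rng)
        d = cp_single(make_decomposition(t), "z1")
        with pytest.raises(UsageError):
            cp_single(d, "z1")

    def test_absent_column_rejected(self, rng):
        t = random_table(rng)
        with pytest.raises(UsageError):
            cp_single(make_decomposition(t), "nope")


class TestCPMultivariate:
    def test_noisy_copies_recover_latent(self):
        rng = np.random.default_rng(5)
        n = 1000
        latent = rng.standard_normal(n)
        Z = latent[:, None] + 0.05 * rng.standard_normal((n, 4))
        Z -= Z.mean(axis=0)
        X = centered(rng, n, 3)
        y = latent + X @ np.array([0.5, -0.3, 0.2]) + 0.3 * rng.standard_normal(n)
        y -= y.mean()
        t = table_from_matrix(y, X, Z, z_groups=["g", "g", "g", "g"])
        d = make_decomposition(t)
        d, tp, curve = cp_multivariate(
            d, "g", ["z1", "z2", "z3", "z4"], "y", ValidationConfig(reps=60, seed=1)
        )
        assert tp is not None
        c = abs(tp.t_tp @ latent) / (np.linalg.norm(tp.t_tp) * np.linalg.norm(latent))
        assert c >= 0.99
        # residual y is close to y adjusted for the latent
        e_oracle = pseudoinverse_adjust(latent - latent.mean(), y)
        resid = d.residual["y"].to_numpy()
        assert np.corrcoef(resid, e_oracle)[0, 1] > 0.99

    def test_group_orthogonal_to_outcome_skipped(self):
        rng = np.random.default_rng(6)
        n = 300
        X = centered(rng, n, 3)
        y = X @ np.ones(3) + 0.5 * rng.standard_normal(n)
        y -= y.mean()
        Z = centered(rng, n, 4)  # independent of y
        t = table_from_matrix(y, X, Z, z_groups=["g"] * 4)
        d = make_decomposition(t)
        with pytest.warns(UserWarning, match="non-predictive|no validated"):
            d, tp, curve = cp_multivariate(
                d, "g", ["z1", "z2", "z3", "z4"], "y", ValidationConfig(reps=60, seed=2)
            )
        assert tp is None
        assert curve.selected_A == 0
        np.testing.assert_allclose(d.residual["y"].to_numpy(), y, atol=1e-12)

    def test_tp_score_column_participates_in_partition(self):
        rng = np.random.default_rng(7)
        n = 400
        latent = rng.standard_normal(n)
        Z = latent[:, None] + 0.2 * rng.standard_normal((n, 3))
        Z -= Z.mean(axis=0)
        X = centered(rng, n, 2)
        y = latent + X @ np.ones(2) + 0.3 * rng.standard_normal(n)
        y -= y.mean()
        t = table_from_matrix(y, X, Z, z_groups=["g"] * 3)
        d = make_decomposition(t)
        d, tp, _ = cp_multivariate(
            d, "g", ["z1", "z2", "z3"], "y", ValidationConfig(reps=50, seed=3)
        )
        assert "tp_g" in d.column_labels
        assert (d.residual["tp_g"].to_numpy() == 0.0).all()
        vp = variance_partition(d)
        np.testing.assert_allclose(vp.table.sum(axis=1).to_numpy(), 100.0, atol=0.01)


class TestCPSequence:
    def test_orthogonal_covariates_order_invariant(self, rng):
        n = 60
        Z = centered(rng, n, 2)
        # Gram-Schmidt after centering keeps columns centered and orthogonal
        Z[:, 1] -= Z[:, 0] * (Z[:, 0] @ Z[:, 1]) / (Z[:, 0] @ Z[:, 0])
        X = centered(rng, n, 3)
        y = X @ np.ones(3) + Z @ np.array([0.5, -0.5]) + rng.standard_normal(n)
        y -= y.mean()
        t12 = table_from_matrix(y, X, Z)
        d12 = cp_sequence(t12, ["z1", "z2"])
        d21 = cp_sequence(t12, ["z2", "z1"])
        diff = np.abs(d12.residual.to_numpy() - d21.residual.to_numpy()).max()
        assert diff < 1e-8

    def test_sequence_over_orthogonal_basis_equals_pseudoinverse(self, rng):
        n = 50
        Z = centered(rng, n, 3)
        for j in range(1, 3):  # centered Gram-Schmidt -> orthogonal basis
            for i in range(j):
                Z[:, j] -= Z[:, i] * (Z[:, i] @ Z[:, j]) / (Z[:, i] @ Z[:, i])
        X = centered(rng, n, 4)
        y = X @ np.ones(4) + Z @ np.array([1.0, -1.0, 0.5]) + rng.standard_normal(n)
        y -= y.mean()
        t = table_from_matrix(y, X, Z)
        d = cp_sequence(t, ["z1", "z2", "z3"])
        M = np.column_stack([y, X])
        oracle = pseudoinverse_adjust(Z, M)
        got = d.residual[["y", "x1", "x2", "x3", "x4"]].to_numpy()
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_adjustment_routes_agree(self, rng):
        # CP simultaneous adjustment == PLS on (y_adj, X_adj) == PLS on (y, X_adj)
        n, m = 80, 5
        X = centered(rng, n, m)
        z = centered(rng, n, 1)
        y = X @ rng.standard_normal(m) + 0.8 * z[:, 0] + 0.5 * rng.standard_normal(n)
        y -= y.mean()
        t = table_from_matrix(y, X, z)
        d = cp_sequence(t, ["z1"])
        y_cp = d.residual["y"].to_numpy()
        X_cp = d.residual[[f"x{j + 1}" for j in range(m)]].to_numpy()
        y_adj = pseudoinverse_adjust(z, y)
        X_adj = pseudoinverse_adjust(z, X)
        for A in (1, 2, 3):
            b_cp = fit_pls1(X_cp, y_cp, A).b
            b_both = fit_pls1(X_adj, y_adj, A).b
            b_xonly = fit_pls1(X_adj, y, A).b
            scale = np.abs(b_both).max()
            assert np.abs(b_cp - b_both).max() < 1e-6 * scale
            assert np.abs(b_xonly - b_both).max() < 1e-6 * scale

    def test_residual_invariant_to_score_scaling(self, rng):
        # projecting on z or on standardized z gives identical residuals
        t = random_table(rng, n=50)
        d = cp_single(make_decomposition(t), "z1")
        z = t.column("z1")
        zs = standardize_vector(z)
        M = np.column_stack([t.column("y")] + [t.column(f"x{j + 1}") for j in range(4)])
        resid_raw = M - np.outer(z, z @ M / (z @ z))
        resid_std = M - np.outer(zs, zs @ M / (zs @ zs))
        np.testing.assert_allclose(resid_raw, resid_std, atol=1e-10)
        got = d.residual[["y", "x1", "x2", "x3", "x4"]].to_numpy()
        np.testing.assert_allclose(got, resid_std, atol=1e-10)


class TestPseudoinverseAdjust:
    def test_full_rank_equals_ols_residuals(self, rng):
        Z = centered(rng, 40, 3)
        M = centered(rng, 40, 5)
        got = pseudoinverse_adjust(Z, M)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ M)
        np.testing.assert_allclose(got, M - Z @ beta, atol=1e-10)

    def test_duplicated_column_invariance(self, rng):
        Z = centered(rng, 30, 2)
        Zdup = np.column_stack([Z, Z[:, 0]])
        M = centered(rng, 30, 4)
        np.testing.assert_allclose(
            pseudoinverse_adjust(Zdup, M), pseudoinverse_adjust(Z, M), atol=1e-10
        )

    def test_m_in_column_space_gives_zero(self, rng):
        Z = centered(rng, 25, 3)
        M = Z @ rng.standard_normal((3, 2))
        assert np.abs(pseudoinverse_adjust(Z, M)).max() < 1e-10

    def test_residual_orthogonal_to_z(self, rng):
        Z = centered(rng, 35, 4)
        M = centered(rng, 35, 3)
        R = pseudoinverse_adjust(Z, M)
        assert np.abs(Z.T @ R).max() < 1e-8


class TestVariancePartition:
    def test_percentages_sum_to_100(self, rng):
        t = random_table(rng, k=2)
        d = cp_sequence(t, ["z1", "z2"])
        vp = variance_partition(d)
        np.testing.assert_allclose(vp.table.sum(axis=1).to_numpy(), 100.0, atol=0.01)

    def test_variable_identical_to_first_covariate(self, rng):
        n = 40
        z = centered(rng, n, 1)[:, 0]
        X = np.column_stack([z, centered(rng, n, 2)])
        y = z + centered(rng, n, 1)[:, 0]
        y -= y.mean()
        t = table_from_matrix(y, X, z)
        d = cp_sequence(t, ["z1"])
        vp = variance_partition(d)
        assert vp.table.loc["x1", "z1"] == pytest.approx(100.0, abs=1e-6)
        assert vp.table.loc["x1", "residual"] == pytest.approx(0.0, abs=1e-6)
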