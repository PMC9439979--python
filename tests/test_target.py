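import numpy as np
import pytest

from covproj import (
    DegenerateError,
    fit_pls1,
    selectivity_ratio,
    signed_selectivity_ratio,
    standardize_vector,
    target_project,
    vip,
)
from covproj.target import SR_CAP, explained_y_fraction, importance_table

from .conftest import centered


def random_model(rng, n=50, m=6, A=3, noise=1.0):
    X = centered(rng, n, m)
    y = X @ rng.standard_normal(m) + noise * rng.standard_normal(n)
    y -= y.mean()
    return fit_pls1(X, y, A), X, y


class TestTargetProject:
    def test_single_component_model_identity(self, rng):
        model, X, y = random_model(rng, A=1)
        tp = target_project(model, X, y)
        # t_tp collinear with the single PLS score; identical predictions
        c = tp.t_tp @ model.T[:, 0] / np.linalg.norm(tp.t_tp) / np.linalg.norm(model.T[:, 0])
        assert abs(abs(c) - 1.0) < 1e-10
        np.testing.assert_allclose(tp.fitted(), model.fitted(), rtol=1e-8)

    def test_tp_preserves_pls_prediction(self, rng):
        for A in (1, 2, 4):
            model, X, y = random_model(rng, A=A)
            tp = target_project(model, X, y)
            yhat = X @ model.b
            assert np.abs(yhat - tp.fitted()).max() < 1e-8 * np.linalg.norm(yhat)

    def test_weight_is_unit_normalized_regression_vector(self, rng):
        model, X, y = random_model(rng)
        tp = target_project(model, X)
        assert abs(np.linalg.norm(tp.w_tp) - 1.0) < 1e-10
        np.testing.assert_allclose(tp.w_tp * tp.b_norm, model.b, rtol=1e-10)

    def test_explained_plus_residual_is_total_ss(self, rng):
        model, X, y = random_model(rng)
        tp = target_project(model, X)
        total = (X**2).sum(axis=0)
        np.testing.assert_allclose(
            tp.explained_x_ss + tp.residual_x_ss, total, rtol=1e-8
        )

    def test_explained_y_fraction_in_unit_interval(self, rng):
        model, X, y = random_model(rng)
        tp = target_project(model, X, y)
        assert 0.0 <= tp.explained_y_fraction <= 1.0
        assert tp.explained_y_fraction == pytest.approx(explained_y_fraction(tp, y))

    def test_zero_regression_vector_rejected(self, rng):
        model, X, _ = random_model(rng)
        model.b = np.zeros_like(model.b)
        with pytest.raises(DegenerateError):
            target_project(model, X)


class TestSelectivityRatio:
    def test_matches_brute_force_per_variable_regression(self, rng):
        model, X, y = random_model(rng, n=50, m=6, A=2)
        tp = target_project(model, X)
        sr = selectivity_ratio(tp)
        t = tp.t_tp
        for i in range(X.shape[1]):
            # independent oracle: simple regression of x_i on the TP score
            coef = float(t @ X[:, i]) / float(t @ t)
            expl = coef**2 * float(t @ t)
            resid = float(((X[:, i] - coef * t) ** 2).sum())
            assert sr[i] == pytest.approx(expl / resid, rel=1e-8)

    def test_orthogonal_variable_scores_zero(self, rng):
        t = rng.standard_normal(80)
        t -= t.mean()
        x_orth = rng.standard_normal(80)
        x_orth -= x_orth.mean()
        x_orth -= t * (t @ x_orth) / (t @ t)
        X = np.column_stack([t + 0.01 * rng.standard_normal(80), x_orth])
        X -= X.mean(axis=0)
        y = t - t.mean()
        model = fit_pls1(X, y, 1)
        tp = target_project(model, X)
        sr = selectivity_ratio(tp)
        assert sr[1] < 1e-3 * sr[0]

    def test_variable_equal_to_score_hits_cap(self, rng):
        t = standardize_vector(rng.standard_normal(60))
        X = np.column_stack([t, t])  # t_tp is exactly t; zero residual per column
        y = t
        model = fit_pls1(X, y, 1)
        tp = target_project(model, X)
        sr = selectivity_ratio(tp)
        assert sr[0] == SR_CAP and sr[1] == SR_CAP

    def test_sr_invariant_to_score_rescaling(self, rng):
        model, X, y = random_model(rng)
        tp = target_project(model, X)
        sr = selectivity_ratio(tp)
        scaled = target_project(model, X)
        scaled.t_tp = 5.0 * scaled.t_tp  # SR depends only on SS split
        np.testing.assert_allclose(selectivity_ratio(scaled), sr)

    def test_signed_variant_carries_loading_sign(self, rng):
        model, X, y = random_model(rng)
        tp = target_project(model, X)
        signed = signed_selectivity_ratio(tp)
        np.testing.assert_allclose(np.abs(signed), selectivity_ratio(tp))
        assert (np.sign(signed) == np.sign(tp.p_tp)).all()

    def test_noise_variables_vanish_at_large_n(self):
        rng = np.random.default_rng(77)
        n = 2000
        t = rng.standard_normal(n)
        X = np.column_stack(
            [np.outer(t, [1.0, 0.8, -0.6]) + 0.2 * rng.standard_normal((n, 3)),
             rng.standard_normal((n, 3))]
        )
        X -= X.mean(axis=0)
        y = t + 0.1 * rng.standard_normal(n)
        y -= y.mean()
        model = fit_pls1(X, y, 1)
        sr = selectivity_ratio(target_project(model, X))
        assert sr[3:].max() < 0.05


class TestVIP:
    def test_mean_squared_vip_is_one(self, rng):
        model, X, y = random_model(rng, m=8, A=4)
        v = vip(model)
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-10)

    def test_single_component_closed_form(self, rng):
        model, X, y = random_model(rng, A=1)
        m = X.shape[1]
        np.testing.assert_allclose(
            vip(model), np.abs(model.W[:, 0]) * np.sqrt(m), rtol=1e-10
        )

    def test_direct_formula_oracle(self, rng):
        model, X, y = random_model(rng, m=7, A=3)
        # independent evaluation of the standard VIP formula
        m, A = model.W.shape
        ssy = np.array(
            [model.q[a] ** 2 * model.T[:, a] @ model.T[:, a] for a in range(A)]
        )
        expected = np.array(
            [
                np.sqrt(
                    m
                    * sum(
                        ssy[a] * (model.W[i, a] / np.linalg.norm(model.W[:, a])) ** 2
                        for a in range(A)
                    )
                    / ssy.sum()
                )
                for i in range(m)
            ]
        )
        np.testing.assert_allclose(vip(model), expected, rtol=1e-10)


def test_importance_table_columns(rng):
    model, X, y = random_model(rng, m=4)
    tp = target_project(model, X)
    tbl = importance_table(model, tp, [f"v{i}" for i in range(4)])
    assert list(tbl.columns) == ["variable", "signed_sr", "sr", "vip", "p_tp", "w_tp"]
    assert len(tbl) == 4
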