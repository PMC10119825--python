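"""Shapley axioms, sampled-estimator convergence, global/dependence extractions."""

import numpy as np
import pandas as pd
import pytest

from ucflow import (
    ConfigurationError,
    dependence_interaction,
    global_importance,
    shapley_exact,
    shapley_sampled,
)


def linear_model(coefs):
    c = np.asarray(coefs, dtype=float)
    return lambda X: np.asarray(X, float) @ c


class TestExact:
    def test_linear_closed_form(self):
        """For linear f, phi_i = coef_i * (x_i - background mean_i)."""
        f = linear_model([2.0, 3.0])
        res = shapley_exact(f, np.array([1.0, 1.0]), np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(res.phi, [2.0, 3.0], atol=1e-10)
        assert res.base_value == pytest.approx(0.0)
        assert res.prediction == pytest.approx(5.0)

    def test_linear_closed_form_general_background(self):
        rng = np.random.default_rng(0)
        coefs = np.array([1.5, -2.0, 0.5, 4.0])
        bg = rng.normal(size=(30, 4))
        x = rng.normal(size=4)
        res = shapley_exact(linear_model(coefs), x, bg)
        np.testing.assert_allclose(res.phi, coefs * (x - bg.mean(axis=0)), atol=1e-8)

    def test_dummy_feature_gets_zero(self):
        f = lambda X: np.asarray(X)[:, 0] ** 2  # ignores feature 1
        rng = np.random.default_rng(1)
        res = shapley_exact(f, rng.normal(size=2), rng.normal(size=(20, 2)))
        assert abs(res.phi[1]) < 1e-12

    def test_null_contrast_instance_equals_background(self):
        f = lambda X: np.asarray(X).sum(axis=1) ** 2
        row = np.array([1.0, 2.0, 3.0])
        res = shapley_exact(f, row, row[None, :])
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-12)
        assert res.prediction == pytest.approx(res.base_value)

    def test_efficiency_on_nonlinear_model(self):
        rng = np.random.default_rng(2)
        f = lambda X: np.exp(0.1 * np.asarray(X)).sum(axis=1) * np.asarray(X)[:, 0]
        res = shapley_exact(f, rng.normal(size=5), rng.normal(size=(40, 5)))
        assert abs(res.base_value + res.phi.sum() - res.prediction) < 1e-8

    def test_symmetry_of_exchangeable_features(self):
        f = lambda X: (np.asarray(X)[:, 0] + np.asarray(X)[:, 1]) ** 2
        bg = np.random.default_rng(3).normal(size=(25, 2))
        bg[:, 1] = bg[:, 0]  # identical columns
        res = shapley_exact(f, np.array([1.7, 1.7]), bg)
        assert res.phi[0] == pytest.approx(res.phi[1], abs=1e-8)

    def test_linearity_of_attributions(self):
        rng = np.random.default_rng(4)
        f1 = lambda X: np.asarray(X)[:, 0] * np.asarray(X)[:, 1]
        f2 = lambda X: np.sin(np.asarray(X)[:, 2])
        f12 = lambda X: f1(X) + f2(X)
        x, bg = rng.normal(size=3), rng.normal(size=(15, 3))
        r1, r2, r12 = (shapley_exact(f, x, bg) for f in (f1, f2, f12))
        np.testing.assert_allclose(r12.phi, r1.phi + r2.phi, atol=1e-8)

    def test_feature_count_cap_redirects_to_sampler(self):
        f = lambda X: np.asarray(X).sum(axis=1)
        with pytest.raises(ConfigurationError, match="sampled"):
            shapley_exact(f, np.zeros(16), np.zeros((3, 16)))


class TestSampled:
    def test_agrees_with_exact_oracle_within_three_se(self):
        rng = np.random.default_rng(5)
        f = lambda X: (
            np.asarray(X)[:, 0] * np.asarray(X)[:, 1]
            + np.abs(np.asarray(X)[:, 2])
            + np.asarray(X)[:, 3:].sum(axis=1) ** 2
        )
        x, bg = rng.normal(size=6), rng.normal(size=(25, 6))
        exact = shapley_exact(f, x, bg)
        sampled = shapley_sampled(f, x, bg, n_permutations=2000, seed=0)
        err = np.abs(sampled.phi - exact.phi)
        # permutations are coupled across features; allow the efficiency-residual
        # share but demand every feature agree within 3 reported SEs
        assert (err <= 3 * sampled.standard_errors + 1e-9).all()

    def test_efficiency_enforced_exactly(self):
        rng = np.random.default_rng(6)
        f = lambda X: np.cos(np.asarray(X)).prod(axis=1)
        res = shapley_sampled(f, rng.normal(size=4), rng.normal(size=(10, 4)), seed=1)
        assert res.base_value + res.phi.sum() == pytest.approx(res.prediction, abs=1e-10)

    def test_se_scales_as_inverse_root_permutations(self):
        # needs an interaction model: for additive f the per-permutation
        # contributions are constant and the SE is identically ~0
        rng = np.random.default_rng(7)
        f = lambda X: np.asarray(X).sum(axis=1) ** 2
        x, bg = rng.normal(size=5), rng.normal(size=(15, 5))
        ratios = []
        for seed in (2, 3, 4):
            se_small = shapley_sampled(f, x, bg, n_permutations=200, seed=seed).standard_errors
            se_big = shapley_sampled(f, x, bg, n_permutations=400, seed=seed).standard_errors
            ratios.append(se_big.mean() / se_small.mean())
        assert 0.6 <= np.mean(ratios) <= 0.8  # ~ 1/sqrt(2)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        f = lambda X: np.asarray(X).sum(axis=1)
        x, bg = rng.normal(size=3), rng.normal(size=(8, 3))
        a = shapley_sampled(f, x, bg, n_permutations=50, seed=3)
        b = shapley_sampled(f, x, bg, n_permutations=50, seed=3)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_too_few_permutations_rejected(self):
        f = lambda X: np.asarray(X).sum(axis=1)
        with pytest.raises(ConfigurationError):
            shapley_sampled(f, np.zeros(2), np.zeros((2, 2)), n_permutations=5)


class TestGlobalImportance:
    def _attribs(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        f = linear_model([5.0, 1.0, 0.0])
        bg = rng.normal(size=(20, 3))
        return [shapley_exact(f, rng.normal(size=3), bg) for _ in range(n)]

    def test_ranking_by_mean_abs_phi(self):
        out = global_importance(self._attribs())
        assert out["feature"].iloc[0] == "x0"      # largest coefficient
        assert out["feature"].iloc[-1] == "x2"     # dummy feature ranks last
        assert out["mean_abs_phi"].iloc[-1] == pytest.approx(0.0, abs=1e-10)
        assert (np.diff(out["mean_abs_phi"]) <= 1e-12).all()

    def test_single_attribution_ranks_by_its_own_phi(self):
        a = self._attribs(n=1)
        out = global_importance(a)
        np.testing.assert_allclose(
            out["mean_abs_phi"].to_numpy(),
            sorted(np.abs(a[0].phi), reverse=True),
        )

    def test_summary_pairs_carried_per_feature(self):
        attribs = self._attribs(n=7)
        out = global_importance(attribs).set_index("feature")
        assert all(len(out.loc["x1", c]) == 7 for c in ("values", "phis"))


class TestDependence:
    def _product_attribs(self):
        f = lambda X: np.asarray(X)[:, 0] * np.asarray(X)[:, 1]
        bg = np.array([[s1, s2] for s1 in (-1.0, 1.0) for s2 in (-1.0, 1.0)])
        grid = [np.array([a, b]) for a in (-2.0, -1.0, 1.0, 2.0) for b in (-2.0, 1.0, 2.0)]
        return [shapley_exact(f, x, bg) for x in grid]

    def test_product_model_sign_tracks_interaction(self):
        rows = dependence_interaction(self._product_attribs(), "x0", "x1")
        for _, r in rows.iterrows():
            assert np.sign(r["phi_x"]) == np.sign(r["x_value"] * r["color_value"])

    def test_row_count_and_zero_line(self):
        attribs = self._product_attribs()
        rows = dependence_interaction(attribs, "x1", "x0")
        assert len(rows) == len(attribs)
        assert (rows["zero_line"] == 0.0).all()

    def test_unknown_feature_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            dependence_interaction(self._product_attribs(), "x9", "x0")


class TestPipelineAttribution:
    def test_voting_attribution_on_drift_scenario(self, drift_scenario):
        """During a level-4 episode the alert feature carries real attribution
        mass for the Voting model, and the additivity identity holds."""
        from ucflow import explain_date, reduced_bank

        series, panel = drift_scenario
        bank = reduced_bank(seed=0)
        res = explain_date(
            series, panel, bank, "2020-04-15", model_name="Voting",
            feature_set="all", method="sampled", n_background=40,
            n_permutations=80, seed=0,
        )
        assert res.base_value + res.phi.sum() == pytest.approx(res.prediction, abs=1e-8)
        frame = res.to_frame().set_index("feature")
        assert frame.loc["covid_level", "value"] == 4

    def test_alert_attribution_larger_under_drift_than_calm(self, drift_scenario):
        from ucflow import explain_date, reduced_bank

        series, panel = drift_scenario
        bank = reduced_bank(seed=0)

        def mean_abs_alert(dates):
            out = []
            for d in dates:
                res = explain_date(
                    series, panel, bank, d, model_name="Voting", feature_set="all",
                    method="sampled", n_background=30, n_permutations=60, seed=0,
                )
                out.append(abs(res.phi[res.feature_names.index("covid_level")]))
            return np.mean(out)

        drift_dates = ["2020-04-08", "2020-04-15", "2020-04-22"]
        calm_dates = ["2019-04-10", "2019-04-17", "2019-04-24"]
        assert mean_abs_alert(drift_dates) > mean_abs_alert(calm_dates)
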