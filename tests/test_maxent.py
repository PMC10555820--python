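"""Hinge features, the penalized Gibbs fit and its KKT certificate,
prediction scaling, contributions, importances and the a/b/c suite."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from hydrisk import maxent as mx


def _linear_map(x: pd.Series) -> mx.FeatureMap:
    lo, hi = float(x.min()), float(x.max())
    fm = mx.FeatureMap({x.name: (np.array([lo, hi]), lo, hi)}, {})
    fm._name_features()
    return fm


@pytest.fixture(scope="module")
def shifted():
    rng = np.random.default_rng(5)
    bg = pd.DataFrame({"x": rng.normal(size=800), "z": rng.normal(size=800)})
    pres = pd.DataFrame({"x": rng.normal(1.0, 0.7, 200), "z": rng.normal(size=200)})
    return pres, bg


class TestBuildFeatures:
    def test_forward_hinge_at_minimum_is_minmax_identity(self, rng):
        x = pd.DataFrame({"v": rng.uniform(2, 10, 50)})
        fm, F = mx.build_features(x, n_knots=5)
        knots, lo, hi = fm.continuous["v"]
        scaled = (x["v"] - lo) / (hi - lo)
        assert np.allclose(F[:, 0], scaled)

    def test_forward_hinge_zero_at_its_knot(self, rng):
        x = pd.DataFrame({"v": np.linspace(0, 1, 11)})
        fm, _ = mx.build_features(x, n_knots=6)
        knots, lo, hi = fm.continuous["v"]
        for i, k in enumerate(knots[:-1]):
            val = fm.transform(pd.DataFrame({"v": [k]}))[0, i]
            assert val == 0.0

    def test_features_bounded_in_unit_interval(self, shifted):
        pres, bg = shifted
        fm, F = mx.build_features(pd.concat([bg, pres]), n_knots=10)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_piecewise_linear_targets_exactly_representable(self, rng):
        x = rng.uniform(0, 1, 400)
        fm, F = mx.build_features(pd.DataFrame({"v": x}), n_knots=9)
        knots = fm.continuous["v"][0]
        # random piecewise-linear function with breakpoints on the knot grid
        node_vals = rng.normal(size=len(knots))
        target = np.interp(x, knots, node_vals)
        design = np.column_stack([F, np.ones(len(x))])
        resid = np.linalg.lstsq(design, target, rcond=None)[1]
        sse = resid[0] if len(resid) else np.sum(
            (design @ np.linalg.lstsq(design, target, rcond=None)[0] - target) ** 2
        )
        assert sse < 1e-16 * len(x)

    def test_constant_variable_excluded_with_warning(self):
        x = pd.DataFrame({"v": np.ones(10), "w": np.arange(10.0)})
        with pytest.warns(UserWarning, match="constant variable"):
            fm, _ = mx.build_features(x, n_knots=4)
        assert "v" not in fm.continuous

    def test_factor_levels_one_hot(self):
        x = pd.DataFrame({"f": ["a", "b", "a", "c"]})
        fm, F = mx.build_features(x, factors=["f"], n_knots=4)
        assert fm.factors["f"] == ["a", "b", "c"]
        assert np.array_equal(F.sum(axis=1), np.ones(4))


class TestFitPredict:
    def test_raw_predictions_sum_to_one_over_background(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-5)
        assert mx.predict_maxent(m, bg, "raw").sum() == pytest.approx(1.0, abs=1e-8)

    def test_uniform_model_raw_is_one_over_n(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-5)
        m.coefficients = np.zeros_like(m.coefficients)
        from scipy.special import logsumexp

        m.log_z = float(logsumexp(fm.transform(bg) @ m.coefficients))
        raw = mx.predict_maxent(m, bg, "raw")
        assert np.allclose(raw, 1.0 / len(bg))

    def test_cloglog_is_monotone_in_raw_with_identical_auc(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-5)
        raw = mx.predict_maxent(m, bg, "raw")
        clog = mx.predict_maxent(m, bg, "cloglog")
        order = np.argsort(raw)
        assert (np.diff(clog[order]) >= -1e-15).all()
        assert ((clog > 0) & (clog < 1)).all()
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        s_raw = np.r_[mx.predict_maxent(m, pres, "raw"), raw]
        s_clog = np.r_[mx.predict_maxent(m, pres, "cloglog"), clog]
        assert roc_auc_score(y, s_raw) == pytest.approx(roc_auc_score(y, s_clog))

    def test_kkt_constraint_at_zero_regularization(self, shifted):
        pres, bg = shifted
        fm = _linear_map(bg["x"])
        m = mx.fit_maxent(pres[["x"]], bg[["x"]], fm, reg_multiplier=0.0, tol=1e-7)
        F = fm.transform(bg[["x"]])
        q = np.exp(F @ m.coefficients - m.log_z)
        for j in range(F.shape[1]):
            assert (q * F[:, j]).sum() == pytest.approx(
                fm.transform(pres[["x"]])[:, j].mean(), abs=1e-4
            )

    def test_zero_reg_linear_feature_matches_weighted_logistic(self, shifted):
        # the maxent solution coincides with logistic regression in which
        # background carries infinite weight; with the affinely dependent
        # forward/reverse pair the net slope is lambda_fwd - lambda_rev
        import statsmodels.api as sm

        pres, bg = shifted
        fm = _linear_map(bg["x"])
        m = mx.fit_maxent(pres[["x"]], bg[["x"]], fm, reg_multiplier=0.0, tol=1e-8,
                          max_iter=100000)
        f = np.r_[fm.transform(pres[["x"]])[:, 0], fm.transform(bg[["x"]])[:, 0]]
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        w = np.r_[np.ones(len(pres)), np.full(len(bg), 1e7)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.GLM(
                y, sm.add_constant(f), family=sm.families.Binomial(), freq_weights=w
            ).fit()
        net = m.coefficients[0] - m.coefficients[1]
        assert net == pytest.approx(ref.params[1], abs=1e-3)

    def test_null_presences_shrink_to_near_zero_gain(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({"x": rng.normal(size=2000)})
        pres = bg.iloc[rng.choice(2000, 500, replace=False)]
        fm, _ = mx.build_features(bg, n_knots=10)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-5)
        assert m.training_gain <= 0.05
        assert np.abs(m.coefficients).max() < 1.0

    def test_gain_monotone_in_regularization_and_vanishes(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        gains = [
            mx.fit_maxent(pres, bg, fm, reg_multiplier=r, tol=1e-5).training_gain
            for r in (1.0, 10.0, 1000.0)
        ]
        assert gains[0] >= gains[1] >= gains[2]
        m_inf = mx.fit_maxent(pres, bg, fm, reg_multiplier=1000.0, tol=1e-5)
        assert np.allclose(m_inf.coefficients, 0.0, atol=1e-6)
        assert abs(m_inf.training_gain) < 1e-6

    def test_kkt_certificate_on_converged_fit(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=6)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-6)
        assert m.converged
        Fp, Fb = fm.transform(pres), fm.transform(bg)
        g = mx._grad_smooth(m.coefficients, Fp.mean(axis=0), Fb)
        viol = np.where(
            m.coefficients == 0.0,
            np.maximum(np.abs(g) - m.reg_weights, 0.0),
            np.abs(g + m.reg_weights * np.sign(m.coefficients)),
        )
        assert viol.max() <= 1e-6 * 1.01

    def test_non_finite_features_rejected(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=5)
        bad = pres.copy()
        bad.loc[bad.index[0], "x"] = np.nan
        with pytest.raises(ValueError):
            mx.fit_maxent(bad, bg, fm)


class TestScreeningAndImportance:
    def test_duplicated_variable_dropped(self, shifted):
        pres, bg = shifted
        pres2 = pres.assign(x2=pres["x"])
        bg2 = bg.assign(x2=bg["x"])
        kept = mx.select_uncorrelated_vars(pres2, bg2, ["x", "x2", "z"])
        assert "z" in kept
        assert sum(v in kept for v in ("x", "x2")) == 1

    def test_uncorrelated_set_fully_kept_and_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        bg = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        pres = pd.DataFrame(rng.normal(0.5, 1, (100, 3)), columns=["a", "b", "c"])
        kept = mx.select_uncorrelated_vars(pres, bg, ["a", "b", "c"], threshold=0.75)
        assert set(kept) == {"a", "b", "c"}
        pooled = pd.concat([pres, bg])
        for i, u in enumerate(kept):
            for v in kept[i + 1:]:
                assert abs(np.corrcoef(pooled[u], pooled[v])[0, 1]) < 0.75

    def test_single_variable_contribution_is_100(self, shifted):
        pres, bg = shifted
        out = mx.jackknife_contribution(pres[["x"]], bg[["x"]], n_knots=8)
        assert out.sum() == pytest.approx(100.0)
        assert out["x"] == pytest.approx(100.0)

    def test_contributions_sum_to_100_and_informative_variable_dominates(self, shifted):
        pres, bg = shifted
        out = mx.jackknife_contribution(pres, bg, n_knots=8)
        assert out.sum() == pytest.approx(100.0)
        assert out["x"] > out["z"]
        assert out["z"] < 15.0  # z is independent of presence

    def test_permutation_importance_zero_for_unused_variable(self, shifted):
        pres, bg = shifted
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-5)
        # zero out every coefficient belonging to z
        owner = np.array(fm.feature_variable)
        m.coefficients[owner == "z"] = 0.0
        out = mx.permutation_importance(m, pres, bg, seed=0)
        assert out["z"] == pytest.approx(0.0, abs=1e-9)
        assert out.sum() == pytest.approx(100.0)
        assert out["x"] > out["z"]


class TestEvaluateRepeated:
    def test_split_counts_and_determinism(self, shifted):
        pres, bg = shifted
        out1 = mx.evaluate_repeated(pres, bg, reps=4, seed=3, n_knots=6, tol=1e-3)
        out2 = mx.evaluate_repeated(pres, bg, reps=4, seed=3, n_knots=6, tol=1e-3)
        assert out1 == out2
        assert out1["reps_done"] == 4

    def test_no_overfitting_on_self_generated_data(self, shifted):
        pres, bg = shifted
        out = mx.evaluate_repeated(pres, bg, reps=6, seed=4, n_knots=8, tol=1e-4)
        fm, _ = mx.build_features(pd.concat([bg, pres]), n_knots=8)
        m = mx.fit_maxent(pres, bg, fm, tol=1e-4)
        train = mx.training_auc(m, pres, bg)
        assert abs(out["auc_mean"] - train) < 0.05

    def test_too_few_presences_rejected(self, shifted):
        _, bg = shifted
        with pytest.raises(ValueError):
            mx.evaluate_repeated(bg.head(3), bg, reps=2)


class TestModelSuite:
    @pytest.fixture(scope="class")
    def suite(self, world):
        table = world.assemblage.flat_table()
        table["biome"] = world.biome.ravel().astype(str)
        table["pft"] = world.pft.ravel().astype(str)
        for i, name in enumerate(world.env.names):
            table[name] = world.env.flat()[i]
        table = table.dropna(subset=["n_hsm_neg", "var_hsm"])
        pres_cells = np.unique(world.mortality["cell"])
        pres_cells = pres_cells[np.isin(pres_cells, table.index)]
        rng = np.random.default_rng(0)
        bg_cells = rng.choice(
            table.index.difference(pres_cells), size=400, replace=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mx.run_model_suite(
                table.loc[pres_cells], table.loc[bg_cells],
                factor_vars=["biome", "pft"],
                continuous_vars=["env1", "env2", "env3", "env4"],
                hydraulic_vars=["n_hsm_neg", "var_hsm"],
                reps=5, seed=1, n_knots=8, tol=1e-3,
            )

    def test_three_models_with_equal_b_c_predictor_counts(self, suite):
        assert all(k in suite for k in ("a", "b", "c"))
        assert len(suite["variables"]["b"]) == len(suite["variables"]["c"])
        assert set(suite["replaced"]) <= {"env1", "env2", "env3", "env4"}

    def test_type_c_swaps_lowest_contribution_continuous_for_hydraulics(self, suite):
        b_vars = suite["variables"]["b"]
        c_vars = suite["variables"]["c"]
        assert set(c_vars) == (set(b_vars) - set(suite["replaced"])) | {
            "n_hsm_neg", "var_hsm"
        }

    def test_hydraulics_informed_model_not_worse_than_factors_only(self, suite):
        assert suite["c"]["test_auc_mean"] >= suite["a"]["test_auc_mean"] - 0.02

    def test_missing_layer_rejected(self, world):
        table = world.assemblage.flat_table()
        with pytest.raises(KeyError, match="missing"):
            mx.run_model_suite(
                table.head(10), table.tail(10),
                factor_vars=[], continuous_vars=["nope"],
                hydraulic_vars=["n_hsm_neg", "var_hsm"],
            )
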