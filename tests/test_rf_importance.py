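import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from microstab import (
    PredictorInputs,
    assemble_predictors,
    permutation_importance,
    tune_and_fit,
)
from microstab._util import substream_rng
from microstab.rf_importance import _oob_masks, oob_mse


def _inputs(n=24, seed=0, genus=False):
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n)]
    diversity = pd.DataFrame(
        {"richness": rng.uniform(50, 400, n), "shannon": rng.uniform(1, 5, n)}, index=ids
    )
    ordination = pd.DataFrame(
        rng.normal(size=(n, 4)), index=ids, columns=["PCoA1", "PCoA2", "PCoA3", "PCoA4"]
    )
    comp = pd.DataFrame(
        {"mean_operon_number": rng.uniform(1, 6, n), "proteo_actino_ratio": rng.lognormal(0, 1, n)},
        index=ids,
    )
    if genus:
        comp["genus_Pseudomonas"] = rng.uniform(0, 0.2, n)
        comp["genus_Bacillus"] = rng.uniform(0, 0.2, n)
    cov = pd.DataFrame(
        {
            "biomass": rng.lognormal(5, 0.3, n),
            "dna_yield": rng.lognormal(1, 0.3, n),
            "abund_16s": rng.lognormal(14, 0.4, n),
            "tetw": rng.lognormal(6, 1, n),
            "tetm": rng.lognormal(5, 1, n),
            "aoa": rng.lognormal(10, 0.5, n),
            "aob": rng.lognormal(9, 0.5, n),
        },
        index=ids,
    )
    return PredictorInputs(diversity=diversity, ordination=ordination, composition=comp, covariates=cov)


class TestAssemblePredictors:
    def test_nitrifiers_only_for_nitrification(self):
        inputs = _inputs()
        y = pd.Series(np.arange(24, dtype=float), index=inputs.diversity.index)
        x_nit, _ = assemble_predictors(inputs, "nitrification", y)
        x_cmin, _ = assemble_predictors(inputs, "c_mineralization", y)
        assert {"aoa", "aob"} <= set(x_nit.columns)
        assert not {"aoa", "aob"} & set(x_cmin.columns)

    def test_axis_count_respected(self):
        inputs = _inputs()
        y = pd.Series(np.arange(24, dtype=float), index=inputs.diversity.index)
        x, _ = assemble_predictors(inputs, "sir", y, n_axes=3)
        assert "PCoA3" in x.columns and "PCoA4" not in x.columns

    def test_constant_column_dropped_with_warning(self):
        inputs = _inputs()
        inputs.covariates["tetw"] = 5.0
        y = pd.Series(np.arange(24, dtype=float), index=inputs.diversity.index)
        with pytest.warns(UserWarning, match="tetw"):
            x, _ = assemble_predictors(inputs, "sir", y)
        assert "tetw" not in x.columns

    def test_alternative_variant_appends_genus_columns(self):
        inputs = _inputs(genus=True)
        y = pd.Series(np.arange(24, dtype=float), index=inputs.diversity.index)
        x, _ = assemble_predictors(inputs, "sir", y, variant="alternative")
        assert "genus_Pseudomonas" in x.columns

    def test_too_few_complete_rows_errors(self):
        inputs = _inputs(n=12)
        y = pd.Series(np.nan, index=inputs.diversity.index)
        y.iloc[:5] = 1.0
        with pytest.raises(ValueError, match="complete rows"):
            assemble_predictors(inputs, "sir", y)


class TestOobMachinery:
    def test_oob_predictions_match_sklearn(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(35, 3)).astype(np.float32)
        y = X[:, 0] * 2 + rng.normal(0, 0.2, 35)
        model = RandomForestRegressor(
            n_estimators=60, oob_score=True, random_state=3, n_jobs=1
        ).fit(X, y)
        ours = oob_mse(model, X, y)
        theirs = float(np.mean((model.oob_prediction_ - y) ** 2))
        assert ours == pytest.approx(theirs, rel=1e-12)


class TestTuneAndFit:
    def test_single_predictor_trivial_grid(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        y = pd.Series(X["x"] * 2 + rng.normal(0, 0.1, 30))
        model, trace = tune_and_fit(X, y, n_trees=100, seed=0)
        assert trace["max_features"].tolist() == [1]
        assert model.tuned_max_features_ == 1

    def test_deterministic_trace(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = pd.Series(X["a"] + rng.normal(0, 0.5, 30))
        _, t1 = tune_and_fit(X, y, n_trees=100, seed=5)
        _, t2 = tune_and_fit(X, y, n_trees=100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_strong_signal_high_oob_r2(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = pd.Series(3 * X["a"] + rng.normal(0, 0.1, 200))
        model, trace = tune_and_fit(X, y, n_trees=300, seed=0)
        r2 = 1 - trace["oob_mse"].min() / np.var(y)
        assert r2 > 0.8

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        with pytest.raises(ValueError, match="constant"):
            tune_and_fit(X, pd.Series(np.ones(30)), n_trees=100)


class TestPermutationImportance:
    def _fit(self, n=60, seed=0, trees=150):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["signal", "noise1", "noise2"])
        y = pd.Series(2.0 * X["signal"] + rng.normal(0, 0.3, n))
        model = RandomForestRegressor(n_estimators=trees, random_state=seed, n_jobs=1).fit(
            X.to_numpy(np.float32), y
        )
        return model, X, y

    def test_planted_signal_ranked_first(self):
        wins = 0
        for seed in range(5):
            model, X, y = self._fit(seed=seed)
            res = permutation_importance(model, X, y, n_shuffles=5, seed=seed)
            wins += res.table.index[0] == "signal"
        assert wins >= 4

    def test_pure_noise_importance_near_zero(self):
        model, X, y = self._fit(seed=1)
        res = permutation_importance(model, X, y, n_shuffles=10, seed=1)
        signal_imp = res.table.loc["signal", "raw_importance"]
        for col in ("noise1", "noise2"):
            assert abs(res.table.loc[col, "raw_importance"]) < 0.15 * signal_imp

    def test_deterministic(self):
        model, X, y = self._fit(seed=2)
        a = permutation_importance(model, X, y, n_shuffles=1, seed=9).table
        b = permutation_importance(model, X, y, n_shuffles=1, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_ranks_are_permutation_and_clamping(self):
        model, X, y = self._fit(seed=3)
        res = permutation_importance(model, X, y, n_shuffles=5, seed=3)
        assert sorted(res.table["rank"]) == [1, 2, 3]
        assert (res.table["importance"] >= 0).all()

    def test_importance_invariant_to_affine_predictor_rescaling(self):
        _, X, y = self._fit(seed=4)
        X2 = X.copy()
        X2["noise1"] = X2["noise1"] * 1000.0 + 5.0
        m1 = RandomForestRegressor(n_estimators=100, random_state=0, n_jobs=1).fit(
            X.to_numpy(np.float32), y
        )
        m2 = RandomForestRegressor(n_estimators=100, random_state=0, n_jobs=1).fit(
            X2.to_numpy(np.float32), y
        )
        r1 = permutation_importance(m1, X, y, n_shuffles=3, seed=0).table
        r2 = permutation_importance(m2, X2, y, n_shuffles=3, seed=0).table
        assert np.allclose(
            r1["raw_importance"], r2["raw_importance"], rtol=1e-4, atol=1e-8
        )

    def test_matches_from_scratch_oracle_on_tiny_instance(self):
        """Cross-check against an independent OOB bookkeeping route."""
        from sklearn.ensemble._forest import _generate_unsampled_indices

        model, X, y = self._fit(n=30, seed=5, trees=10)
        xv = X.to_numpy(np.float32)
        yv = y.to_numpy()
        n = len(yv)

        def oracle_mse(xmat):
            acc = np.zeros(n)
            cnt = np.zeros(n)
            for tree in model.estimators_:
                oob_idx = _generate_unsampled_indices(tree.random_state, n, n, None)
                acc[oob_idx] += tree.predict(xmat[oob_idx])
                cnt[oob_idx] += 1
            ok = cnt > 0
            return float(np.mean((acc[ok] / cnt[ok] - yv[ok]) ** 2))

        baseline = oracle_mse(xv)
        expected = {}
        for j, col in enumerate(X.columns):
            deltas = []
            for k in range(2):
                rng = substream_rng(7, "shuffle", col, k)
                xp = xv.copy()
                xp[:, j] = xp[rng.permutation(n), j]
                deltas.append(oracle_mse(xp) - baseline)
            expected[col] = np.mean(deltas)
        res = permutation_importance(model, X, y, n_shuffles=2, seed=7)
        for col in X.columns:
            assert res.table.loc[col, "raw_importance"] == pytest.approx(expected[col], rel=1e-10)
        assert res.oob_mse == pytest.approx(baseline, rel=1e-10)
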