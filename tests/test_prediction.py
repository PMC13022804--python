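"""Train/test protocol, random-forest skill, KGE and annual reconstruction."""

import numpy as np
import pandas as pd
import pytest

from riverghg import prediction as pr
from riverghg import synthetic_data as sd


class TestSplit:
    @pytest.mark.parametrize(("n", "expected_train"), [(1000, 700), (10, 7)])
    def test_split_sizes(self, n, expected_train):
        table = pd.DataFrame({"x": np.arange(n)})
        spec = pr.ModelSpec("x", log_transform=False)
        train, test = pr.split_train_test(table, spec)
        assert len(train) == expected_train and len(test) == n - expected_train

    def test_split_reproducible_and_disjoint(self):
        table = pd.DataFrame({"x": np.arange(100)})
        spec = pr.ModelSpec("x", log_transform=False, seed=7)
        t1, s1 = pr.split_train_test(table, spec)
        t2, s2 = pr.split_train_test(table, spec)
        assert t1.index.equals(t2.index) and s1.index.equals(s2.index)
        assert set(t1.index).isdisjoint(s1.index)
        assert len(t1) + len(s1) == len(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pr.split_train_test(pd.DataFrame(), pr.ModelSpec("x", log_transform=False))


class TestKge:
    def test_perfect_agreement(self):
        assert pr.kge([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_hand_computed_bias_only_case(self):
        # r = 1, alpha = 1, beta = 3/2 -> 1 - sqrt(0.25) = 0.5
        assert pr.kge([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(0.5)

    def test_anticorrelated_is_strongly_negative(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert pr.kge(obs, -obs) <= 1.0 - 2.0

    def test_constant_observations_undefined(self):
        with pytest.raises(ValueError):
            pr.kge([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_constant_prediction_is_defined(self):
        obs = np.array([1.0, 2.0, 3.0])
        score = pr.kge(obs, np.full(3, obs.mean()))
        assert score == pytest.approx(1.0 - np.sqrt(2.0))


def _single_predictor_scenario(noise, seed, n_catchments=30):
    specs = sd.default_response_specs()
    specs["CO2_sat"] = sd.ResponseSpec(
        1.0, {"NDVI": 3.0}, log=True, noise_sd=noise, site_sd=0.0
    )
    cfg = sd.ScenarioConfig(
        n_catchments=n_catchments, timestep_days=24, seed=seed, response_specs=specs
    )
    return sd.generate_scenario(cfg)


class TestTuneAndTrain:
    SPEC = dict(n_estimators=40, mtry_grid_size=3, cv_folds=3, seed=142)

    def test_noiseless_single_predictor_is_learned(self):
        scenario = _single_predictor_scenario(noise=0.0, seed=21)
        camp = sd.sample_field_campaign(scenario, "sparse-field", seed=21, fraction=0.15)
        spec = pr.ModelSpec("CO2_sat", **self.SPEC)
        train, test = pr.split_train_test(camp, spec)
        model = pr.tune_and_train(train, spec)
        report = pr.evaluate(model, test)
        assert report.r2_test > 0.95

    def test_pure_noise_response_has_no_skill(self):
        specs = sd.default_response_specs()
        specs["CO2_sat"] = sd.ResponseSpec(5.0, {}, log=True, noise_sd=0.5, site_sd=0.0)
        cfg = sd.ScenarioConfig(n_catchments=40, timestep_days=24, seed=22, response_specs=specs)
        camp = sd.sample_field_campaign(
            sd.generate_scenario(cfg), "sparse-field", seed=22, fraction=0.35
        )
        assert len(camp) >= 2000
        spec = pr.ModelSpec("CO2_sat", **self.SPEC)
        train, test = pr.split_train_test(camp, spec)
        report = pr.evaluate(pr.tune_and_train(train, spec), test)
        assert report.r2_test < 0.1

    def test_log_backtransform_is_strictly_positive(self):
        scenario = _single_predictor_scenario(noise=0.3, seed=23, n_catchments=10)
        camp = sd.sample_field_campaign(scenario, "sparse-field", seed=23, fraction=0.2)
        spec = pr.ModelSpec("CO2_sat", **self.SPEC)
        train, test = pr.split_train_test(camp, spec)
        model = pr.tune_and_train(train, spec)
        assert (model.predict(test) > 0).all()

    def test_mtry_chosen_from_grid(self):
        scenario = _single_predictor_scenario(noise=0.2, seed=24, n_catchments=10)
        camp = sd.sample_field_campaign(scenario, "sparse-field", seed=24, fraction=0.1)
        spec = pr.ModelSpec("CO2_sat", **self.SPEC)
        model = pr.tune_and_train(camp, spec)
        grid = pr._mtry_grid(len(spec.features), spec.mtry_grid_size)
        assert model.mtry in grid

    def test_too_few_rows_rejected(self):
        table = pd.DataFrame({c: [1.0, 2.0] for c in pr.DEFAULT_FEATURES} | {"y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            pr.tune_and_train(table, pr.ModelSpec("y", log_transform=False, cv_folds=10))

    def test_nonnumeric_response_rejected(self):
        table = pd.DataFrame(
            {c: np.ones(20) for c in pr.DEFAULT_FEATURES} | {"y": ["a"] * 20}
        )
        with pytest.raises(ValueError):
            pr.tune_and_train(table, pr.ModelSpec("y", log_transform=False, cv_folds=3))


class _StubEstimator:
    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, x):
        return self.values[: len(x)]


def _stub_model(values, response="y", log=False):
    spec = pr.ModelSpec(response, log_transform=log, cv_folds=2)
    spec.features = ["x"]
    return pr.FittedModel(spec=spec, estimator=_StubEstimator(values), mtry=1, features=["x"])


class TestEvaluate:
    def test_perfect_predictions(self):
        test = pd.DataFrame({"x": [0, 1, 2, 3], "y": [1.0, 2.0, 3.0, 4.0],
                             "catchment_id": ["a", "a", "b", "b"]})
        report = pr.evaluate(_stub_model([1.0, 2.0, 3.0, 4.0]), test)
        assert report.mae_test == 0.0
        assert report.r2_test == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in report.kge_per_site.values())

    def test_mae_percent_arithmetic(self):
        test = pd.DataFrame({"x": [0, 1], "y": [9.5, 10.5]})
        report = pr.evaluate(_stub_model([10.0, 10.0]), test)
        assert report.mae_test == pytest.approx(0.5)
        assert report.mae_pct_of_mean == pytest.approx(5.0)

    def test_mean_predictor_has_no_explanatory_power(self):
        y = np.array([1.0, 4.0, 2.0, 5.0])
        test = pd.DataFrame({"x": np.arange(4), "y": y})
        report = pr.evaluate(_stub_model(np.full(4, y.mean())), test)
        assert report.r2_test <= 0.0

    def test_sites_with_single_observation_skipped(self):
        test = pd.DataFrame({"x": [0, 1, 2], "y": [1.0, 2.0, 3.0],
                             "catchment_id": ["a", "a", "b"]})
        report = pr.evaluate(_stub_model([1.0, 2.0, 3.0]), test)
        assert set(report.kge_per_site) == {"a"}

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            pr.evaluate(_stub_model([]), pd.DataFrame(columns=["x", "y"]))


class TestReconstructAnnual:
    def test_cardinality_and_positivity(self, small_scenario):
        ann = sd.annual_means(small_scenario)
        model = _stub_model(np.zeros(len(ann)), response="CO2_sat", log=True)
        model.features = ["NDVI"]
        out = pr.reconstruct_annual({"CO2_sat": model}, ann, (2002, 2022))
        n_years = small_scenario.config.year_end - small_scenario.config.year_start + 1
        assert len(out) == small_scenario.config.n_catchments * n_years
        assert (out["value"] > 0).all()  # exp back-transform

    def test_missing_predictors_reported(self, small_scenario):
        ann = sd.annual_means(small_scenario).drop(columns=["NDVI"])
        model = _stub_model(np.zeros(len(ann)), response="CO2_sat", log=True)
        model.features = ["NDVI"]
        with pytest.raises(ValueError, match="NDVI"):
            pr.reconstruct_annual({"CO2_sat": model}, ann)

    def test_constant_predictors_give_constant_predictions(self):
        ann = pd.DataFrame(
            {
                "catchment_id": ["a"] * 3,
                "year": [2002, 2003, 2004],
                "x": [1.0, 1.0, 1.0],
            }
        )
        model = _stub_model(np.full(3, 2.5), response="r", log=False)
        out = pr.reconstruct_annual({"r": model}, ann)
        assert out["value"].nunique() == 1
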