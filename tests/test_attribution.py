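"""Driver preparation, per-catchment elastic net and coefficient averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from riverghg import attribution as at
from riverghg import synthetic_data as sd


def _panel(beta, n_catchments=10, noise=0.1, seed=0, n_years=21):
    return sd.generate_driver_panel(n_catchments, beta, n_years=n_years, noise_sd=noise, seed=seed)


class TestPrepareDrivers:
    def test_standardized_within_catchment(self):
        panel, _ = _panel({"water_temperature": 1.0, "DOC": 0.5}, n_catchments=4)
        mats = at.prepare_drivers(
            panel, "response", drivers=["water_temperature", "DOC"], freeze_landuse_after=None
        )
        for m in mats:
            np.testing.assert_allclose(m.x.mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(m.x.std(ddof=0), 1.0, atol=1e-9)

    def test_din_don_derived_from_nutrients(self):
        years = np.arange(2002, 2012)
        frame = pd.DataFrame(
            {
                "catchment_id": "a",
                "year": years,
                "NH4": 0.1 + 0.01 * np.arange(10),
                "NO3": 0.4,
                "TN": 1.0,
                "DOC": 5.0,
                "water_temperature": np.linspace(10, 12, 10),
                "cropland_pct": np.linspace(10, 11, 10),
                "urban_pct": np.linspace(1, 2, 10),
                "precipitation": np.linspace(2, 3, 10),
                "DO": np.linspace(8, 9, 10),
                "CO2_sat": np.linspace(300, 400, 10),
            }
        )
        mats = at.prepare_drivers(frame, "CO2_sat", freeze_landuse_after=None)
        assert len(mats) == 1
        derived = frame["TN"] - (frame["NH4"] + frame["NO3"])
        # the standardized DON column reflects TN - DIN row-wise
        z = (derived - derived.mean()) / derived.std(ddof=0)
        np.testing.assert_allclose(mats[0].x["DON"].to_numpy(), z, atol=1e-9)

    def test_missing_years_dropped_and_counted(self):
        panel, _ = _panel({"a": 1.0}, n_catchments=2, n_years=15)
        panel.loc[panel.index[:3], "response"] = np.nan
        mats = at.prepare_drivers(panel, "response", drivers=["a"], freeze_landuse_after=None)
        assert mats[0].n_dropped_years == 3
        assert len(mats[0].y) == 12

    def test_short_catchments_excluded(self):
        panel, _ = _panel({"a": 1.0}, n_catchments=3, n_years=5)
        mats = at.prepare_drivers(panel, "response", drivers=["a"], min_years=8,
                                  freeze_landuse_after=None)
        assert mats == []

    def test_landuse_frozen_after_record_end(self):
        years = np.arange(2002, 2023)
        frame = pd.DataFrame(
            {
                "catchment_id": "a",
                "year": years,
                "cropland_pct": np.linspace(10, 30, 21),
                "response": np.linspace(0, 1, 21),
            }
        )
        mats = at.prepare_drivers(frame, "response", drivers=["cropland_pct"])
        raw = frame.copy()
        frozen_value = raw.loc[raw["year"] == 2019, "cropland_pct"].iloc[0]
        raw.loc[raw["year"] > 2019, "cropland_pct"] = frozen_value
        z = (raw["cropland_pct"] - raw["cropland_pct"].mean()) / raw["cropland_pct"].std(ddof=0)
        np.testing.assert_allclose(mats[0].x["cropland_pct"].to_numpy(), z, atol=1e-9)


def _enet_objective(coef, x, y, alpha, l1_ratio):
    resid = y - x @ coef
    n = len(y)
    return (
        resid @ resid / (2 * n)
        + alpha * l1_ratio * np.abs(coef).sum()
        + 0.5 * alpha * (1 - l1_ratio) * coef @ coef
    )


class TestElasticNetFit:
    def test_known_effect_recovered_at_low_noise(self):
        panel, _ = _panel({"water_temperature": 2.0, "DOC": 0.0, "DO": 0.0}, noise=0.01, seed=3)
        mats = at.prepare_drivers(
            panel, "response", drivers=["water_temperature", "DOC", "DO"],
            freeze_landuse_after=None,
        )
        coefs, r2 = at.fit_catchment_elastic_net(mats[0], at.ElasticNetConfig(seed=3))
        assert coefs["water_temperature"] == pytest.approx(2.0, abs=0.05)
        assert abs(coefs["DOC"]) < 0.05 and abs(coefs["DO"]) < 0.05
        assert r2 > 0.99

    def test_pure_noise_shrunk_to_near_zero(self):
        panel, _ = _panel({"a": 0.0, "b": 0.0, "c": 0.0}, noise=1.0, seed=4)
        mats = at.prepare_drivers(panel, "response", drivers=["a", "b", "c"],
                                  freeze_landuse_after=None)
        coefs, _ = at.fit_catchment_elastic_net(mats[0], at.ElasticNetConfig(seed=4))
        assert coefs.abs().max() < 0.5

    def test_constant_response_returns_zero_vector(self):
        panel, _ = _panel({"a": 1.0}, n_catchments=2, noise=0.0, seed=5)
        panel["response"] = 3.14
        mats = at.prepare_drivers(panel, "response", drivers=["a"], freeze_landuse_after=None)
        coefs, r2 = at.fit_catchment_elastic_net(mats[0])
        assert (coefs == 0.0).all() and r2 == 0.0

    def test_matches_bruteforce_solver_at_fixed_penalty(self):
        """Dual route: sklearn's coordinate descent vs direct minimization."""
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(6)
        x = rng.standard_normal((40, 3))
        x = (x - x.mean(0)) / x.std(0)
        y = x @ np.array([1.0, -0.5, 0.0]) + rng.normal(0, 0.2, 40)
        alpha, l1_ratio = 0.1, 0.5
        skl = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True, max_iter=50000)
        skl.fit(x, y)
        res = optimize.minimize(
            _enet_objective,
            np.zeros(3),
            args=(x, y - y.mean(), alpha, l1_ratio),
            method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 20000},
        )
        np.testing.assert_allclose(skl.coef_, res.x, atol=2e-4)

    def test_coefficients_vanish_at_infinite_penalty_and_shrink_monotonically(self):
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 3))
        y = x @ np.array([1.0, 0.5, -0.8]) + rng.normal(0, 0.1, 30)
        norms = []
        for alpha in [1e-4, 1e-2, 0.1, 1.0, 100.0]:
            m = ElasticNet(alpha=alpha, l1_ratio=0.5, max_iter=50000).fit(x, y)
            norms.append(np.abs(m.coef_).sum())
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] == 0.0

    def test_duplicated_predictor_shares_coefficient_mass(self):
        """Grouping property at a fixed moderate penalty: duplicated columns
        receive equal coefficients whose sum tracks the single-column fit."""
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(8)
        x = rng.standard_normal((60, 2))
        x = (x - x.mean(0)) / x.std(0)
        y = x @ np.array([1.0, -0.4]) + rng.normal(0, 0.05, 60)
        single = ElasticNet(alpha=0.1, l1_ratio=0.5, max_iter=50000).fit(x, y)
        x_dup = np.column_stack([x[:, 0], x[:, 0], x[:, 1]])
        dup = ElasticNet(alpha=0.1, l1_ratio=0.5, max_iter=50000).fit(x_dup, y)
        assert dup.coef_[0] == pytest.approx(dup.coef_[1], abs=5e-3)
        assert dup.coef_[0] + dup.coef_[1] == pytest.approx(single.coef_[0], rel=0.15)


class TestAverageCoefficients:
    def test_mean_and_se(self):
        vecs = [
            pd.Series({"wt": 1.0}, name="a"),
            pd.Series({"wt": 3.0}, name="b"),
        ]
        eff = at.average_coefficients(vecs, r2s=[0.5, 0.7])
        row = eff.table.iloc[0]
        assert row["mean_coef"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(1.0)
        assert eff.mean_r2 == pytest.approx(0.6)

    def test_identical_vectors_zero_se(self):
        vecs = [pd.Series({"wt": 1.5}, name=str(i)) for i in range(5)]
        assert at.average_coefficients(vecs).table["se"].iloc[0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            at.average_coefficients([])

    def test_mismatched_predictor_sets_rejected(self):
        vecs = [pd.Series({"wt": 1.0}, name="a"), pd.Series({"doc": 1.0}, name="b")]
        with pytest.raises(ValueError):
            at.average_coefficients(vecs)

    def test_climate_dominance_recovered(self):
        """Imposed WT effect > land-use effect shows up in the averaged ranking."""
        beta = {"water_temperature": 0.8, "cropland_pct": 0.2, "urban_pct": 0.1}
        panel, _ = _panel(beta, n_catchments=15, noise=0.2, seed=9)
        eff = at.attribute(
            panel,
            "response",
            at.ElasticNetConfig(seed=9),
            drivers=list(beta),
            freeze_landuse_after=None,
        )
        table = eff.table.set_index("predictor")["mean_coef"].abs()
        assert table["water_temperature"] > table["cropland_pct"] > table["urban_pct"]
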