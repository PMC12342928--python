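"""Dilution line residuals, driver attribution and correlation helpers."""

import numpy as np
import pandas as pd
import pytest

from oceanch4 import synthetic as syn
from oceanch4.mixing import (
    DilutionModel,
    MixingError,
    correlations,
    dilution_residuals,
    driver_regression,
)


@pytest.fixture
def transect_model():
    # fresh methane-rich endmember vs saline methane-poor endmember
    return DilutionModel(s_a=33.2, ch4_a=6.11, s_b=35.1, ch4_b=5.15)


class TestDilutionModel:
    def test_endpoints(self, transect_model):
        assert transect_model.predict(33.2) == pytest.approx(6.11)
        assert transect_model.predict(35.1) == pytest.approx(5.15)

    def test_midpoint(self, transect_model):
        assert transect_model.predict(34.15) == pytest.approx(5.63, abs=1e-9)

    def test_midpoint_equals_mean_of_endpoints(self, transect_model):
        mid = (transect_model.ch4_a + transect_model.ch4_b) / 2
        assert transect_model.predict(34.15) == pytest.approx(mid)

    def test_exactly_linear_in_salinity(self, transect_model):
        s = np.linspace(33.2, 35.1, 7)
        pred = transect_model.predict(s)
        assert np.allclose(np.diff(pred, 2), 0.0, atol=1e-12)

    def test_equal_salinities_rejected(self):
        with pytest.raises(MixingError):
            DilutionModel(s_a=34.0, ch4_a=6.0, s_b=34.0, ch4_b=5.0)


class TestDilutionResiduals:
    def test_observations_on_the_line_give_zero(self, transect_model):
        s = np.linspace(33.2, 35.1, 20)
        resid, summary = dilution_residuals(transect_model, s, transect_model.predict(s))
        assert np.allclose(resid, 0.0, atol=1e-12)
        assert summary["mean_residual"] == pytest.approx(0.0, abs=1e-12)

    def test_imposed_consumption_anomaly_recovered(self):
        # conservative CH4 mixing plus a uniform -0.3 nmol/l consumption
        cfg = syn.default_scenario(seed=31, n_stations=20, production_anomaly=-0.3)
        samples, truth = syn.generate_section(cfg)
        model = DilutionModel(
            s_a=cfg.endmembers.properties[0, 1],
            ch4_a=cfg.ch4_endmember[0],
            s_b=cfg.endmembers.properties[1, 1],
            ch4_b=cfg.ch4_endmember[1],
        )
        resid, summary = dilution_residuals(model, samples["S"], samples["ch4_nmol_l"])
        assert summary["mean_residual"] == pytest.approx(-0.3, abs=0.05)

    def test_conservative_mixture_centred_on_zero(self):
        cfg = syn.default_scenario(seed=32, n_stations=20)
        samples, _ = syn.generate_section(cfg)
        model = DilutionModel(
            s_a=cfg.endmembers.properties[0, 1],
            ch4_a=cfg.ch4_endmember[0],
            s_b=cfg.endmembers.properties[1, 1],
            ch4_b=cfg.ch4_endmember[1],
        )
        resid, summary = dilution_residuals(model, samples["S"], samples["ch4_nmol_l"])
        se = summary["sd_residual"] / np.sqrt(summary["n"])
        assert abs(summary["mean_residual"]) < 4 * se + 1e-3


class TestDriverRegression:
    def test_single_driver_takes_all_explained_variance(self, rng):
        sst = rng.normal(20, 3, 100)
        other = rng.normal(34, 0.5, 100)
        # residualize so the nuisance predictor is exactly orthogonal in sample
        sst_c = sst - sst.mean()
        other = other - other.mean()
        other -= (other @ sst_c) / (sst_c @ sst_c) * sst_c
        y = 2.0 * sst + 1.0
        out = driver_regression(y, pd.DataFrame({"SST": sst, "S": other}))
        assert out.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        assert out.shares_pct["SST"] == pytest.approx(100.0, abs=1e-6)
        assert out.shares_pct["S"] == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_two_to_one_variance_split(self):
        n = 400
        t = np.arange(n)
        x1 = np.where(t % 2 == 0, 1.0, -1.0)
        x2 = np.where(t % 4 < 2, 1.0, -1.0)  # orthogonal to x1
        y = np.sqrt(2.0) * x1 + 1.0 * x2
        out = driver_regression(y, pd.DataFrame({"a": x1, "b": x2}))
        assert out.shares_pct["a"] == pytest.approx(200.0 / 3.0, abs=0.1)
        assert out.shares_pct["b"] == pytest.approx(100.0 / 3.0, abs=0.1)

    def test_pure_noise_has_near_zero_adjusted_r2(self, rng):
        y = rng.normal(0, 1, 300)
        X = pd.DataFrame(rng.normal(0, 1, (300, 3)), columns=["a", "b", "c"])
        out = driver_regression(y, X)
        assert abs(out.adjusted_r2) < 0.05

    def test_shares_sum_to_explained_fraction(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=["a", "b", "c"])
        y = X["a"] + 0.5 * X["b"] + rng.normal(0, 0.5, 200)
        out = driver_regression(y, X)
        assert out.shares_pct.sum() == pytest.approx(100.0 * out.r2, abs=1e-6)
        assert (out.shares_pct >= 0).all()

    def test_permutation_symmetry_of_shares(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (150, 3)), columns=["a", "b", "c"])
        y = X["a"] + 0.7 * X["b"] + 0.3 * X["c"] + rng.normal(0, 0.4, 150)
        out1 = driver_regression(y, X)
        out2 = driver_regression(y, X[["c", "a", "b"]])
        for col in "abc":
            assert out2.shares_pct[col] == pytest.approx(out1.shares_pct[col], rel=1e-9)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(MixingError, match="n > p"):
            driver_regression([1.0, 2.0, 3.0], pd.DataFrame({"a": [1, 2, 3], "b": [2, 1, 2]}))


class TestCorrelations:
    def test_perfect_linear_pair(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        out = correlations(df, [("x", "y")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_structural_k_vs_mox(self):
        k = np.linspace(0.001, 0.05, 30)
        df = pd.DataFrame({"k": k, "mox": k * 3.21})
        out = correlations(df, [("k", "mox")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_bivariate_normal_sampling_distribution(self, rng):
        rho = 0.5
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        df = pd.DataFrame(xy, columns=["a", "b"])
        out = correlations(df, [("a", "b")])
        assert out.loc[0, "r"] == pytest.approx(rho, abs=0.08)

    def test_pairwise_complete_handling(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, 4.0, 5.0], "y": [2.0, 4.1, 6.0, 8.2, 9.9]}
        )
        out = correlations(df, [("x", "y")])
        assert out.loc[0, "n"] == 4
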