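import math

import numpy as np
import pandas as pd
import pytest

from hgtrade.errors import ConfigurationError, ValidationError
from hgtrade.health import (
    HealthParams,
    economic_loss,
    fha_deaths,
    iq_decrement,
    scenario_impacts,
    small_dose_limit_check,
)
from hgtrade.synthetic_world import Demographics


def simple_params(**overrides):
    kwargs = dict(
        beta=1.0, lambda_=1.0, gamma=0.1, phi=0.01, omega=1.0,
        bw=70.0, bw_mode="multiply", deflators={2005: 1.0, 2008: 1.0},
    )
    kwargs.update(overrides)
    return HealthParams(**kwargs)


def demo_table(rows):
    cols = ["births", "pop_male", "pop_female", "cf_male", "cf_female", "gdp_pc"]
    return Demographics(pd.DataFrame(rows, columns=cols, index=list(rows)).T.T)


class TestIQDecrement:
    def test_zero_exposure(self):
        assert iq_decrement(0.0, simple_params()) == 0.0

    def test_hand_value(self):
        # γλβ = 0.1 per (µg/day·kg), BW = 70 kg, E = 1 µg/day → 7 points
        p = simple_params(gamma=0.1, lambda_=1.0, beta=1.0, bw=70.0)
        assert iq_decrement(1.0, p) == pytest.approx(7.0)

    def test_linearity(self):
        p = simple_params()
        assert iq_decrement(2.0, p) == pytest.approx(2 * iq_decrement(1.0, p))

    def test_bw_divide_mode(self):
        p = simple_params(bw_mode="divide", bw=70.0)
        assert iq_decrement(7.0, p) == pytest.approx(0.1 * 7.0 / 70.0)

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValidationError):
            iq_decrement(-1.0, simple_params())


class TestFHADeaths:
    def one_country(self, pop=1e6, cf=0.002):
        return pd.DataFrame(
            {"pop_male": [pop], "pop_female": [0.0], "cf_male": [cf], "cf_female": [0.0]},
            index=["A"],
        )

    def test_zero_exposure_zero_deaths(self):
        p = simple_params()
        assert fha_deaths(pd.Series({"A": 0.0}), self.one_country(), p)["A"] == 0.0

    def test_omega_zero_kills_effect(self):
        p = simple_params(omega=0.0)
        assert fha_deaths(pd.Series({"A": 50.0}), self.one_country(), p)["A"] == 0.0

    def test_hand_value(self):
        # POP 1e6, Cf 0.002, ω = 1, exponent 0.001 → 1e6·0.002·(1−e^−0.001)
        p = simple_params(phi=0.001, lambda_=1.0, beta=1.0, bw=1.0)
        got = fha_deaths(pd.Series({"A": 1.0}), self.one_country(), p)["A"]
        assert got == pytest.approx(1e6 * 0.002 * (1 - math.exp(-0.001)), rel=1e-12)
        assert got == pytest.approx(1.999, abs=1e-3)

    def test_bounded_by_omega_population_risk(self):
        p = simple_params(omega=0.7)
        demo = self.one_country()
        huge = fha_deaths(pd.Series({"A": 1e9}), demo, p)["A"]
        assert huge <= 0.7 * 1e6 * 0.002 + 1e-9

    def test_gender_sum(self):
        demo = pd.DataFrame(
            {"pop_male": [1e6], "pop_female": [2e6], "cf_male": [0.002], "cf_female": [0.001]},
            index=["A"],
        )
        p = simple_params(phi=0.001, bw=1.0)
        got = fha_deaths(pd.Series({"A": 1.0}), demo, p)["A"]
        expect = (1e6 * 0.002 + 2e6 * 0.001) * (1 - math.exp(-0.001))
        assert got == pytest.approx(expect, rel=1e-12)


class TestSmallDoseLimit:
    def test_zero_dose(self):
        assert small_dose_limit_check(simple_params(), 0.0) == 0.0

    @pytest.mark.parametrize("x", [0.001, 0.01])
    def test_taylor_gap(self, x):
        p = simple_params(phi=1.0, lambda_=1.0, beta=1.0, bw=1.0)
        gap = small_dose_limit_check(p, x)
        assert gap == pytest.approx(x / 2, rel=0.01)
        assert gap <= x  # second-order bound


class TestEconomicLoss:
    def test_zero_impacts(self):
        loss = economic_loss(0.0, 0.0, simple_params())
        assert loss["loss_total"] == 0.0

    def test_hand_value_with_unit_deflators(self):
        # 100 IQ points and 1 death: 18,832·100 + 6.3e6 = 8,083,200 + ...
        loss = economic_loss(100.0, 1.0, simple_params())
        assert loss["loss_iq"] == pytest.approx(1_883_200.0)
        assert loss["loss_fha"] == pytest.approx(6_300_000.0)
        assert loss["loss_total"] == pytest.approx(8_183_200.0)

    def test_doubling_impacts_doubles_loss(self):
        p = simple_params()
        one = economic_loss(10.0, 2.0, p)["loss_total"]
        two = economic_loss(20.0, 4.0, p)["loss_total"]
        assert two == pytest.approx(2 * one)

    def test_deflators_applied(self):
        p = simple_params(deflators={2005: 2.0, 2008: 1.5})
        loss = economic_loss(1.0, 1.0, p)
        assert loss["loss_iq"] == pytest.approx(18832.0 * 1.5)
        assert loss["loss_fha"] == pytest.approx(6.3e6 * 2.0)

    def test_missing_deflator_rejected(self):
        with pytest.raises(ConfigurationError, match="deflator"):
            economic_loss(1.0, 1.0, simple_params(deflators={2008: 1.0}))

    def test_country_vsl_elasticity(self):
        p = simple_params(use_country_vsl=True, vsl_elasticity=1.0,
                          vsl_reference_gdp=40000.0)
        vsl = p.vsl_2020(np.array([40000.0, 20000.0]))
        assert vsl[0] == pytest.approx(6.3e6)
        assert vsl[1] == pytest.approx(3.15e6)
        flat = simple_params(use_country_vsl=True, vsl_elasticity=0.0)
        assert np.allclose(flat.vsl_2020(np.array([40000.0, 20000.0])), 6.3e6)


class TestScenarioImpacts:
    def demo(self):
        return Demographics(pd.DataFrame(
            {
                "births": [1000.0, 2000.0],
                "pop_male": [5e5, 7e5],
                "pop_female": [5e5, 7e5],
                "cf_male": [0.002, 0.003],
                "cf_female": [0.001, 0.002],
                "gdp_pc": [40000.0, 10000.0],
            },
            index=["A", "B"],
        ))

    def test_equal_scenarios_have_zero_nets(self):
        e = pd.Series({"A": 3.0, "B": 5.0})
        impacts = scenario_impacts(e, e.copy(), self.demo(), simple_params())
        for q in ("iq_total", "fha_deaths", "loss_total"):
            assert np.all(impacts.table[f"{q}_net"].values == 0.0)

    def test_single_country_hand_chain(self):
        p = simple_params(gamma=0.1, phi=0.01, bw=1.0, omega=0.5)
        demo = Demographics(pd.DataFrame(
            {"births": [100.0], "pop_male": [1e6], "pop_female": [0.0],
             "cf_male": [0.002], "cf_female": [0.0], "gdp_pc": [1000.0]},
            index=["A"],
        ))
        e_wt, e_nt = pd.Series({"A": 2.0}), pd.Series({"A": 3.0})
        got = scenario_impacts(e_wt, e_nt, demo, p).table
        iq_wt, iq_nt = 0.1 * 2.0, 0.1 * 3.0
        deaths_wt = 1e6 * 0.002 * 0.5 * (1 - math.exp(-0.01 * 2.0))
        deaths_nt = 1e6 * 0.002 * 0.5 * (1 - math.exp(-0.01 * 3.0))
        assert got.loc["A", "iq_per_fetus_net"] == pytest.approx(iq_wt - iq_nt)
        assert got.loc["A", "iq_total_net"] == pytest.approx((iq_wt - iq_nt) * 100.0)
        assert got.loc["A", "fha_deaths_net"] == pytest.approx(deaths_wt - deaths_nt)
        loss_net = 18832.0 * (iq_wt - iq_nt) * 100.0 + 6.3e6 * (deaths_wt - deaths_nt)
        assert got.loc["A", "loss_total_net"] == pytest.approx(loss_net)

    def test_net_deaths_add_up_globally(self):
        e_wt = pd.Series({"A": 2.0, "B": 4.0})
        e_nt = pd.Series({"A": 2.5, "B": 3.0})
        impacts = scenario_impacts(e_wt, e_nt, self.demo(), simple_params())
        summary = impacts.global_summary()
        assert summary.loc["fha_deaths", "net"] == pytest.approx(
            impacts.table["fha_deaths_net"].sum()
        )

    def test_net_sign_tracks_exposure_delta(self):
        e_wt = pd.Series({"A": 2.0, "B": 4.0})
        e_nt = pd.Series({"A": 2.5, "B": 3.0})
        impacts = scenario_impacts(e_wt, e_nt, self.demo(), simple_params()).table
        assert impacts.loc["A", "loss_total_net"] < 0  # trade helps A
        assert impacts.loc["B", "loss_total_net"] > 0  # trade hurts B

    def test_loss_components_sum(self):
        e_wt = pd.Series({"A": 2.0, "B": 4.0})
        e_nt = pd.Series({"A": 2.5, "B": 3.0})
        t = scenario_impacts(e_wt, e_nt, self.demo(), simple_params()).table
        for tag in ("wt", "nt", "net"):
            np.testing.assert_allclose(
                t[f"loss_total_{tag}"], t[f"loss_iq_{tag}"] + t[f"loss_fha_{tag}"],
                rtol=1e-9,
            )

    def test_missing_demographics_flagged_not_zeroed(self, caplog):
        demo = self.demo()
        e = pd.Series({"A": 2.0, "B": 4.0, "C": 1.0})
        with caplog.at_level("WARNING"):
            impacts = scenario_impacts(e, e * 1.1, demo, simple_params())
        assert impacts.n_missing == 1
        assert np.isnan(impacts.table.loc["C", "iq_total_wt"])
        summary = impacts.global_summary()
        assert np.isfinite(summary.values.astype(float)).all()

    def test_difference_mode_matches_linear_iq(self):
        p = simple_params()
        e_wt = pd.Series({"A": 2.0, "B": 4.0})
        e_nt = pd.Series({"A": 2.5, "B": 3.0})
        per = scenario_impacts(e_wt, e_nt, self.demo(), p, mode="per_scenario").table
        diff = scenario_impacts(e_wt, e_nt, self.demo(), p, mode="difference").table
        # IQ is linear: both readings agree; FHA is log-linear: they differ
        np.testing.assert_allclose(per["iq_total_net"], diff["iq_total_net"], rtol=1e-12)
        assert not np.allclose(per["fha_deaths_net"], diff["fha_deaths_net"], rtol=1e-12)
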