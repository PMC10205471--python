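import numpy as np
import pandas as pd
import pytest

from hgtrade.errors import ScalingError, ValidationError, WeightingError
from hgtrade.exposure import (
    catch_weighted_plankton,
    exposure_delta_decomposition,
    exposure_no_trade,
    exposure_with_trade,
    mean_soil,
    no_trade_pathways,
    pathway_exposures,
    population_weighted_deposition,
)
from conftest import make_field, single_cell_mask


def diet_frame(rows):
    return pd.DataFrame(rows).T.rename(
        columns=dict(enumerate(["I_seafood", "I_fwfish", "I_rice"]))
    )


def conc_frame(rows):
    return pd.DataFrame(rows).T.rename(
        columns=dict(enumerate(["C_seafood", "C_fwfish", "C_rice"]))
    )


def env_frame(index, ratios):
    """Environment table with WT proxies = 1 and NT = the requested ratios
    (per pathway order seafood→P, fwfish→D, rice→S)."""
    p, d, s = ratios
    return pd.DataFrame(
        {"P_WT": 1.0, "P_NT": p, "D_WT": 1.0, "D_NT": d, "S_WT": 1.0, "S_NT": s},
        index=index,
    )


class TestCountryProxies:
    def test_population_weighted_deposition_hand_values(self):
        D = make_field([[4.0, 8.0]])
        pop = make_field([[1.0, 3.0]])
        mask = single_cell_mask((1, 2), {"A": np.array([[1.0, 1.0]])})
        got = population_weighted_deposition(D, mask, pop)
        assert got["A"] == pytest.approx(7.0)

    def test_uniform_deposition_returns_constant(self):
        D = make_field(np.full((2, 3), 2.5))
        pop = make_field(np.random.default_rng(0).random((2, 3)) + 0.1)
        b = np.full((2, 3), 0.3)
        b[0, 0] = 0.0
        mask = single_cell_mask((2, 3), {"A": (0, 0), "B": b})
        got = population_weighted_deposition(D, mask, pop)
        assert np.allclose(got.values, 2.5)

    def test_point_mass_population(self):
        D = make_field([[4.0, 9.0]])
        pop = make_field([[0.0, 5.0]])
        mask = single_cell_mask((1, 2), {"A": np.array([[1.0, 1.0]])})
        assert population_weighted_deposition(D, mask, pop)["A"] == pytest.approx(9.0)

    def test_zero_population_rejected(self):
        D = make_field([[1.0]])
        pop = make_field([[0.0]])
        mask = single_cell_mask((1, 1), {"A": (0, 0)})
        with pytest.raises(WeightingError, match="population"):
            population_weighted_deposition(D, mask, pop)

    def test_catch_weighted_plankton_hand_values(self):
        P = make_field([[2.0, 6.0]])
        w = {"A": np.array([[0.25, 0.75]])}
        got = catch_weighted_plankton(P, w, ["A", "B"])
        assert got["A"] == pytest.approx(5.0)
        assert np.isnan(got["B"])  # no catch → missing, not zero

    def test_catch_single_cell_and_uniform(self):
        P = make_field([[3.0, 7.0]])
        got = catch_weighted_plankton(P, {"A": np.array([[0.0, 1.0]])}, ["A"])
        assert got["A"] == pytest.approx(7.0)
        uniform = make_field(np.full((1, 2), 4.0))
        got = catch_weighted_plankton(uniform, {"A": np.array([[0.5, 0.5]])}, ["A"])
        assert got["A"] == pytest.approx(4.0)

    def test_zero_sum_catch_weights_rejected(self):
        P = make_field([[1.0]])
        with pytest.raises(WeightingError):
            catch_weighted_plankton(P, {"A": np.array([[0.0]])}, ["A"])

    def test_mean_soil_hand_values(self):
        S = make_field([[3.0, 5.0]])
        mask = single_cell_mask((1, 2), {"A": np.array([[1.0, 1.0]])})
        assert mean_soil(S, mask)["A"] == pytest.approx(4.0)
        single = single_cell_mask((1, 2), {"B": (0, 1)})
        assert mean_soil(S, single)["B"] == pytest.approx(5.0)


class TestExposure:
    def test_with_trade_hand_value(self):
        diets = diet_frame({"A": [100.0, 50.0, 200.0]})
        conc = conc_frame({"A": [0.10, 0.05, 0.01]})
        assert exposure_with_trade(diets, conc)["A"] == pytest.approx(14.5)

    def test_zero_intake_gives_zero(self):
        diets = diet_frame({"A": [0.0, 0.0, 0.0]})
        conc = conc_frame({"A": [0.1, 0.1, 0.1]})
        assert exposure_with_trade(diets, conc)["A"] == 0.0

    def test_linear_in_concentration(self):
        diets = diet_frame({"A": [10.0, 20.0, 30.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        assert exposure_with_trade(diets, conc * 2)["A"] == pytest.approx(
            2 * exposure_with_trade(diets, conc)["A"]
        )

    def test_negative_inputs_rejected(self):
        diets = diet_frame({"A": [-1.0, 0.0, 0.0]})
        conc = conc_frame({"A": [0.1, 0.1, 0.1]})
        with pytest.raises(ValidationError):
            exposure_with_trade(diets, conc)

    def test_no_trade_equal_ratios_reproduce_with_trade(self):
        diets = diet_frame({"A": [100.0, 50.0, 200.0]})
        conc = conc_frame({"A": [0.10, 0.05, 0.01]})
        env = env_frame(diets.index, (1.0, 1.0, 1.0))
        assert exposure_no_trade(diets, conc, env)["A"] == pytest.approx(
            exposure_with_trade(diets, conc)["A"]
        )

    def test_no_trade_hand_value(self):
        # equal 1 µg/day per pathway, ratios (2, 0.5, 1) → 3.5 µg/day
        diets = diet_frame({"A": [10.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        env = env_frame(diets.index, (2.0, 0.5, 1.0))
        assert exposure_no_trade(diets, conc, env)["A"] == pytest.approx(3.5)

    def test_single_pathway_relative_change(self):
        eps = 1e-3
        diets = diet_frame({"A": [0.0, 0.0, 200.0]})
        conc = conc_frame({"A": [0.0, 0.0, 0.01]})
        env = env_frame(diets.index, (1.0, 1.0, 1.0 + eps))
        e_wt = exposure_with_trade(diets, conc)["A"]
        e_nt = exposure_no_trade(diets, conc, env)["A"]
        assert (e_nt - e_wt) / e_wt == pytest.approx(eps, rel=1e-9)

    def test_zero_intake_pathway_skips_missing_proxy(self):
        # zero seafood intake: a missing P proxy must not matter
        diets = diet_frame({"A": [0.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        env = env_frame(diets.index, (np.nan, 1.0, 1.0))
        assert np.isfinite(exposure_no_trade(diets, conc, env)["A"])

    def test_zero_proxy_with_intake_rejected(self):
        diets = diet_frame({"A": [10.0, 0.0, 0.0]})
        conc = conc_frame({"A": [0.1, 0.0, 0.0]})
        env = env_frame(diets.index, (1.0, 1.0, 1.0))
        env["P_WT"] = 0.0
        with pytest.raises(ScalingError):
            exposure_no_trade(diets, conc, env)

    def test_monotone_in_no_trade_proxy(self):
        diets = diet_frame({"A": [10.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        lo = exposure_no_trade(diets, conc, env_frame(diets.index, (1.0, 1.0, 1.0)))["A"]
        hi = exposure_no_trade(diets, conc, env_frame(diets.index, (1.4, 1.0, 1.0)))["A"]
        assert hi >= lo

    def test_scenario_symmetry(self):
        # swapping the scenario labels and inverting the ratios recovers E_WT
        diets = diet_frame({"A": [10.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        ratios = (2.0, 0.5, 1.25)
        env = env_frame(diets.index, ratios)
        e_nt = exposure_no_trade(diets, conc, env)
        # re-base to the no-trade world: concentrations pick up the ratios,
        # and the scenario labels swap (so the ratios invert)
        conc_nt = conc.copy()
        for col, r in zip(["C_seafood", "C_fwfish", "C_rice"], ratios):
            conc_nt[col] = conc[col] * r
        swapped = env.rename(
            columns={
                "P_WT": "P_NT", "P_NT": "P_WT",
                "D_WT": "D_NT", "D_NT": "D_WT",
                "S_WT": "S_NT", "S_NT": "S_WT",
            }
        )
        wt = exposure_with_trade(diets, conc)
        assert exposure_with_trade(diets, conc_nt)["A"] == pytest.approx(e_nt["A"])
        assert exposure_no_trade(diets, conc_nt, swapped)["A"] == pytest.approx(wt["A"])


class TestDecomposition:
    def test_pathway_deltas_sum_exactly(self):
        diets = diet_frame({"A": [10.0, 20.0, 100.0], "B": [5.0, 0.0, 50.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01], "B": [0.2, 0.0, 0.02]})
        env = env_frame(diets.index, (1.3, 0.8, 1.1))
        wt = pathway_exposures(diets, conc)
        nt = no_trade_pathways(diets, conc, env)
        delta = exposure_delta_decomposition(wt, nt)
        np.testing.assert_array_equal(
            delta["total"].values,
            (delta[["seafood", "fwfish", "rice"]].sum(axis=1)).values,
        )
        np.testing.assert_allclose(
            delta["total"].values,
            (exposure_no_trade(diets, conc, env) - exposure_with_trade(diets, conc)).values,
        )

    def test_hand_deltas(self):
        diets = diet_frame({"A": [10.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        env = env_frame(diets.index, (2.0, 0.5, 1.0))
        delta = exposure_delta_decomposition(
            pathway_exposures(diets, conc), no_trade_pathways(diets, conc, env)
        )
        assert delta.loc["A", ["seafood", "fwfish", "rice"]].tolist() == pytest.approx(
            [1.0, -0.5, 0.0]
        )

    def test_identical_ratios_give_zero_deltas(self):
        diets = diet_frame({"A": [10.0, 20.0, 100.0]})
        conc = conc_frame({"A": [0.1, 0.05, 0.01]})
        env = env_frame(diets.index, (1.0, 1.0, 1.0))
        delta = exposure_delta_decomposition(
            pathway_exposures(diets, conc), no_trade_pathways(diets, conc, env)
        )
        assert np.allclose(delta.values, 0.0)

    def test_single_pathway_full_attribution(self):
        diets = diet_frame({"A": [0.0, 0.0, 100.0]})
        conc = conc_frame({"A": [0.0, 0.0, 0.01]})
        env = env_frame(diets.index, (1.0, 1.0, 1.2))
        delta = exposure_delta_decomposition(
            pathway_exposures(diets, conc), no_trade_pathways(diets, conc, env)
        )
        assert delta.loc["A", "rice"] == pytest.approx(delta.loc["A", "total"])
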