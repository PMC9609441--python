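import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from nanotwin.milling import (
    BreakageModel,
    BreakageOperator,
    MaterialMechanics,
    ParticleSizeDistribution,
    SizeGrid,
    austin_cumulative_b,
    austin_rate,
    build_operator,
    d50,
    devegt_cumulative_b,
    devegt_rate,
    discretize_breakage,
    fit_breakage,
    fracture_energy,
    kapur_cumulative_b,
    kapur_rate,
    kinetic_energy,
    lognormal_psd,
    pbm_rhs,
    simulate_milling,
    sweep_parameter,
)


@pytest.fixture
def small_grid():
    """4-bin geometric grid, 4 um down to 0.25 um."""
    return SizeGrid(np.array([4.0, 2.0, 1.0, 0.5, 0.25]) * 1e-6)


@pytest.fixture
def mech():
    return MaterialMechanics()


# ---------------------------------------------------------------------------
# grids and distributions
# ---------------------------------------------------------------------------


class TestSizeGrid:
    def test_representative_is_geometric_mean(self, small_grid):
        assert small_grid.representative[0] == pytest.approx(
            math.sqrt(4.0 * 2.0) * 1e-6
        )

    def test_rejects_increasing_edges(self):
        with pytest.raises(ValueError):
            SizeGrid(np.array([1.0, 2.0, 3.0, 4.0]))

    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            SizeGrid(np.array([2.0, 1.0]))

    def test_default_grid_spans_case_study_sizes(self):
        grid = SizeGrid.geometric()
        assert grid.n_bins == 20
        assert grid.edges[0] == pytest.approx(5e-6)
        assert grid.edges[-1] == pytest.approx(0.05e-6)


class TestPsd:
    def test_mass_fractions_must_sum_to_one(self, small_grid):
        with pytest.raises(ValueError):
            ParticleSizeDistribution(small_grid, np.array([0.5, 0.2, 0.1, 0.1]))

    def test_lognormal_psd_normalized_with_median_on_grid(self, small_grid):
        psd = lognormal_psd(small_grid, median=1e-6, gsd=1.4)
        assert psd.w.sum() == pytest.approx(1.0, abs=1e-12)
        assert d50(psd) == pytest.approx(1.0, rel=0.05)  # um


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------


class TestEnergetics:
    def test_kinetic_energy_product(self):
        assert kinetic_energy(100.0, 1300.0, 1e-18) == pytest.approx(1.3e-13)
        assert kinetic_energy(100.0, 1300.0, 0.0) == 0.0
        assert kinetic_energy(100.0, 1300.0, 2e-18) == pytest.approx(
            2 * kinetic_energy(100.0, 1300.0, 1e-18)
        )

    def test_kinetic_energy_rejects_negative(self):
        with pytest.raises(ValueError):
            kinetic_energy(-1.0, 1300.0, 1e-18)

    def test_fracture_energy_volume_scaling(self):
        # E(V) / E(8V) = 8^(5/12) from the (V0/V)^(1/4) power inside ^( 5/3 )
        e1 = fracture_energy(0.3, 5e9, 2.2e4, 1e-27, 1e-18)
        e8 = fracture_energy(0.3, 5e9, 2.2e4, 1e-27, 8e-18)
        assert e1 / e8 == pytest.approx(8 ** (5.0 / 12.0), rel=1e-12)

    def test_fracture_energy_hand_evaluation(self):
        poisson, young, delta, v0, vi = 0.3, 5e9, 2.2e4, 1e-27, 1e-18
        expected = (
            0.896
            * (math.pi * (1 - poisson**2) / young) ** (2 / 3)
            * (0.0183 * delta**2 * (v0 / vi) ** 0.25) ** (5 / 3)
        )
        assert fracture_energy(poisson, young, delta, v0, vi) == pytest.approx(
            expected, rel=1e-12
        )

    def test_fracture_energy_zero_without_cohesion(self):
        assert fracture_energy(0.3, 5e9, 0.0, 1e-27, 1e-18) == 0.0


# ---------------------------------------------------------------------------
# rates and fragment distributions
# ---------------------------------------------------------------------------


class TestRates:
    def test_devegt_rate_linear_in_c(self, small_grid, mech):
        s1 = devegt_rate(small_grid, 1.0, mech)
        s2 = devegt_rate(small_grid, 2.0, mech)
        assert np.allclose(s2, 2 * s1)
        assert np.all(devegt_rate(small_grid, 0.0, mech) == 0.0)

    def test_devegt_rate_matches_per_bin_oracle(self, small_grid, mech):
        x = small_grid.representative
        vi = (math.pi / 6.0) * x**3
        expected = (
            1.0
            * kinetic_energy(mech.wm_kin, mech.rho, vi)
            * fracture_energy(mech.poisson, mech.young, mech.delta_solubility, mech.v0, vi)
            * mech.yield_pressure
            / (mech.rho * mech.mill_volume * mech.hardness * x * mech.k1c)
        )
        assert np.allclose(devegt_rate(small_grid, 1.0, mech), expected, rtol=1e-12)

    def test_devegt_rate_size_exponent(self, small_grid, mech):
        # the combined energetics reduce to S proportional to x^0.75
        s = devegt_rate(small_grid, 1.0, mech)
        x = small_grid.representative
        ratio = s / x**0.75
        assert np.allclose(ratio, ratio[0])

    def test_austin_rate_cutoff_and_power(self):
        assert austin_rate(0.5e-6, 8e-5, 1.6, 1e-6) == 0.0
        assert austin_rate(1e-6, 8e-5, 1.6, 1e-6) == pytest.approx(8e-5)
        assert austin_rate(2e-6, 8e-5, 1.6, 1e-6) == pytest.approx(8e-5 * 2**1.6)

    def test_kapur_rate_power_law(self):
        assert kapur_rate(1.0, 0.008, 1.2) == pytest.approx(0.008)
        with pytest.raises(ValueError):
            kapur_rate(-1.0, 0.008, 1.2)


class TestCumulativeDistributions:
    def test_devegt_halving_ratio(self):
        assert devegt_cumulative_b(0.5, 1.0) == pytest.approx(2 ** (-1.25))
        assert devegt_cumulative_b(1.0, 1.0) == 1.0
        assert devegt_cumulative_b(0.5, 1.0, exponent=1.0) == pytest.approx(0.5)

    def test_devegt_rejects_fragment_above_parent(self):
        with pytest.raises(ValueError):
            devegt_cumulative_b(2.0, 1.0)

    def test_austin_normalized_and_limits(self):
        assert austin_cumulative_b(1.0, 1.0, 0.3, 1.17, 4.0) == pytest.approx(1.0)
        # phi = 1 collapses to a single power law
        assert austin_cumulative_b(0.5, 1.0, 1.0, 1.25, 4.0) == pytest.approx(
            devegt_cumulative_b(0.5, 1.0)
        )

    def test_austin_hand_evaluation(self):
        expected = 0.3 * 0.5**1.17 + 0.7 * 0.5**4
        assert austin_cumulative_b(0.5, 1.0, 0.3, 1.17, 4.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.1771, abs=2e-4)

    def test_kapur_equals_devegt_at_exponent_1_25(self):
        assert kapur_cumulative_b(0.37, 1.0, 1.25) == pytest.approx(
            devegt_cumulative_b(0.37, 1.0)
        )


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


class TestDiscretization:
    def test_columns_sum_to_one(self, small_grid):
        b = discretize_breakage(lambda xi, xj: devegt_cumulative_b(xi, xj), small_grid)
        sums = b[:, :-1].sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.all(np.abs(np.triu(b)) == 0.0)

    def test_four_bin_entries_match_hand_computed_edge_differences(self, small_grid):
        # parent of column 0 is its lower edge e1; B = (x/e1)^1.25
        e = small_grid.edges
        b = discretize_breakage(lambda xi, xj: devegt_cumulative_b(xi, xj), small_grid)
        r = lambda x: (x / e[1]) ** 1.25
        assert b[1, 0] == pytest.approx(r(e[1]) - r(e[2]))  # 1 - (e2/e1)^1.25
        assert b[2, 0] == pytest.approx(r(e[2]) - r(e[3]))
        # finest bin absorbs the sub-grid tail
        assert b[3, 0] == pytest.approx((r(e[3]) - r(e[4])) + r(e[4]))

    def test_two_bin_grid_sends_everything_to_finer_bin(self):
        grid = SizeGrid(np.array([4.0, 2.0, 1.0, 0.5]) * 1e-6)
        b = discretize_breakage(lambda xi, xj: devegt_cumulative_b(xi, xj), grid)
        for j in range(grid.n_bins - 1):
            assert b[:, j].sum() == pytest.approx(1.0)
        assert b[2, 1] == pytest.approx(1.0)  # only one finer bin available

    def test_non_monotone_distribution_rejected(self, small_grid):
        bad = lambda xi, xj: 1.0 - np.asarray(xi) / xj  # increasing toward fines
        with pytest.raises(ValueError):
            discretize_breakage(bad, small_grid)

    def test_kapur_e_1_25_reproduces_devegt_matrix(self, small_grid, mech):
        kapur = build_operator(
            BreakageModel("kapur", {"e": 1.25, "k": 0.75, "A": 1.0}), small_grid
        )
        devegt = build_operator(
            BreakageModel("de_vegt", {"c": 1.0}), small_grid, mech
        )
        assert np.allclose(kapur.b, devegt.b, atol=1e-14)


# ---------------------------------------------------------------------------
# the population balance
# ---------------------------------------------------------------------------


def _operator(small_grid, a_rate=1e-3):
    model = BreakageModel("kapur", {"e": 1.25, "k": 0.75, "A": a_rate * (1e-6) ** -0.75})
    return build_operator(model, small_grid)


class TestPbmRhs:
    def test_zero_rates_give_zero_derivative(self, small_grid):
        op = BreakageOperator(S=np.zeros(4), b=np.zeros((4, 4)))
        psd = lognormal_psd(small_grid, 1e-6, 1.4)
        assert np.all(pbm_rhs(psd, op) == 0.0)

    def test_single_loaded_bin_direct_substitution(self, small_grid):
        op = _operator(small_grid)
        w = np.zeros(4)
        w[0] = 1.0
        psd = ParticleSizeDistribution(small_grid, w)
        rhs = pbm_rhs(psd, op)
        assert rhs[0] == pytest.approx(-op.S[0])
        assert np.allclose(rhs[1:], op.S[0] * op.b[1:, 0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_mass_conserving_for_any_psd(self, raw):
        grid = SizeGrid(np.array([4.0, 2.0, 1.0, 0.5, 0.25]) * 1e-6)
        w = np.array(raw)
        psd = ParticleSizeDistribution(grid, w / w.sum())
        rhs = pbm_rhs(psd, _operator(grid))
        assert rhs.sum() == pytest.approx(0.0, abs=1e-15)

    def test_dimension_mismatch_rejected(self, small_grid):
        psd = lognormal_psd(small_grid, 1e-6, 1.4)
        with pytest.raises(ValueError):
            pbm_rhs(psd, BreakageOperator(S=np.zeros(5), b=np.zeros((5, 5))))


class TestSimulation:
    def test_zero_rate_model_keeps_d50_constant(self, small_grid):
        psd = lognormal_psd(small_grid, 1e-6, 1.4)
        model = BreakageModel("kapur", {"e": 1.25, "k": 0.75, "A": 0.0})
        result = simulate_milling(psd, model, t_end=600.0, dt_out=200.0)
        assert np.allclose(result.d50_profile, result.d50_profile[0], rtol=1e-9)

    def test_mass_conserved_and_d50_monotone(self, feed_psd):
        model = BreakageModel(
            "kapur", {"e": 1.25, "k": 0.75, "A": 1e-3 * (1e-6) ** -0.75}
        )
        result = simulate_milling(feed_psd, model, t_end=3600.0, dt_out=120.0)
        for psd in result.psd_trajectory:
            assert abs(psd.w.sum() - 1.0) < 1e-8
        assert np.all(np.diff(result.d50_profile) <= 1e-9)

    def test_matrix_exponential_oracle_on_three_bins(self):
        grid = SizeGrid(np.array([2.0, 1.0, 0.5, 0.25]) * 1e-6)
        psd = lognormal_psd(grid, 1e-6, 1.3)
        model = BreakageModel("kapur", {"e": 2.0, "k": 1.0, "A": 2e-3 * 1e6})
        op = build_operator(model, grid)
        result = simulate_milling(psd, model, t_end=1200.0, dt_out=300.0)
        for t, sim in zip(result.times, result.psd_trajectory):
            exact = expm(op.matrix * t) @ psd.w
            assert np.allclose(sim.w, exact, rtol=1e-6, atol=1e-10)

    def test_doubling_rates_halves_time_to_any_d50(self, small_grid):
        psd = lognormal_psd(small_grid, 2e-6, 1.3)
        a = 1e-3 * (1e-6) ** -0.75
        slow = BreakageModel("kapur", {"e": 1.25, "k": 0.75, "A": a})
        fast = BreakageModel("kapur", {"e": 1.25, "k": 0.75, "A": 2 * a})
        r_slow = simulate_milling(psd, slow, times=np.array([0.0, 800.0]))
        r_fast = simulate_milling(psd, fast, times=np.array([0.0, 400.0]))
        assert r_fast.d50_profile[-1] == pytest.approx(r_slow.d50_profile[-1], rel=1e-6)


class TestD50:
    def test_single_bin_returns_representative(self, small_grid):
        w = np.array([0.0, 1.0, 0.0, 0.0])
        psd = ParticleSizeDistribution(small_grid, w)
        assert d50(psd) == pytest.approx(small_grid.representative[1] * 1e6)

    def test_even_split_returns_shared_edge(self, small_grid):
        w = np.array([0.5, 0.5, 0.0, 0.0])
        psd = ParticleSizeDistribution(small_grid, w)
        assert d50(psd) == pytest.approx(small_grid.edges[1] * 1e6)

    def test_uniform_mass_interpolates_to_middle_edge(self, small_grid):
        w = np.full(4, 0.25)
        psd = ParticleSizeDistribution(small_grid, w)
        # cumulative undersize hits exactly 0.5 at the middle edge (1 um)
        assert d50(psd) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitting:
    def test_devegt_self_fit_recovers_rate_constant(self, feed_psd, mech):
        truth = BreakageModel("de_vegt", {"c": 3e5})
        ref = simulate_milling(
            feed_psd, truth, mech, times=np.linspace(0.0, 3600.0, 13)
        )
        frame = pd.DataFrame({"time_s": ref.times, "d50_um": ref.d50_profile})
        fit = fit_breakage("de_vegt", frame, mech=mech, psd0=feed_psd)
        assert fit.model.params["c"] == pytest.approx(3e5, rel=0.01)
        assert fit.mse_percent < 1e-6

    def test_austin_self_fit_recovers_rate_parameters(self, feed_psd, mech):
        x_crit = feed_psd.grid.edges[-1]
        truth = {"phi": 0.3, "gamma_b": 1.17, "beta": 4.0, "a": 8e-5, "d": 1.6,
                 "x_crit": x_crit}
        ref = simulate_milling(
            feed_psd,
            BreakageModel("austin", truth),
            mech,
            times=np.linspace(0.0, 3600.0, 13),
        )
        frame = pd.DataFrame({"time_s": ref.times, "d50_um": ref.d50_profile})
        fit = fit_breakage(
            "austin",
            frame,
            mech=mech,
            psd0=feed_psd,
            fixed={"phi": 0.3, "gamma_b": 1.17, "beta": 4.0},
            n_starts=4,
            max_nfev=50,
        )
        assert fit.model.params["a"] == pytest.approx(8e-5, rel=0.05)
        assert fit.model.params["d"] == pytest.approx(1.6, rel=0.05)

    def test_kapur_self_fit_recovers_rate_parameters(self, feed_psd, mech):
        a_true = 1.2e-3 * (1e-6) ** -0.9
        truth = {"e": 2.0, "k": 0.9, "A": a_true}
        ref = simulate_milling(
            feed_psd,
            BreakageModel("kapur", truth),
            mech,
            times=np.linspace(0.0, 3600.0, 13),
        )
        frame = pd.DataFrame({"time_s": ref.times, "d50_um": ref.d50_profile})
        fit = fit_breakage(
            "kapur",
            frame,
            mech=mech,
            psd0=feed_psd,
            fixed={"e": 2.0},
            n_starts=4,
            max_nfev=50,
        )
        assert fit.model.params["k"] == pytest.approx(0.9, rel=0.05)
        assert fit.model.params["A"] == pytest.approx(a_true, rel=0.05)

    def test_reference_needs_three_points(self, feed_psd):
        frame = pd.DataFrame({"time_s": [0.0, 100.0], "d50_um": [1.5, 1.0]})
        with pytest.raises(ValueError):
            fit_breakage("de_vegt", frame, psd0=feed_psd)


class TestSweep:
    def test_devegt_rate_parameter_monotone(self, feed_psd, mech):
        model = BreakageModel("de_vegt", {"c": 1e5})
        frame = sweep_parameter(
            model, "c", [1e5, 3e5], feed_psd, mech, t_end=1200.0, dt_out=300.0
        )
        low = frame[frame["value"] == 1e5].sort_values("time_s")["d50_um"].to_numpy()
        high = frame[frame["value"] == 3e5].sort_values("time_s")["d50_um"].to_numpy()
        assert np.all(high <= low + 1e-12)

    def test_single_value_matches_simulate(self, feed_psd, mech):
        model = BreakageModel("de_vegt", {"c": 1e5})
        frame = sweep_parameter(
            model, "c", [1e5], feed_psd, mech, t_end=600.0, dt_out=300.0
        )
        direct = simulate_milling(feed_psd, model, mech, t_end=600.0, dt_out=300.0)
        assert np.allclose(
            frame.sort_values("time_s")["d50_um"].to_numpy(), direct.d50_profile
        )

    def test_unknown_parameter_rejected(self, feed_psd):
        model = BreakageModel("de_vegt", {"c": 1e5})
        with pytest.raises(ValueError):
            sweep_parameter(model, "nonexistent", [1.0], feed_psd)
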