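import math

import pytest

from nanotwin.constants import K_BOLTZMANN, N_AVOGADRO, R_GAS
from nanotwin import properties as P


@pytest.fixture
def api():
    return P.ApiRecord(
        name="synthetic-api",
        mr=600.0,
        vm=4e-4,
        s0=1e-8,
        segments=P.SegmentParams(m_seg=20.0, sigma=3.5, u_over_k=250.0),
        delta_interlayer=5e-10,
    )


@pytest.fixture
def stabilizer():
    return P.StabilizerRecord(
        name="synthetic-stab",
        mw=8400.0,
        density=951.0,
        zeta_potential=-17.0,
        segments=P.SegmentParams(m_seg=400.0, sigma=3.1, u_over_k=200.0),
    )


class TestCombiningRules:
    def test_arithmetic_mean_of_diameters(self):
        sigma_ab, _ = P.lorentz_berthelot(2.89, 3.34, 206.74, 192.72)
        assert sigma_ab == pytest.approx(3.115)

    def test_geometric_mean_of_energies(self):
        _, eps_ab = P.lorentz_berthelot(2.89, 3.34, 206.74, 192.72)
        assert eps_ab == pytest.approx(math.sqrt(206.74 * 192.72))
        assert eps_ab == pytest.approx(199.6, abs=0.05)

    def test_identity_on_equal_components(self):
        assert P.lorentz_berthelot(3.0, 3.0, 150.0, 150.0) == (3.0, 150.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            P.lorentz_berthelot(-1.0, 3.0, 150.0, 150.0)


class TestCopolymerSegments:
    @pytest.mark.parametrize(
        "mw,group,expected",
        [(1000.0, "EO", 52.0), (1000.0, "PO", 37.0), (0.0, "PO", 0.0)],
    )
    def test_group_contributions(self, mw, group, expected):
        assert P.copolymer_segments(mw, group) == pytest.approx(expected)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            P.copolymer_segments(1000.0, "XX")

    def test_copolymer_combines_mass_fractions(self):
        seg = P.copolymer_params(1000.0, eo_mass_fraction=0.8)
        assert seg.m_seg == pytest.approx(0.8 * 52.0 + 0.2 * 37.0)
        assert seg.sigma == pytest.approx(3.115)


class TestSurfaceTension:
    def test_bracket_vanishes_at_reference_solubility(self):
        s0 = 55.6 * math.exp(-5.0)
        assert P.surface_tension(298.15, 9.51e5, 600.0, s0) == pytest.approx(0.0)

    def test_linear_in_temperature(self):
        g1 = P.surface_tension(300.0, 9.51e5, 600.0, 1e-8)
        g2 = P.surface_tension(600.0, 9.51e5, 600.0, 1e-8)
        assert g2 == pytest.approx(2 * g1)

    def test_hand_evaluation(self):
        # direct scalar evaluation of the correlation
        t, rho, mr, s0 = 298.15, 9.51e5, 600.0, 1e-8
        expected = (
            -0.33
            * K_BOLTZMANN
            * t
            * (N_AVOGADRO * rho / mr) ** (2 / 3)
            * (math.log(s0 / 55.6) + 5.0)
        )
        assert P.surface_tension(t, rho, mr, s0) == pytest.approx(expected, rel=1e-12)
        assert expected > 0  # sparingly soluble -> positive surface tension

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(ValueError):
            P.surface_tension(298.15, 9.51e5, 600.0, 0.0)


class TestGibbsSurface:
    def test_decays_with_radius(self):
        small = P.gibbs_surface(1e-2, 4e-4, 1e-7)
        large = P.gibbs_surface(1e-2, 4e-4, 1e-4)
        assert abs(large) < abs(small) / 100

    def test_zero_at_radius_equal_to_curvature_parameter(self):
        c = P.curvature_parameter(4e-4)
        assert P.gibbs_surface(1e-2, 4e-4, c) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation(self):
        gamma, vm, r = 1e-2, 4e-4, 1e-7
        c = 1.5 * (vm / N_AVOGADRO) ** (1 / 3)
        expected = (2 * gamma * vm / r) * (1 - c / r)
        assert P.gibbs_surface(gamma, vm, r) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            P.gibbs_surface(1e-2, 4e-4, 0.0)


class TestGibbsInterface:
    def test_hand_evaluation(self, api, stabilizer):
        gamma, vm, r = 1e-2, 4e-4, 1e-7
        sigma_cross = 0.5 * (3.5 + 3.1) * 1e-10
        eps_cross = math.sqrt(250.0 * 200.0) * K_BOLTZMANN
        expected = (
            1.7
            * (250.0 * K_BOLTZMANN)
            * (3.5e-10)
            * 951.0
            / (5e-10 * sigma_cross * eps_cross * 400.0)
            * gamma
            * vm
            / r
        )
        value = P.gibbs_interface(api, stabilizer, gamma, vm, r)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_inverse_in_segment_number(self, api, stabilizer):
        import dataclasses

        base = P.gibbs_interface(api, stabilizer, 1e-2, 4e-4, 1e-7)
        heavy = dataclasses.replace(
            stabilizer, segments=P.SegmentParams(4000.0, 3.1, 200.0)
        )
        tenfold = P.gibbs_interface(api, heavy, 1e-2, 4e-4, 1e-7)
        assert tenfold == pytest.approx(base / 10.0, rel=1e-12)

    def test_vanishes_without_stabilizer_density(self, api, stabilizer):
        import dataclasses

        airy = dataclasses.replace(stabilizer, density=1e-300)
        assert P.gibbs_interface(api, airy, 1e-2, 4e-4, 1e-7) == pytest.approx(
            0.0, abs=1e-280
        )

    def test_homogeneous_in_surface_tension(self, api, stabilizer):
        one = P.gibbs_interface(api, stabilizer, 1e-2, 4e-4, 1e-7)
        two = P.gibbs_interface(api, stabilizer, 2e-2, 4e-4, 1e-7)
        assert two == pytest.approx(2 * one, rel=1e-12)
        # the surface term scales identically
        assert P.gibbs_surface(2e-2, 4e-4, 1e-7) == pytest.approx(
            2 * P.gibbs_surface(1e-2, 4e-4, 1e-7), rel=1e-12
        )


class TestSolubilityEnhancement:
    def test_zero_energy_gives_unity(self):
        for t in (250.0, 298.15, 400.0):
            assert P.solubility_enhancement(0.0, t) == 1.0

    def test_unit_exponent(self):
        t = 298.15
        assert P.solubility_enhancement(R_GAS * t, t) == pytest.approx(math.e)

    def test_closed_form_doubling(self):
        t = 310.0
        assert P.solubility_enhancement(2 * R_GAS * t * math.log(2), t) == pytest.approx(4.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            P.solubility_enhancement(100.0, 0.0)


class TestRanking:
    def test_case_study_records_select_poloxamer_188(self):
        candidates = [("HPC-SL", 0.0019), ("Poloxamer-407", 0.0039), ("Poloxamer-188", 0.0056)]
        ranked, selected = P.rank_stabilizers(candidates)
        assert selected == "Poloxamer-188"
        assert [name for name, _ in ranked] == [
            "Poloxamer-188",
            "Poloxamer-407",
            "HPC-SL",
        ]

    def test_gmi_order_matches_zeta_magnitude_order(self):
        from nanotwin import fixtures

        rows = sorted(fixtures.STABILIZERS, key=lambda r: -r["gmi"])
        zetas = [abs(r["zeta_potential"]) for r in rows]
        assert zetas == sorted(zetas, reverse=True)
        assert zetas == [17.0, 13.7, 11.7]

    def test_output_is_permutation_with_nonincreasing_gmi(self):
        candidates = [("a", 1.0), ("b", 3.0), ("c", 2.0)]
        ranked, _ = P.rank_stabilizers(candidates)
        assert sorted(ranked) == sorted(candidates)
        values = [g for _, g in ranked]
        assert values == sorted(values, reverse=True)

    def test_tie_breaks_lexicographically(self):
        _, selected = P.rank_stabilizers([("zeta", 1.0), ("alpha", 1.0)])
        assert selected == "alpha"

    def test_single_and_empty(self):
        assert P.rank_stabilizers([("only", 0.5)])[1] == "only"
        with pytest.raises(ValueError):
            P.rank_stabilizers([])


class TestMaterialsIO:
    def test_yaml_roundtrip_and_report(self, tmp_path):
        materials = tmp_path / "materials.yaml"
        materials.write_text(
            """
api:
  name: synthetic-api
  mr: 600.0
  vm: 4.0e-4
  s0: 1.0e-8
  delta_interlayer: 5.0e-10
  segments: {m_seg: 20.0, sigma: 3.5, u_over_k: 250.0}
stabilizers:
  - name: A
    mw: 8400.0
    density: 951.0
    zeta_potential: -17.0
    gmi_reference: 0.0056
  - name: B
    mw: 12600.0
    density: 954.0
    zeta_potential: -13.7
    gmi_reference: 0.0039
"""
        )
        api, stabs = P.load_materials(materials)
        assert api.name == "synthetic-api"
        assert len(stabs) == 2
        report = P.ranking_report(stabs, tmp_path / "rank.csv")
        assert report.iloc[0]["name"] == "A"
        assert bool(report.iloc[0]["selected"])
        assert (tmp_path / "rank.csv").exists()

    def test_report_requires_reference_values(self):
        record = P.StabilizerRecord(name="X", mw=1.0, density=1.0, zeta_potential=0.0)
        with pytest.raises(ValueError):
            P.ranking_report([record])


def test_linear_temperature_property():
    rho = P.LinearTProperty(a=1000.0, b=-0.5, t_ref=298.15)
    assert rho(298.15) == 1000.0
    assert rho(308.15) == pytest.approx(995.0)
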