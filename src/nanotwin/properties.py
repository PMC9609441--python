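"""Stabilizer screening by surface / interfacial Gibbs energy.

Coating a drug nanocrystal with a polymeric stabilizer lowers the Gibbs
energy of dissolution.  The size-reduction contribution splits into a
surface term ``Gms`` (the classical Ostwald-Freundlich curvature term) and
an interfacial term ``Gmi`` produced by the semi-solid stabilizer layer.
Their sum ``GEE`` sets the solubility enhancement ratio through

    GEE = Gms + Gmi = R T ln(K2 / K1),

where ``K2/K1`` is the ratio of dissolution equilibrium coefficients after
and before comminution.  The stabilizer whose interfacial term dominates
the Gibbs-energy decrease is the one selected; experimentally this ranking
tracks the magnitude of the zeta potential.

Molecular inputs are PC-SAFT segment parameters (segment number ``m``,
segment diameter ``sigma``, pair-potential depth ``u/k``).  Cross
API-stabilizer parameters come from the Lorentz-Berthelot combining rules:
arithmetic mean for diameters, geometric mean for energies.  Pair-potential
depths are stored as ``u/k`` in Kelvin and converted to Joules through the
Boltzmann constant at the point of use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .constants import (
    ANGSTROM,
    K_BOLTZMANN,
    N_AVOGADRO,
    R_GAS,
    WATER_MOLARITY,
)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentParams:
    """PC-SAFT segment parameters of one component.

    m_seg: segments per chain (dimensionless)
    sigma: segment diameter (Angstrom)
    u_over_k: pair-potential depth over the Boltzmann constant (K)
    """

    m_seg: float
    sigma: float
    u_over_k: float

    def __post_init__(self):
        for name in ("m_seg", "sigma", "u_over_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SegmentParams.{name} must be positive")

    @property
    def epsilon_joule(self) -> float:
        """Pair-potential depth in Joules (u/k times k_B)."""
        return self.u_over_k * K_BOLTZMANN


@dataclass(frozen=True)
class StabilizerRecord:
    name: str
    mw: float  # g mol^-1
    density: float  # kg m^-3
    zeta_potential: float  # mV
    segments: Optional[SegmentParams] = None  # needed only for Gmi recomputation
    gmi_reference: Optional[float] = None  # units as printed in the source table

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("molar mass must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ApiRecord:
    name: str
    mr: float  # g mol^-1
    vm: float  # m^3 mol^-1
    s0: float  # mol L^-1, aqueous solubility of the pure API
    segments: SegmentParams
    delta_interlayer: float  # m, distance between molecular layers

    def __post_init__(self):
        if self.vm <= 0:
            raise ValueError("molar volume must be positive")
        if self.s0 <= 0:
            raise ValueError("solubility must be positive")


@dataclass(frozen=True)
class GibbsResult:
    gamma: float  # N m^-1
    c_param: float  # m
    gms: float  # J mol^-1
    gmi: float  # J mol^-1
    gee: float  # J mol^-1
    k_ratio: float  # dimensionless
    temperature: float  # K
    radius: float  # m


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def lorentz_berthelot(
    sigma_a: float, sigma_b: float, eps_a: float, eps_b: float
) -> tuple[float, float]:
    """Cross segment diameter and energy by the Lorentz-Berthelot rules.

    Diameter: arithmetic mean.  Energy: geometric mean.  Units are
    preserved (the energy pair may be in K or J, as long as both agree).
    """
    if min(sigma_a, sigma_b, eps_a, eps_b) <= 0:
        raise ValueError("combining-rule inputs must be positive")
    return 0.5 * (sigma_a + sigma_b), math.sqrt(eps_a * eps_b)


def copolymer_segments(mw_total: float, group: str) -> float:
    """Segment-number contribution of one repeat-unit group.

    The segment number of a poly(ethylene oxide) / poly(propylene oxide)
    chain scales linearly with its molar mass: 0.052/g for EO, 0.037/g
    for PO.  For a copolymer, call once per group with the group's share
    ``mw_total = mass_fraction * MW`` and sum the contributions.
    """
    if mw_total < 0:
        raise ValueError("molar mass must be non-negative")
    coefficients = {"EO": 0.052, "PO": 0.037}
    try:
        return coefficients[group] * mw_total
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected 'EO' or 'PO'") from None


def copolymer_params(
    mw: float, eo_mass_fraction: float
) -> SegmentParams:
    """PC-SAFT parameters of an EO/PO copolymer.

    Segment number: sum of per-group contributions weighted by the mass
    fraction of each group.  Cross diameter and energy: Lorentz-Berthelot
    combination of the EO and PO group parameters.
    """
    if not 0.0 <= eo_mass_fraction <= 1.0:
        raise ValueError("eo_mass_fraction must be in [0, 1]")
    m_seg = copolymer_segments(mw * eo_mass_fraction, "EO") + copolymer_segments(
        mw * (1.0 - eo_mass_fraction), "PO"
    )
    sigma, u_over_k = lorentz_berthelot(2.89, 3.34, 206.74, 192.72)
    return SegmentParams(m_seg=m_seg, sigma=sigma, u_over_k=u_over_k)


def surface_tension(temperature: float, density: float, mr: float, s0: float) -> float:
    """Particle surface tension from molecular density and solubility.

    gamma = -0.33 kB T (NA rho / Mr)^(2/3) [ln(S0/55.6) + 5]

    temperature in K, density in g m^-3, mr in g mol^-1, s0 in mol L^-1
    (55.6 is the molarity of pure water).  Returns N m^-1.  For sparingly
    soluble drugs the bracket is negative, so gamma is positive.
    """
    if min(temperature, density, mr) <= 0:
        raise ValueError("temperature, density and molar mass must be positive")
    if s0 <= 0:
        raise ValueError("solubility must be positive (log undefined otherwise)")
    number_density = N_AVOGADRO * density / mr  # molecules per m^3
    return (
        -0.33
        * K_BOLTZMANN
        * temperature
        * number_density ** (2.0 / 3.0)
        * (math.log(s0 / WATER_MOLARITY) + 5.0)
    )


def curvature_parameter(vm: float) -> float:
    """C = 1.5 (Vm / NA)^(1/3): molecular length scale of the API (m)."""
    if vm <= 0:
        raise ValueError("molar volume must be positive")
    return 1.5 * (vm / N_AVOGADRO) ** (1.0 / 3.0)


def gibbs_surface(gamma: float, vm: float, radius: float) -> float:
    """Surface Gibbs-energy term Gms = (2 gamma Vm / r)(1 - C/r), J mol^-1."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if vm <= 0:
        raise ValueError("molar volume must be positive")
    c = curvature_parameter(vm)
    return (2.0 * gamma * vm / radius) * (1.0 - c / radius)


def gibbs_interface(
    api: ApiRecord,
    stab: StabilizerRecord,
    gamma: float,
    vm: float,
    radius: float,
) -> float:
    """Interfacial Gibbs-energy term of the stabilizer coating (J mol^-1).

    Gmi = 1.7 * eps_API * sigma_API * rho_stab
          / (Delta * sigma_cross * eps_cross * m_stab) * gamma * Vm / r

    with the cross parameters from the Lorentz-Berthelot rules.  Energies
    enter as Joules (u/k converted through k_B); the energy and diameter
    ratios are dimensionless, so the term inherits the J mol^-1 scale of
    gamma*Vm/r times the dimensionless prefactor rho_stab-dependent group.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if stab.segments is None:
        raise ValueError(f"stabilizer {stab.name!r} has no segment parameters")
    if stab.segments.m_seg <= 0:
        raise ValueError("stabilizer segment number must be positive")
    sigma_cross_A, u_cross_K = lorentz_berthelot(
        api.segments.sigma,
        stab.segments.sigma,
        api.segments.u_over_k,
        stab.segments.u_over_k,
    )
    eps_api = api.segments.epsilon_joule
    sigma_api = api.segments.sigma * ANGSTROM
    sigma_cross = sigma_cross_A * ANGSTROM
    eps_cross = u_cross_K * K_BOLTZMANN
    prefactor = (
        1.7
        * eps_api
        * sigma_api
        * stab.density
        / (api.delta_interlayer * sigma_cross * eps_cross * stab.segments.m_seg)
    )
    return prefactor * gamma * vm / radius


def solubility_enhancement(gee: float, temperature: float) -> float:
    """K2/K1 = exp(GEE / (R T)): solubility gain from the Gibbs-energy drop.

    Saturates to ``inf`` (with a numpy overflow warning suppressed) for
    Gibbs energies far beyond the physical range.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    import numpy as np

    with np.errstate(over="ignore"):
        return float(np.exp(gee / (R_GAS * temperature)))


def gibbs_analysis(
    api: ApiRecord,
    stab: StabilizerRecord,
    temperature: float,
    radius: float,
    density: Optional[float] = None,
) -> GibbsResult:
    """Full surface + interface Gibbs-energy budget for one API/stabilizer pair.

    ``density`` (g m^-3) defaults to the API molar mass over molar volume.
    """
    if density is None:
        density = api.mr / api.vm  # g m^-3 since mr in g/mol, vm in m^3/mol
    gamma = surface_tension(temperature, density, api.mr, api.s0)
    gms = gibbs_surface(gamma, api.vm, radius)
    gmi = gibbs_interface(api, stab, gamma, api.vm, radius)
    gee = gms + gmi
    return GibbsResult(
        gamma=gamma,
        c_param=curvature_parameter(api.vm),
        gms=gms,
        gmi=gmi,
        gee=gee,
        k_ratio=solubility_enhancement(gee, temperature),
        temperature=temperature,
        radius=radius,
    )


def rank_stabilizers(candidates: Sequence[tuple[str, float]]) -> tuple[list[tuple[str, float]], str]:
    """Order stabilizer candidates by interfacial Gibbs energy.

    Returns the list sorted by descending Gmi and the selected (maximum
    Gmi) name.  Ties break lexicographically by name.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no stabilizer candidates supplied")
    ranked = sorted(candidates, key=lambda item: (-item[1], item[0]))
    return ranked, ranked[0][0]


# ---------------------------------------------------------------------------
# tabulated temperature-dependent properties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTProperty:
    """Property varying linearly with temperature: value = a + b*(T - T_ref).

    Stands in for equation-of-state predictions of density and heat
    capacity, which enter this package as tabulated inputs.
    """

    a: float
    b: float = 0.0
    t_ref: float = 298.15

    def __call__(self, temperature: float) -> float:
        return self.a + self.b * (temperature - self.t_ref)


# ---------------------------------------------------------------------------
# materials I/O and the ranking report
# ---------------------------------------------------------------------------


def _segments_from_mapping(data: dict) -> SegmentParams:
    return SegmentParams(
        m_seg=float(data["m_seg"]),
        sigma=float(data["sigma"]),
        u_over_k=float(data["u_over_k"]),
    )


def load_materials(path) -> tuple[Optional[ApiRecord], list[StabilizerRecord]]:
    """Read API and stabilizer records from a YAML/JSON materials file.

    Schema::

        api:                      # optional
          name, mr, vm, s0, delta_interlayer,
          segments: {m_seg, sigma, u_over_k}
        stabilizers:
          - name, mw, density, zeta_potential,
            gmi_reference,        # optional
            segments: {m_seg, sigma, u_over_k}
    """
    with open(path) as handle:
        data = yaml.safe_load(handle)
    api = None
    if data.get("api"):
        block = data["api"]
        api = ApiRecord(
            name=block["name"],
            mr=float(block["mr"]),
            vm=float(block["vm"]),
            s0=float(block["s0"]),
            segments=_segments_from_mapping(block["segments"]),
            delta_interlayer=float(block["delta_interlayer"]),
        )
    stabilizers = []
    for block in data.get("stabilizers", []):
        stabilizers.append(
            StabilizerRecord(
                name=block["name"],
                mw=float(block["mw"]),
                segments=(
                    _segments_from_mapping(block["segments"])
                    if block.get("segments")
                    else None
                ),
                density=float(block["density"]),
                zeta_potential=float(block["zeta_potential"]),
                gmi_reference=(
                    float(block["gmi_reference"])
                    if block.get("gmi_reference") is not None
                    else None
                ),
            )
        )
    return api, stabilizers


def ranking_report(records: Sequence[StabilizerRecord], path=None) -> pd.DataFrame:
    """Rank stabilizer records by their reference Gmi and optionally write CSV.

    Records lacking ``gmi_reference`` are rejected: ranking needs a common
    Gmi scale.
    """
    missing = [r.name for r in records if r.gmi_reference is None]
    if missing:
        raise ValueError(f"records without gmi_reference: {missing}")
    ranked, selected = rank_stabilizers([(r.name, r.gmi_reference) for r in records])
    by_name = {r.name: r for r in records}
    frame = pd.DataFrame(
        [
            {
                "name": name,
                "gmi": gmi,
                "density_kg_m3": by_name[name].density,
                "zeta_potential_mV": by_name[name].zeta_potential,
                "selected": name == selected,
            }
            for name, gmi in ranked
        ]
    )
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False)
    return frame
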