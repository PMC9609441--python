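"""Bundled experimental fixtures for the Itraconazole / Poloxamer-188 case study.

The package ships four small data tables transcribed from the published
wet-milling / spray-drying study it models:

* ``EO_PO_GROUPS`` -- PC-SAFT group parameters for the ethylene-oxide and
  propylene-oxide repeat units of the poloxamer copolymers.  The segment
  number scales linearly with total molar mass (coefficient per gram).
* ``MILLING_D50`` -- three replicate wet-milling runs of Itraconazole with
  Poloxamer-188, sampled as D50 (um) at six times (s).
* ``PROCESS_DEFAULTS`` -- mill and spray-dryer operating inputs.
* ``STABILIZERS`` -- interfacial Gibbs-energy records, densities and zeta
  potentials of the three stabilizer candidates.  The Gmi column is stored
  as printed (units not stated in the source); it is used for ranking only.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: PC-SAFT parameters of the EO and PO groups.  m_seg per gram of total
#: molar mass; sigma in Angstrom; u/k in Kelvin.
EO_PO_GROUPS = {
    "EO": {"m_seg_per_mw": 0.052, "sigma_A": 2.89, "u_over_k_K": 206.74},
    "PO": {"m_seg_per_mw": 0.037, "sigma_A": 3.34, "u_over_k_K": 192.72},
}

#: Replicate milling experiments: D50 (um) vs time (s).
MILLING_D50_TIMES_S = [360.0, 720.0, 1440.0, 2160.0, 2880.0, 3600.0]
MILLING_D50_UM = {
    "experiment_1": [1.39, 0.874, 0.784, 0.522, 0.467, 0.305],
    "experiment_2": [1.31, 0.792, 0.742, 0.501, 0.434, 0.297],
    "experiment_3": [1.37, 0.846, 0.783, 0.520, 0.436, 0.301],
}

#: Mill and spray-dryer operating inputs (value, unit).
PROCESS_DEFAULTS = {
    "water_quantity": (9.0, "mL"),
    "api_content": (0.5, "g"),
    "stabilizer_content": (0.25, "g"),
    "mannitol_content": (1.0, "g"),
    "initial_d50": (1.5, "um"),
    "grinding_time": (1.0, "h"),
    "rotor_speed": (600.0, "rpm"),
    "rotor_diameter": (40.0, "mm"),
    "mill_volume": (48.0, "mL"),
    "air_temperature": (110.0, "degC"),
    "air_flow": (800.0, "L/h"),
    "air_pressure": (5.0, "bar"),
    "chamber_volume": (5.0, "L"),
    "drying_time": (1.0, "h"),
    "final_product_d50": (10.0, "um"),  # reported output, not an input
}

#: Stabilizer records: interfacial Gibbs energy (as printed), density
#: (kg m^-3) and zeta potential (mV).
STABILIZERS = [
    {"name": "HPC-SL", "gmi": 0.0019, "density": 1320.0, "zeta_potential": -11.7},
    {"name": "Poloxamer-407", "gmi": 0.0039, "density": 954.0, "zeta_potential": -13.7},
    {"name": "Poloxamer-188", "gmi": 0.0056, "density": 951.0, "zeta_potential": -17.0},
]


def milling_training_frame() -> pd.DataFrame:
    """Pooled replicate D50(t) data as a tidy frame.

    Columns: ``time_s``, ``d50_um``, ``experiment_id``.  The three replicates
    are treated as independent samples of the same comminution profile.
    """
    rows = []
    for exp, values in MILLING_D50_UM.items():
        for t, d in zip(MILLING_D50_TIMES_S, values):
            rows.append({"time_s": t, "d50_um": d, "experiment_id": exp})
    return pd.DataFrame(rows).sort_values(
        ["time_s", "experiment_id"], ignore_index=True
    )


def stabilizer_frame() -> pd.DataFrame:
    return pd.DataFrame(STABILIZERS)


def group_parameter_frame() -> pd.DataFrame:
    rows = [{"group": g, **p} for g, p in EO_PO_GROUPS.items()]
    return pd.DataFrame(rows)


def process_defaults_frame() -> pd.DataFrame:
    rows = [
        {"parameter": k, "value": v, "unit": u}
        for k, (v, u) in PROCESS_DEFAULTS.items()
    ]
    return pd.DataFrame(rows)


def export_fixtures(outdir) -> list[Path]:
    """Write the four fixture tables as CSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in [
        ("table1_group_parameters.csv", group_parameter_frame()),
        ("table2_milling_d50.csv", milling_training_frame()),
        ("table3_process_defaults.csv", process_defaults_frame()),
        ("table4_stabilizers.csv", stabilizer_frame()),
    ]:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
    return written
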