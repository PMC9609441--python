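"""End-to-end digital-twin thread for solidified nanosuspension manufacture.

Chains the four lifecycle stages: (a) stabilizer selection from the
interfacial Gibbs-energy records, (b) augmentation of the discrete
experimental D50(t) samples into a dense reference profile, (c) breakage
model fitting and wet-milling simulation, and (d) spray-drying
simulation.  Each stage persists its outputs (CSV/JSON) under the
configured output directory and is summarized in a machine-parseable
thread report; a failing stage is flagged and downstream stages are
skipped.  The run is deterministic given the global seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fixtures, properties
from .config import RunConfig
from .milling import (
    MaterialMechanics,
    SizeGrid,
    fit_all_families,
    lognormal_psd,
    simulate_milling,
)
from .spraydrying import DryerConfig, simulate_spraydry
from .surrogate import augment_profile, polyfit_profile, train_ann

logger = logging.getLogger(__name__)

#: JSON-schema-like sketch of the thread report, kept in-package so reports
#: can be validated without a network schema registry.
REPORT_SCHEMA = {
    "type": "object",
    "required": ["seed", "stages"],
    "properties": {
        "seed": {"type": "integer"},
        "stages": {
            "type": "object",
            "properties": {
                name: {
                    "type": "object",
                    "required": ["status"],
                }
                for name in ("stabilizer", "augment", "milling", "spraydry")
            },
        },
    },
}


def validate_report(report: dict) -> None:
    """Check a thread report against the bundled schema sketch."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for name, stage in report["stages"].items():
        if "status" not in stage:
            raise ValueError(f"stage {name!r} missing status")
        if stage["status"] not in {"ok", "failed", "skipped", "disabled"}:
            raise ValueError(f"stage {name!r} has invalid status {stage['status']!r}")


def _stage_stabilizer(config: RunConfig, outdir: Path) -> dict:
    if config.materials_file:
        _, records = properties.load_materials(config.materials_file)
    else:
        records = [
            properties.StabilizerRecord(
                name=row["name"],
                mw={"HPC-SL": 100000.0, "Poloxamer-407": 12600.0, "Poloxamer-188": 8400.0}[
                    row["name"]
                ],
                density=row["density"],
                zeta_potential=row["zeta_potential"],
                gmi_reference=row["gmi"],
            )
            for row in fixtures.STABILIZERS
        ]
    frame = properties.ranking_report(records, outdir / "stabilizer_ranking.csv")
    selected = frame.loc[frame["selected"], "name"].iloc[0]
    return {
        "status": "ok",
        "selected": selected,
        "ranking": frame["name"].tolist(),
        "gmi_provenance": "fixture" if not config.materials_file else "materials_file",
    }


def _stage_augment(config: RunConfig, outdir: Path) -> dict:
    data = fixtures.milling_training_frame()
    data.to_csv(outdir / "training_data.csv", index=False)
    sur = config.surrogate
    ann = train_ann(
        data,
        layer_sizes=(1, *sur.hidden_layers, 1),
        seed=config.seed,
        epochs=sur.epochs,
        learning_rate=sur.learning_rate,
    )
    ann.to_json(outdir / "ann_model.json")
    poly = polyfit_profile(data, order=sur.polynomial_order)
    t_grid = np.linspace(0.0, data["time_s"].max(), sur.n_dense)
    profile = augment_profile(poly, t_grid, allow_extrapolation=True)
    profile.to_frame().to_csv(outdir / "dense_reference.csv", index=False)
    ann_profile = augment_profile(
        ann, np.linspace(data["time_s"].min(), data["time_s"].max(), sur.n_dense)
    )
    ann_profile.to_frame().to_csv(outdir / "ann_profile.csv", index=False)
    return {
        "status": "ok",
        "ann_mse_percent": ann.mse_percent,
        "polynomial_mse_percent": poly.mse_percent,
        "polynomial_order": sur.polynomial_order,
        "reference_profile": "dense_reference.csv",
        "reference_provenance": "computed",
    }


def _stage_milling(config: RunConfig, outdir: Path, reference: pd.DataFrame) -> dict:
    mill = config.mill
    grid = SizeGrid.geometric(
        x_max=mill.grid_x_max_um * 1e-6,
        x_min=mill.grid_x_min_um * 1e-6,
        n_bins=mill.grid_n_bins,
    )
    psd0 = lognormal_psd(grid, median=mill.initial_d50_um * 1e-6, gsd=mill.initial_gsd)
    mech = MaterialMechanics(mill_volume=mill.mill_volume_mL * 1e-6)
    started = time.perf_counter()
    results = fit_all_families(
        reference,
        mech=mech,
        psd0=psd0,
        multistart_seed=config.seed,
        n_starts=config.fit.n_starts,
        max_nfev=config.fit.max_nfev,
        b_exponent=config.fit.b_exponent,
    )
    elapsed = time.perf_counter() - started
    fits = {}
    best_name, best = None, None
    for family in config.fit.families:
        result = results[family]
        result.to_json(outdir / f"fit_{family}.json")
        fits[family] = {
            "mse_percent": result.mse_percent,
            "converged": result.converged,
            "n_evaluations": result.n_evaluations,
        }
        if best is None or result.mse_percent < best.mse_percent:
            best_name, best = family, result
    trajectory = simulate_milling(
        psd0, best.model, mech, t_end=mill.grinding_time_h * 3600.0, dt_out=60.0
    )
    trajectory.to_frame().to_csv(outdir / "milling_trajectory.csv", index=False)
    pd.DataFrame(
        {"time_s": trajectory.times, "d50_um": trajectory.d50_profile}
    ).to_csv(outdir / "milling_d50.csv", index=False)
    ranking = sorted(fits, key=lambda k: fits[k]["mse_percent"])
    fits["seconds_total"] = elapsed
    return {
        "status": "ok",
        "fits": fits,
        "ranking": ranking,
        "best_family": best_name,
        "final_d50_um": float(trajectory.d50_profile[-1]),
    }


def _stage_spraydry(config: RunConfig, outdir: Path, psd=None) -> dict:
    block = config.dryer
    dryer = DryerConfig(
        air_temperature=block.air_temperature_C,
        air_flow=block.air_flow_L_h,
        air_pressure=block.air_pressure_bar,
        chamber_volume=block.chamber_volume_L,
        drying_time=block.drying_time_h,
        residence_time=block.residence_time_s,
        inlet_humidity=block.inlet_humidity,
        heat_transfer_coeff=block.heat_transfer_coeff,
        critical_moisture=block.critical_moisture,
        droplet_median=block.droplet_median_um * 1e-6,
        droplet_gsd=block.droplet_gsd,
        n_droplet_bins=block.n_droplet_bins,
        n_solids_bins=block.n_solids_bins,
        n_steps=block.n_steps,
        bdf_order=block.bdf_order,
    )
    result = simulate_spraydry(dryer, psd)
    result.gas_frame().to_csv(outdir / "spraydry_gas.csv", index=False)
    return {
        "status": "ok",
        "mean_final_moisture": result.mean_final_moisture,
        "outlet_humidity": float(result.outlet_humidity[-1]),
        "gas_temperature_K": float(result.gas_temperature[-1]),
        "water_closure": result.water_closure,
        "enthalpy_closure": result.enthalpy_closure,
    }


def run_thread(config: Optional[RunConfig] = None, outdir=None) -> dict:
    """Execute the digital-twin thread; returns the report dict.

    Stage order: stabilizer -> augment -> milling -> spraydry.  Milling
    requires the augment stage (it fits against the dense reference);
    spray drying uses the milled PSD when milling ran, else the feed
    defaults.  The report is written as ``thread_report.json``.
    """
    if config is None:
        config = RunConfig()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": {}}
    reference = None
    psd = None

    stages = config.stages
    for name, enabled in (
        ("stabilizer", stages.stabilizer),
        ("augment", stages.augment),
        ("milling", stages.milling),
        ("spraydry", stages.spraydry),
    ):
        if not enabled:
            report["stages"][name] = {"status": "disabled"}
            continue
        if name == "milling" and reference is None:
            report["stages"][name] = {
                "status": "skipped",
                "reason": "no dense reference (augment stage did not run)",
            }
            continue
        try:
            logger.info("thread stage %s starting", name)
            if name == "stabilizer":
                report["stages"][name] = _stage_stabilizer(config, outdir)
            elif name == "augment":
                report["stages"][name] = _stage_augment(config, outdir)
                reference = pd.read_csv(outdir / "dense_reference.csv")
            elif name == "milling":
                report["stages"][name] = _stage_milling(config, outdir, reference)
            else:
                report["stages"][name] = _stage_spraydry(config, outdir, psd)
        except Exception as exc:  # flag and skip downstream
            logger.exception("thread stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            for later, _ in (
                ("augment", None),
                ("milling", None),
                ("spraydry", None),
            ):
                if later not in report["stages"]:
                    report["stages"][later] = {
                        "status": "skipped",
                        "reason": f"upstream stage {name} failed",
                    }
            break
    validate_report(report)
    (outdir / "thread_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
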