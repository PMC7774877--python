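"""End-to-end pipeline: simulate -> characterize -> compare (+ stiffness).

``run_pipeline`` executes the full material-qualification workflow from a
flat key-value configuration and writes all report tables, each embedding the
config digest and seed so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .compare import build_comparison_table, build_stiffness_summary
from .core import PhysicalConstants, TissueReference
from .elasticity import fit_youngs_modulus, generate_stress_strain
from .estimate import GateConfig, characterize
from .io import config_digest, read_materials_table, write_report_csv
from .simulate import SimulationConfig, generate_ensemble_pair

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_CONFIG", "characterize_materials"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


DEFAULT_CONFIG = {
    "out_dir": "results",
    "seed": 20201216,
    "n_repeats": 100,
    "noise_snr": 40.0,
    "use_printed_table": False,   # True: skip simulation, compare the packaged table
    "materials_table": None,      # optional path overriding the packaged table
    "stiffness_table": None,      # optional path overriding the packaged table
    "stiffness_noise": 0.02,
    "stiffness_repeats": 20,
    "fit_window_low": 0.02,
    "fit_window_high": 0.10,
}


def characterize_materials(
    seed: int,
    n_repeats: int = 100,
    noise_snr: float = 40.0,
    constants: PhysicalConstants | None = None,
    gate_config: GateConfig = GateConfig(),
) -> pd.DataFrame:
    """Simulate and characterize every packaged material.

    Returns one row per material with the estimated velocity, attenuation,
    backscatter, density-derived impedance, interface coefficients and the
    per-repeat dispersions, plus the ground truth used by the simulator.
    """
    constants = constants or PhysicalConstants()
    seeds = np.random.SeedSequence(seed).generate_state(len(datasets.simulation_samples()))
    rows = []
    for child_seed, sample in zip(seeds, datasets.simulation_samples()):
        config = SimulationConfig(
            n_repeats=n_repeats,
            noise_snr=noise_snr,
            rng_seed=int(child_seed % (2**31)),
        )
        reference, sample_in, _ = generate_ensemble_pair(sample, config, constants)
        props = characterize(sample, reference, sample_in, constants, gate_config)
        rows.append(
            {
                "material": props.name,
                "velocity_m_s": props.c_s,
                "velocity_sd_m_s": props.c_s_sd,
                "attenuation_db_cm": props.alpha,
                "attenuation_sd_db_cm": props.alpha_sd,
                "backscatter_db": props.u,
                "density_kg_m3": props.rho,
                "impedance_1e6": props.Z / 1e6,
                "r": props.r,
                "t": props.t,
                "R": props.R,
                "T": props.T,
                "true_velocity_m_s": sample.true_velocity,
                "true_attenuation_db_cm": sample.true_attenuation_at_f0,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict | None = None) -> dict:
    """Run simulate -> characterize -> compare -> stiffness and write reports.

    Returns a bundle with the output paths and the in-memory tables.  Any
    stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    constants = PhysicalConstants()
    tissue = TissueReference()
    bundle: dict = {"config": cfg, "config_hash": config_digest(cfg), "paths": {}}

    # --- acoustic characterization stage -----------------------------------
    try:
        if cfg["use_printed_table"]:
            if cfg["materials_table"]:
                acoustic = read_materials_table(cfg["materials_table"], kind="acoustic")
            else:
                acoustic = datasets.load_acoustic_table()
        else:
            acoustic = characterize_materials(
                seed=seed,
                n_repeats=int(cfg["n_repeats"]),
                noise_snr=float(cfg["noise_snr"]),
                constants=constants,
            )
    except FileNotFoundError as err:
        raise PipelineError(f"characterize stage: {err}") from err
    except Exception as err:
        raise PipelineError(f"characterize stage failed: {err}") from err
    path = out_dir / "acoustic_properties.csv"
    write_report_csv(path, acoustic.set_index("material"), cfg, seed)
    bundle["paths"]["acoustic"] = path
    bundle["acoustic"] = acoustic

    # --- tissue comparison stage -------------------------------------------
    try:
        report = build_comparison_table(acoustic, tissue, f0=constants.f0)
    except Exception as err:
        raise PipelineError(f"compare stage failed: {err}") from err
    path = out_dir / "tissue_comparison.csv"
    write_report_csv(path, report.table, cfg, seed)
    bundle["paths"]["comparison"] = path
    bundle["comparison"] = report

    # --- stiffness stage ----------------------------------------------------
    try:
        if cfg["stiffness_table"]:
            stiffness = read_materials_table(cfg["stiffness_table"], kind="stiffness")
        else:
            stiffness = datasets.load_stiffness_table()
        window = (float(cfg["fit_window_low"]), float(cfg["fit_window_high"]))
        rng = np.random.default_rng(seed)
        results = {}
        for row in stiffness.itertuples(index=False):
            records = generate_stress_strain(
                E_true=float(row.youngs_modulus_kpa) * 1e3,
                n_repeats=int(cfg["stiffness_repeats"]),
                noise_level=float(cfg["stiffness_noise"]),
                rng=rng,
            )
            results[row.material] = fit_youngs_modulus(
                records, fit_window=window,
                shore_A=float(getattr(row, "durometer_shore_a", np.nan)),
            )
        bands, ratios = build_stiffness_summary(results, tissue)
    except Exception as err:
        raise PipelineError(f"stiffness stage failed: {err}") from err
    path = out_dir / "stiffness_bands.csv"
    write_report_csv(path, bands, cfg, seed)
    bundle["paths"]["stiffness_bands"] = path
    path = out_dir / "softness_ratios.csv"
    write_report_csv(path, ratios, cfg, seed)
    bundle["paths"]["softness_ratios"] = path
    bundle["stiffness_bands"] = bands
    bundle["softness_ratios"] = ratios
    return bundle
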