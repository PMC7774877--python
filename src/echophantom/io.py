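"""Readers and writers: material tables, tension records, RF ensembles, reports.

Delimited-text dialect is pinned throughout: comma-separated, UTF-8, ``.``
decimal, mandatory header row.  RF ensembles persist to NumPy ``.npz``
containers carrying a JSON metadata header (sampling rate, condition, seed,
ground truth) alongside the trace array.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    Condition,
    InvalidInputError,
    PulseEchoEnsemble,
    SchemaError,
    StressStrainRecord,
)

__all__ = [
    "read_materials_table",
    "write_materials_table",
    "read_stress_strain",
    "save_ensemble",
    "load_ensemble",
    "write_report_csv",
    "config_digest",
]

_SCHEMAS = {
    "acoustic": {
        "required": {"material", "attenuation_db_cm"},
        "known": {
            "material",
            "density_kg_m3",
            "attenuation_db_cm",
            "velocity_m_s",
            "impedance_1e6",
            "backscatter_db",
        },
    },
    "stiffness": {
        "required": {"material", "youngs_modulus_kpa"},
        "known": {"material", "durometer_shore_a", "youngs_modulus_kpa"},
    },
}


def read_materials_table(path, kind: str = "acoustic") -> pd.DataFrame:
    """Read and validate a material-property table.

    ``kind`` selects the schema: ``acoustic`` requires ``material`` and
    ``attenuation_db_cm`` plus either ``impedance_1e6`` or the
    velocity/density pair; ``stiffness`` requires ``material`` and
    ``youngs_modulus_kpa``.  Unknown columns warn; missing required columns
    raise :class:`SchemaError` naming them.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"materials table not found: {path}")
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"{path}: empty file, expected a header row") from err
    schema = _SCHEMAS[kind]
    missing = schema["required"] - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    if kind == "acoustic" and "impedance_1e6" not in table.columns:
        if not {"velocity_m_s", "density_kg_m3"} <= set(table.columns):
            raise SchemaError(
                f"{path}: needs 'impedance_1e6' or 'velocity_m_s' + 'density_kg_m3'"
            )
    unknown = set(table.columns) - schema["known"]
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown column(s) {sorted(unknown)}",
            UserWarning,
            stacklevel=2,
        )
    if len(table) == 0:
        raise SchemaError(f"{path}: no material rows")
    return table


def write_materials_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_stress_strain(
    path,
    gauge_length: Optional[float] = None,
    specimen_width: float = 0.010,
    specimen_thickness: float = 0.004,
) -> StressStrainRecord:
    """Read one tension-test record from delimited text.

    Accepts either columns ``(strain, stress_pa)`` or raw machine columns
    ``(extension_mm, force_n)``; the latter needs ``gauge_length`` (m) to
    convert extension to strain, and force is divided by the initial
    cross-section.
    """
    table = pd.read_csv(path)
    cols = set(table.columns)
    if {"strain", "stress_pa"} <= cols:
        strain = table["strain"].to_numpy(float)
        stress = table["stress_pa"].to_numpy(float)
    elif {"extension_mm", "force_n"} <= cols:
        if gauge_length is None:
            raise InvalidInputError(
                "extension/force records need gauge_length to derive strain"
            )
        strain = table["extension_mm"].to_numpy(float) / 1e3 / gauge_length
        stress = table["force_n"].to_numpy(float) / (specimen_width * specimen_thickness)
    else:
        raise SchemaError(
            f"{path}: expected columns (strain, stress_pa) or (extension_mm, force_n)"
        )
    return StressStrainRecord(
        strain=strain,
        stress=stress,
        specimen_width=specimen_width,
        specimen_thickness=specimen_thickness,
    )


def save_ensemble(path, ensemble: PulseEchoEnsemble) -> None:
    """Persist an ensemble to ``.npz`` with a JSON metadata header."""
    meta = {
        "sampling_rate": ensemble.sampling_rate,
        "condition": ensemble.condition.value,
        "plate_depth": ensemble.plate_depth,
        "pulse_center_freq": ensemble.pulse_center_freq,
        **ensemble.metadata,
    }
    np.savez(path, alines=ensemble.alines, metadata=json.dumps(meta))


def load_ensemble(path) -> PulseEchoEnsemble:
    with np.load(path, allow_pickle=False) as npz:
        alines = npz["alines"]
        meta = json.loads(str(npz["metadata"]))
    return PulseEchoEnsemble(
        alines=alines,
        sampling_rate=float(meta.pop("sampling_rate")),
        condition=Condition(meta.pop("condition")),
        plate_depth=float(meta.pop("plate_depth")),
        pulse_center_freq=float(meta.pop("pulse_center_freq")),
        metadata=meta,
    )


def config_digest(config: dict) -> str:
    """Deterministic short digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report_csv(path, table: pd.DataFrame, config: dict, seed) -> None:
    """Write a report table with an embedded config-hash/seed comment header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={config_digest(config)} seed={seed}\n")
        table.to_csv(fh)
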