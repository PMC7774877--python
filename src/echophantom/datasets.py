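"""Packaged material-property tables and simulation sample definitions.

Two small CSVs ship with the package: the measured acoustic properties
(density, attenuation, velocity, impedance, surface backscatter) of six soft
3D-printable / silicone materials, and their tensile stiffness (Shore A
hardness and Young's modulus).  ``simulation_samples`` turns the acoustic
table into ground-truth-labelled specimens for the RF simulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import AcousticSample

__all__ = [
    "load_acoustic_table",
    "load_stiffness_table",
    "simulation_samples",
    "SAMPLE_THICKNESS_M",
]

# Specimen thicknesses used in the simulated protocol, chosen per material so
# the two-way insertion loss stays in the 10-15 dB range (thin slab for the
# strongly attenuating TangoPlus, thicker ones for the low-loss silicones).
SAMPLE_THICKNESS_M: dict[str, float] = {
    "Lay-fomm 40": 0.010,
    "Lay-fomm 60": 0.010,
    "Gel-Lay": 0.010,
    "TangoPlus": 0.0025,
    "Silicone-0050": 0.012,
    "Silicone-0020": 0.015,
}

# Nominal specimen volume (m^3) used to derive mass from density; a 10 ml
# block, representative of the slab specimens.
SPECIMEN_VOLUME_M3 = 1e-5


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("echophantom.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_acoustic_table() -> pd.DataFrame:
    """Acoustic properties of the six characterized materials."""
    return _read_packaged("acoustic_properties.csv")


def load_stiffness_table() -> pd.DataFrame:
    """Shore A hardness and Young's modulus (kPa) of the seven materials."""
    return _read_packaged("stiffness.csv")


def simulation_samples() -> list[AcousticSample]:
    """Ground-truth specimens for the simulator, one per acoustic-table row.

    True velocity, attenuation and density come from the table; the
    front-surface reflectivity is set from the tabulated surface backscatter
    level (amplitude ratio 10^(-|u|/20) re the plate echo) so the simulated
    surface echoes sit at the measured levels.
    """
    table = load_acoustic_table()
    samples = []
    for row in table.itertuples(index=False):
        rho = float(row.density_kg_m3)
        samples.append(
            AcousticSample(
                name=row.material,
                thickness=SAMPLE_THICKNESS_M[row.material],
                mass=rho * SPECIMEN_VOLUME_M3,
                volume=SPECIMEN_VOLUME_M3,
                true_velocity=float(row.velocity_m_s),
                true_attenuation_at_f0=float(row.attenuation_db_cm),
                true_density=rho,
                surface_reflectivity=10.0 ** (-abs(float(row.backscatter_db)) / 20.0),
            )
        )
    return samples
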