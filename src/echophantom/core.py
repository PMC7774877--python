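"""Domain types, physical constants, and tissue reference values.

Everything downstream (simulation, estimation, comparison) consumes the types
defined here.  Internally all quantities are SI (m, s, kg, Pa, Hz); field units
such as dB/cm, MPa and 10^6 kg m^-2 s^-1 appear only at I/O boundaries through
the explicit converters at the bottom of this module.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "PhysicalConstants",
    "AcousticSample",
    "PulseEchoEnsemble",
    "AcousticProperties",
    "StressStrainRecord",
    "TissueReference",
    "ComparisonReport",
    "RoundingPolicy",
    "Condition",
    "InvalidInputError",
    "GeometryError",
    "DetectionError",
    "IncompatibleEnsembleError",
    "SchemaError",
    "NonPhysicalResultWarning",
    "DensityRangeWarning",
    "make_default_constants",
    "make_default_tissue_reference",
    "density",
    "load_constants",
    "save_constants",
    "db_per_cm_to_db_per_m",
    "db_per_m_to_db_per_cm",
    "m_to_cm",
    "pa_to_kpa",
    "kpa_to_pa",
    "pa_to_mpa",
    "mpa_to_pa",
]


class InvalidInputError(ValueError):
    """An input violates a precondition (non-positive mass, zero magnitude...)."""


class GeometryError(ValueError):
    """Sample/apparatus geometry is inconsistent (sample thicker than plate depth)."""


class DetectionError(RuntimeError):
    """No echo could be located above the noise floor within the search gate."""


class IncompatibleEnsembleError(ValueError):
    """Two ensembles cannot be compared (e.g. different sampling rates)."""


class SchemaError(ValueError):
    """A delimited-text table does not match the documented schema."""


class NonPhysicalResultWarning(UserWarning):
    """A computed value lies outside the physically plausible range."""


class DensityRangeWarning(UserWarning):
    """Sample density is outside the expected tissue-mimicking range."""


# Density range (kg/m^3) considered plausible for tissue-mimicking elastomers.
TISSUE_MIMIC_DENSITY_RANGE = (800.0, 2000.0)

# Velocity range (m/s) outside of which estimates are flagged as non-physical.
PLAUSIBLE_VELOCITY_RANGE = (500.0, 4000.0)


class Condition(str, enum.Enum):
    """Acquisition condition of a pulse-echo ensemble."""

    REFERENCE = "reference"
    SAMPLE_IN = "sample_in"


@dataclass(frozen=True)
class PhysicalConstants:
    """Reference constants of the water-bath substitution measurement.

    Attributes
    ----------
    c_w : float
        Speed of sound in degassed water, m/s.
    Z1 : float
        Reference acoustic impedance of water, kg m^-2 s^-1.  Stored
        independently of ``c_w`` times a water density: the two reference
        values are kept verbatim and never reconciled against each other.
    f0 : float
        Working (transmit) frequency, Hz.
    """

    c_w: float = 1447.0
    Z1: float = 1.48e6
    f0: float = 1.5e6

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise InvalidInputError(f"f0 must be positive, got {self.f0}")
        if self.c_w <= 0 or self.Z1 <= 0:
            raise InvalidInputError("c_w and Z1 must be positive")


def make_default_constants() -> PhysicalConstants:
    """Return the default measurement constants.

    Speed of sound in degassed water 1447 m/s, water reference impedance
    1.48e6 kg m^-2 s^-1, working frequency 1.5 MHz.
    """
    return PhysicalConstants()


@dataclass(frozen=True)
class TissueReference:
    """Target-tissue (myocardium) reference values used for comparison.

    The attenuation reference is stated at ``alpha_ref_freq`` and is scaled
    linearly in frequency to the working frequency before differencing.
    """

    alpha_ref: float = 0.5          # dB/cm at alpha_ref_freq
    alpha_ref_freq: float = 1.0e6   # Hz
    Z_ref: float = 1.67e6           # kg m^-2 s^-1
    E_low: float = 0.18e6           # Pa
    E_high: float = 0.28e6          # Pa

    def __post_init__(self) -> None:
        if not (0 < self.E_low <= self.E_high):
            raise InvalidInputError("tissue modulus range must satisfy 0 < E_low <= E_high")
        if self.alpha_ref <= 0 or self.alpha_ref_freq <= 0 or self.Z_ref <= 0:
            raise InvalidInputError("tissue reference values must be positive")


def make_default_tissue_reference() -> TissueReference:
    """Myocardium defaults: 0.5 dB/cm at 1 MHz, Z = 1.67e6, E in [0.18, 0.28] MPa."""
    return TissueReference()


@dataclass(frozen=True)
class RoundingPolicy:
    """Rounding applied when reproducing printed report tables.

    Velocities are rounded to integer m/s, impedances to ``impedance_decimals``
    places in units of 10^6 kg m^-2 s^-1, attenuation difference percentages to
    integers and impedance difference percentages to two decimals.  The policy
    is a named object so reproduction runs can pin it.
    """

    velocity_decimals: int = 0
    impedance_decimals: int = 2      # in units of 1e6
    attenuation_pct_decimals: int = 0
    impedance_pct_decimals: int = 2
    use_rounded_impedance_for_differences: bool = True

    def round_velocity(self, c: float) -> float:
        return float(np.round(c, self.velocity_decimals))

    def round_impedance(self, Z: float) -> float:
        """Round an impedance given in SI units; returns SI units."""
        return float(np.round(Z / 1e6, self.impedance_decimals) * 1e6)

    def round_attenuation_pct(self, pct: float) -> float:
        return float(np.round(pct, self.attenuation_pct_decimals))

    def round_impedance_pct(self, pct: float) -> float:
        return float(np.round(pct, self.impedance_pct_decimals))


@dataclass
class AcousticSample:
    """A physical specimen placed on the reflector plate.

    ``true_*`` fields are ground-truth parameters used only by the simulator;
    they are ignored (and typically unknown) for measured data.
    ``surface_reflectivity`` overrides the impedance-mismatch front-surface
    pressure reflection when set.
    """

    name: str
    thickness: float                 # m
    mass: float                      # kg
    volume: float                    # m^3
    true_velocity: Optional[float] = None          # m/s
    true_attenuation_at_f0: Optional[float] = None  # dB/cm at f0
    true_density: Optional[float] = None            # kg/m^3
    surface_reflectivity: Optional[float] = None    # amplitude ratio

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidInputError(f"thickness must be positive, got {self.thickness}")
        if self.mass <= 0:
            raise InvalidInputError(f"mass must be positive, got {self.mass}")
        if self.volume <= 0:
            raise InvalidInputError(f"volume must be positive, got {self.volume}")
        lo, hi = TISSUE_MIMIC_DENSITY_RANGE
        rho = self.mass / self.volume
        if not (lo <= rho <= hi):
            warnings.warn(
                f"sample {self.name!r}: density {rho:.0f} kg/m^3 outside the "
                f"tissue-mimicking range [{lo:.0f}, {hi:.0f}]",
                DensityRangeWarning,
                stacklevel=2,
            )

    @property
    def density(self) -> float:
        return self.mass / self.volume


def density(sample: AcousticSample) -> float:
    """Mass density of a sample, kg/m^3, from measured mass and model volume."""
    return sample.mass / sample.volume


@dataclass
class PulseEchoEnsemble:
    """Repeated RF A-lines acquired under one condition.

    ``alines`` has shape (n_repeats, n_samples); every trace shares the same
    time base starting at t = 0 with spacing 1/sampling_rate.
    """

    alines: np.ndarray
    sampling_rate: float             # Hz
    condition: Condition
    plate_depth: float               # m
    pulse_center_freq: float         # Hz
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alines = np.atleast_2d(np.asarray(self.alines, dtype=float))
        if self.alines.ndim != 2:
            raise InvalidInputError("alines must be a 2-D (n_repeats, n_samples) array")
        if isinstance(self.condition, str):
            self.condition = Condition(self.condition)
        if self.sampling_rate < 10.0 * self.pulse_center_freq:
            raise InvalidInputError(
                "sampling_rate must be at least 10x the pulse center frequency "
                f"({self.sampling_rate:.3g} < 10 x {self.pulse_center_freq:.3g})"
            )
        if self.plate_depth <= 0:
            raise InvalidInputError("plate_depth must be positive")

    @property
    def n_repeats(self) -> int:
        return self.alines.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alines.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class AcousticProperties:
    """Estimated acoustic quantities of one material.

    ``u_raw`` is the surface-backscatter level as the plain -20 log10 ratio
    (positive when the surface echo is weaker than the plate echo); ``u`` is
    the same level reported as a negative number — the level of the surface
    echo *below* the plate echo — matching the usual tabulated sign.
    """

    name: str
    c_s: float                       # m/s
    alpha: float                     # dB/cm at f0
    u: float                         # dB (negative: below plate level)
    u_raw: float                     # dB (printed-formula sign)
    rho: float                       # kg/m^3
    Z: float                         # kg m^-2 s^-1
    r: float
    t: float
    R: float
    T: float
    c_s_sd: float = 0.0
    alpha_sd: float = 0.0
    u_sd: float = 0.0

    def __post_init__(self) -> None:
        if abs((self.R + self.T) - 1.0) > 1e-9:
            raise InvalidInputError("R + T must equal 1 (intensity conservation)")
        if abs((1.0 - self.r) - self.t) > 1e-9:
            raise InvalidInputError("t must equal 1 - r (amplitude continuity)")


@dataclass
class StressStrainRecord:
    """One uniaxial tension-test repeat.

    Engineering stress (Pa) against engineering strain; both series start at
    zero and strain is non-decreasing.  Default cross-section is the standard
    4 mm x 10 mm tensile specimen.
    """

    strain: np.ndarray
    stress: np.ndarray
    specimen_width: float = 0.010    # m
    specimen_thickness: float = 0.004  # m

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise InvalidInputError("strain and stress must be equal-length 1-D series")
        if self.strain.size < 2:
            raise InvalidInputError("record needs at least two points")
        if self.strain[0] != 0 or self.stress[0] != 0:
            raise InvalidInputError("strain and stress series must start at 0")
        if np.any(np.diff(self.strain) < 0):
            raise InvalidInputError("strain must be non-decreasing")
        if self.specimen_width <= 0 or self.specimen_thickness <= 0:
            raise InvalidInputError("specimen cross-section must be positive")

    @property
    def cross_section(self) -> float:
        """Initial cross-sectional area, m^2."""
        return self.specimen_width * self.specimen_thickness


@dataclass
class ComparisonReport:
    """Material-vs-tissue relative differences (the acoustic comparison table).

    ``table`` is a DataFrame indexed by material with columns
    ``attenuation_difference_pct`` and ``impedance_difference_pct`` plus
    min/max flags; all percentages are absolute relative differences (>= 0).
    """

    table: "object"                  # pandas.DataFrame
    rounding_policy: RoundingPolicy
    tissue: TissueReference
    f0: float

    def __post_init__(self) -> None:
        for col in ("attenuation_difference_pct", "impedance_difference_pct"):
            if col in self.table.columns and (self.table[col] < 0).any():
                raise InvalidInputError(f"{col} contains negative entries")


# ---------------------------------------------------------------------------
# Config (flat key-value) serialization for constants & tissue references
# ---------------------------------------------------------------------------

def save_constants(path, constants: PhysicalConstants,
                   tissue: TissueReference | None = None) -> None:
    """Write constants (and optionally a tissue reference) to a flat YAML file."""
    doc = {"c_w": constants.c_w, "Z1": constants.Z1, "f0": constants.f0}
    if tissue is not None:
        doc.update(
            alpha_ref=tissue.alpha_ref,
            alpha_ref_freq=tissue.alpha_ref_freq,
            Z_ref=tissue.Z_ref,
            E_low=tissue.E_low,
            E_high=tissue.E_high,
        )
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_constants(path) -> tuple[PhysicalConstants, TissueReference]:
    """Read constants and tissue reference from a flat YAML file.

    Missing keys fall back to defaults, so a file may override any subset.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    cdef, tdef = PhysicalConstants(), TissueReference()
    constants = PhysicalConstants(
        c_w=float(doc.get("c_w", cdef.c_w)),
        Z1=float(doc.get("Z1", cdef.Z1)),
        f0=float(doc.get("f0", cdef.f0)),
    )
    tissue = TissueReference(
        alpha_ref=float(doc.get("alpha_ref", tdef.alpha_ref)),
        alpha_ref_freq=float(doc.get("alpha_ref_freq", tdef.alpha_ref_freq)),
        Z_ref=float(doc.get("Z_ref", tdef.Z_ref)),
        E_low=float(doc.get("E_low", tdef.E_low)),
        E_high=float(doc.get("E_high", tdef.E_high)),
    )
    return constants, tissue


# ---------------------------------------------------------------------------
# Unit converters (boundary use only)
# ---------------------------------------------------------------------------

def db_per_cm_to_db_per_m(alpha: float) -> float:
    return alpha * 100.0


def db_per_m_to_db_per_cm(alpha: float) -> float:
    return alpha / 100.0


def m_to_cm(x: float) -> float:
    return x * 100.0


def pa_to_kpa(x: float) -> float:
    return x / 1e3


def kpa_to_pa(x: float) -> float:
    return x * 1e3


def pa_to_mpa(x: float) -> float:
    return x / 1e6


def mpa_to_pa(x: float) -> float:
    return x * 1e6
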