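"""Young's modulus from uniaxial tension tests, and stiffness comparisons.

The modulus is the least-squares slope of engineering stress against
engineering strain over a low-strain fit window (default 2-10 % strain, the
usual linear regime for soft elastomers).  Repeated records give a mean and
standard deviation over repeats.  Comparison helpers express a material's
modulus as percent error bands against a target-tissue modulus range and as
pairwise softness ratios.

A small synthetic generator produces linear (optionally toe-region) records
with multiplicative noise for validation, emulating repeated pulls of a
4 mm x 10 mm specimen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import InvalidInputError, StressStrainRecord, TissueReference

__all__ = [
    "ElasticityResult",
    "DEFAULT_FIT_WINDOW",
    "fit_youngs_modulus",
    "stiffness_error_band",
    "softness_ratio",
    "generate_stress_strain",
]

DEFAULT_FIT_WINDOW = (0.02, 0.10)


@dataclass(frozen=True)
class ElasticityResult:
    """Fitted modulus for one material.

    ``E`` and ``E_sd`` are in Pa; ``shore_A`` is an optional pass-through
    durometer hardness (not derived from the fit).
    """

    E: float
    fit_window: tuple[float, float]
    n_repeats: int
    E_sd: float = 0.0
    shore_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise InvalidInputError(f"E must be positive, got {self.E}")


def _fit_one(record: StressStrainRecord, window: tuple[float, float]) -> float:
    lo, hi = window
    if not (hi > lo):
        raise InvalidInputError(f"degenerate fit window {window}")
    mask = (record.strain >= lo) & (record.strain <= hi)
    if mask.sum() < 10:
        raise InvalidInputError(
            f"fit window {window} contains only {int(mask.sum())} points (< 10)"
        )
    strain = record.strain[mask]
    if np.ptp(strain) == 0:
        raise InvalidInputError("zero strain span inside fit window")
    res = stats.linregress(strain, record.stress[mask])
    return float(res.slope)


def fit_youngs_modulus(
    records: StressStrainRecord | Sequence[StressStrainRecord],
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    shore_A: Optional[float] = None,
) -> ElasticityResult:
    """Least-squares Young's modulus over the fit window.

    A single record gives that record's slope; a sequence of repeats gives
    the mean slope and the standard deviation over repeats.
    """
    if isinstance(records, StressStrainRecord):
        records = [records]
    if len(records) == 0:
        raise InvalidInputError("no records supplied")
    slopes = np.array([_fit_one(r, fit_window) for r in records])
    return ElasticityResult(
        E=float(slopes.mean()),
        fit_window=tuple(fit_window),
        n_repeats=len(records),
        E_sd=float(slopes.std(ddof=1)) if len(records) > 1 else 0.0,
        shore_A=shore_A,
    )


def stiffness_error_band(E: float, tissue: TissueReference) -> tuple[float, float]:
    """Percent error of a modulus against each bound of the tissue range.

    Returns ``100 |E_bound - E| / E_bound`` for the low and high bound,
    ordered (min, max).  Errors are relative to the tissue bound, which is
    what reproduces conventional phantom-vs-tissue error statements.
    """
    if E <= 0:
        raise InvalidInputError("E must be positive")
    errs = [
        100.0 * abs(bound - E) / bound
        for bound in (tissue.E_low, tissue.E_high)
    ]
    return (min(errs), max(errs))


def softness_ratio(E_a: float, E_b: float) -> float:
    """How many times stiffer material a is than material b: E_a / E_b."""
    if E_a <= 0 or E_b <= 0:
        raise InvalidInputError("moduli must be positive")
    return E_a / E_b


def generate_stress_strain(
    E_true: float,
    n_repeats: int = 20,
    noise_level: float = 0.02,
    max_strain: float = 0.15,
    n_points: int = 151,
    toe_strain: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[StressStrainRecord]:
    """Synthetic repeated tension-test records with known modulus.

    The noiseless curve is linear, stress = E_true * strain, optionally with a
    quadratic toe region below ``toe_strain`` joined C1-continuously (above
    the toe the slope is exactly ``E_true``, so a fit window past the toe
    recovers the modulus).  Multiplicative Gaussian noise of relative s.d.
    ``noise_level`` models grip/load-cell variability between repeats.
    """
    if E_true <= 0:
        raise InvalidInputError("E_true must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_points)
    if toe_strain > 0:
        clean = np.where(
            strain < toe_strain,
            E_true * strain**2 / (2.0 * toe_strain),
            E_true * (strain - toe_strain / 2.0),
        )
    else:
        clean = E_true * strain
    records = []
    for _ in range(n_repeats):
        noisy = clean * (1.0 + rng.normal(0.0, noise_level, size=strain.shape))
        noisy[0] = 0.0  # series start pinned at the origin
        records.append(StressStrainRecord(strain=strain, stress=noisy))
    return records
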