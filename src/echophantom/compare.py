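"""Material-vs-myocardium comparison tables.

Builds the acoustic comparison (attenuation and impedance relative
differences against cardiac tissue, with the tissue attenuation reference
scaled linearly in frequency to the working frequency) and the stiffness
summary (error bands against the myocardial modulus range plus pairwise
softness ratios), flagging the min/max of each column.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    ComparisonReport,
    InvalidInputError,
    RoundingPolicy,
    SchemaError,
    TissueReference,
)
from .elasticity import ElasticityResult, softness_ratio, stiffness_error_band

__all__ = [
    "scale_attenuation_linear",
    "relative_difference",
    "build_comparison_table",
    "build_stiffness_summary",
]


def scale_attenuation_linear(alpha_ref: float, f_ref: float, f_target: float) -> float:
    """Scale an attenuation coefficient between frequencies, linear in f.

    alpha(f_target) = alpha_ref * f_target / f_ref; e.g. a 0.5 dB/cm tissue
    reference at 1 MHz becomes 0.75 dB/cm at 1.5 MHz.
    """
    if alpha_ref <= 0 or f_ref <= 0 or f_target <= 0:
        raise InvalidInputError("attenuation and frequencies must be positive")
    return alpha_ref * f_target / f_ref


def relative_difference(value: float, reference: float) -> float:
    """Absolute relative difference in percent: 100 |value - reference| / reference."""
    if reference <= 0:
        raise InvalidInputError("reference must be positive")
    return 100.0 * abs(value - reference) / reference


def _flag_extremes(series: pd.Series) -> pd.Series:
    """' (min)'/' (max)' labels for the extreme entries of a numeric column."""
    flags = pd.Series("", index=series.index, dtype=object)
    flags[series.idxmin()] = "min"
    flags[series.idxmax()] = "max"
    return flags


def build_comparison_table(
    materials: pd.DataFrame,
    tissue: Optional[TissueReference] = None,
    rounding_policy: Optional[RoundingPolicy] = None,
    f0: float = 1.5e6,
) -> ComparisonReport:
    """Relative acoustic differences of each material against cardiac tissue.

    ``materials`` must carry per-material rows with columns ``material``,
    ``attenuation_db_cm`` (at ``f0``) and either ``impedance_1e6`` or both
    ``velocity_m_s`` and ``density_kg_m3`` (impedance then computed as c rho).

    Attenuation differences are taken against the tissue reference scaled to
    ``f0``.  Impedance differences are computed from impedances rounded per
    the policy (2 decimals in 10^6 units by default): printed material tables
    round impedances before differencing, and reproducing them requires
    differencing the rounded values.
    """
    tissue = tissue or TissueReference()
    policy = rounding_policy or RoundingPolicy()
    required = {"material", "attenuation_db_cm"}
    missing = required - set(materials.columns)
    if missing:
        raise SchemaError(f"materials table missing columns: {sorted(missing)}")
    if "impedance_1e6" in materials.columns:
        Z = materials["impedance_1e6"].astype(float) * 1e6
    elif {"velocity_m_s", "density_kg_m3"} <= set(materials.columns):
        Z = materials["velocity_m_s"].astype(float) * materials["density_kg_m3"].astype(float)
    else:
        raise SchemaError(
            "materials table needs 'impedance_1e6' or 'velocity_m_s' + 'density_kg_m3'"
        )
    if policy.use_rounded_impedance_for_differences:
        Z = Z.map(policy.round_impedance)

    alpha_tissue = scale_attenuation_linear(tissue.alpha_ref, tissue.alpha_ref_freq, f0)
    att_pct = materials["attenuation_db_cm"].astype(float).map(
        lambda a: policy.round_attenuation_pct(relative_difference(a, alpha_tissue))
    )
    imp_pct = Z.map(
        lambda z: policy.round_impedance_pct(relative_difference(z, tissue.Z_ref))
    )
    table = pd.DataFrame(
        {
            "material": materials["material"].values,
            "attenuation_difference_pct": att_pct.values,
            "impedance_difference_pct": imp_pct.values,
        }
    ).set_index("material")
    table["attenuation_flag"] = _flag_extremes(table["attenuation_difference_pct"])
    table["impedance_flag"] = _flag_extremes(table["impedance_difference_pct"])
    return ComparisonReport(table=table, rounding_policy=policy, tissue=tissue, f0=f0)


def build_stiffness_summary(
    results: Mapping[str, ElasticityResult],
    tissue: Optional[TissueReference] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stiffness comparison against the tissue modulus range.

    Returns ``(bands, ratios)``: per-material error bands (percent, relative
    to the tissue bounds, with min/max flags on the modulus column) and the
    pairwise softness-ratio matrix ``E_row / E_col``.  A single material
    yields an empty ratio table.
    """
    if len(results) == 0:
        raise InvalidInputError("at least one material required")
    tissue = tissue or TissueReference()
    rows = []
    for name, res in results.items():
        low, high = stiffness_error_band(res.E, tissue)
        rows.append(
            {
                "material": name,
                "E_kPa": res.E / 1e3,
                "shore_A": res.shore_A,
                "error_low_pct": low,
                "error_high_pct": high,
            }
        )
    bands = pd.DataFrame(rows).set_index("material")
    bands["stiffness_flag"] = _flag_extremes(bands["E_kPa"])

    names = list(results)
    if len(names) < 2:
        ratios = pd.DataFrame(index=pd.Index([], name="material"))
    else:
        mat = np.array(
            [[softness_ratio(results[a].E, results[b].E) for b in names] for a in names]
        )
        ratios = pd.DataFrame(mat, index=pd.Index(names, name="material"), columns=names)
    return bands, ratios
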