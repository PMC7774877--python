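"""Acoustic property estimation from pulse-echo ensemble pairs.

The substitution method compares plate echoes acquired with and without the
sample in the beam path:

* velocity      1/c_s = 1/c_w - dT/(2d), with dT the plate-echo time advance;
* attenuation   alpha = -(20 / 2d) log10(A_f / A0_f)   [dB/cm], with A_f the
  spectral magnitude at the working frequency inside the plate-echo gate;
* backscatter   u = -20 log10(A_surface / A0_f)        [dB re plate], from the
  front-surface echo;
* impedance     Z = c_s rho, and the planar-interface amplitude/intensity
  reflection and transmission coefficients r, t, R, T against water.

Echo arrival times come from the analytic-signal envelope peak refined with a
log-domain parabolic fit (exact for Gaussian envelopes).  Spectral magnitudes
are single-frequency windowed DFTs evaluated exactly at the working frequency,
avoiding FFT bin quantization.  All quantities are estimated per repeat and
then averaged, and the per-repeat dispersion is reported alongside the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import hilbert

from .core import (
    AcousticProperties,
    AcousticSample,
    Condition,
    DetectionError,
    IncompatibleEnsembleError,
    InvalidInputError,
    NonPhysicalResultWarning,
    PhysicalConstants,
    PulseEchoEnsemble,
    PLAUSIBLE_VELOCITY_RANGE,
    density,
    m_to_cm,
)

__all__ = [
    "EchoMeasurement",
    "GateConfig",
    "locate_plate_echo",
    "estimate_time_shift",
    "estimate_velocity",
    "estimate_attenuation",
    "estimate_backscatter",
    "impedance",
    "reflection_transmission",
    "characterize",
]

# Peak must exceed this multiple of the whole-trace median envelope to count
# as a detection; a pure-noise gate tops out near 4x the Rayleigh median.
PEAK_TO_FLOOR_MIN = 6.0


@dataclass(frozen=True)
class GateConfig:
    """Gating and spectral-readout settings for echo measurement.

    ``window_periods`` sets the length of the Hann-tapered analysis window in
    carrier periods; ``gate_halfwidth`` bounds the envelope-peak search around
    the nominal arrival for the reference condition; ``velocity_search_range``
    bounds the plate-echo search gate when a sample of known thickness but
    unknown velocity is in place.
    """

    window_periods: float = 6.0
    gate_halfwidth: float = 2e-6           # s
    velocity_search_range: tuple[float, float] = PLAUSIBLE_VELOCITY_RANGE
    gate_margin: float = 1e-6              # s, pulse-tail allowance


@dataclass(frozen=True)
class EchoMeasurement:
    """Arrival time and spectral magnitudes measured on one A-line."""

    t_plate: float                   # s, envelope-peak arrival of plate echo
    A_f: float                       # spectral magnitude at f0, plate-echo gate
    A_surface: Optional[float] = None  # magnitude at f0, front-surface gate

    def __post_init__(self) -> None:
        if self.A_f < 0 or (self.A_surface is not None and self.A_surface < 0):
            raise InvalidInputError("spectral magnitudes must be >= 0")


def _envelope(aline: np.ndarray) -> np.ndarray:
    return np.abs(hilbert(aline))


def _refine_peak(env: np.ndarray, idx: int) -> float:
    """Sub-sample peak position by a quadratic fit on the log envelope.

    For a Gaussian envelope the log is exactly quadratic, so fitting over the
    whole above-half-maximum region recovers the continuum peak; using the
    full region (rather than just three points) keeps the vertex estimate
    stable when the envelope is noisy.
    """
    if idx <= 0 or idx >= env.size - 1:
        return float(idx)
    peak = env[idx]
    if peak <= 0:
        return float(idx)
    thresh = 0.5 * peak
    lo = idx
    while lo > 0 and env[lo - 1] >= thresh:
        lo -= 1
    hi = idx
    while hi < env.size - 1 and env[hi + 1] >= thresh:
        hi += 1
    pts = np.arange(lo, hi + 1)
    if pts.size < 3:
        return float(idx)
    coeffs = np.polyfit(pts - idx, np.log(env[lo : hi + 1]), 2)
    if coeffs[0] >= 0:
        return float(idx)
    vertex = -coeffs[1] / (2.0 * coeffs[0])
    if abs(vertex) > (hi - lo):
        return float(idx)
    return float(idx) + vertex


def _windowed_magnitude_at(
    aline: np.ndarray, sampling_rate: float, center_idx: int, f0: float,
    window_periods: float,
) -> float:
    """|DFT| of a Hann-tapered gate, evaluated exactly at f0.

    The gate spans ``window_periods`` carrier periods centered on
    ``center_idx`` (clipped to the trace).
    """
    half = int(round(0.5 * window_periods / f0 * sampling_rate))
    lo = max(center_idx - half, 0)
    hi = min(center_idx + half + 1, aline.size)
    seg = aline[lo:hi]
    win = np.hanning(seg.size)
    m = np.arange(lo, hi)
    phasor = np.exp(-2j * np.pi * f0 * m / sampling_rate)
    return float(np.abs(np.sum(seg * win * phasor)))


def _locate_in_gate(
    aline: np.ndarray, sampling_rate: float, gate: tuple[float, float], f0: float,
    window_periods: float,
) -> tuple[float, float]:
    """(arrival time, A_f) of the strongest echo within a time gate."""
    env = _envelope(aline)
    i_lo = max(int(np.floor(gate[0] * sampling_rate)), 0)
    i_hi = min(int(np.ceil(gate[1] * sampling_rate)) + 1, aline.size)
    if i_hi <= i_lo:
        raise DetectionError(f"empty search gate {gate}")
    seg = env[i_lo:i_hi]
    idx = i_lo + int(np.argmax(seg))
    peak = env[idx]
    floor = float(np.median(env))
    if peak <= 0 or peak < PEAK_TO_FLOOR_MIN * floor:
        raise DetectionError(
            f"no echo above noise floor in gate [{gate[0]:.3g}, {gate[1]:.3g}] s"
        )
    t_peak = _refine_peak(env, idx) / sampling_rate
    A_f = _windowed_magnitude_at(aline, sampling_rate, idx, f0, window_periods)
    return t_peak, A_f


def locate_plate_echo(
    aline: np.ndarray,
    sampling_rate: float,
    plate_depth: float,
    constants: PhysicalConstants,
    gate: Optional[tuple[float, float]] = None,
    gate_config: GateConfig = GateConfig(),
) -> EchoMeasurement:
    """Measure the plate echo on one A-line.

    The search gate defaults to +-``gate_halfwidth`` around the nominal water
    round trip ``2 plate_depth / c_w``; pass ``gate`` to override.
    """
    aline = np.asarray(aline, dtype=float)
    if gate is None:
        nominal = 2.0 * plate_depth / constants.c_w
        gate = (nominal - gate_config.gate_halfwidth, nominal + gate_config.gate_halfwidth)
    t_plate, A_f = _locate_in_gate(
        aline, sampling_rate, gate, constants.f0, gate_config.window_periods
    )
    return EchoMeasurement(t_plate=t_plate, A_f=A_f)


def _sample_plate_gate(
    plate_depth: float, thickness: float, constants: PhysicalConstants,
    gate_config: GateConfig,
) -> tuple[float, float]:
    """Plate-echo search gate when a sample of given thickness is in place.

    Brackets arrivals for sample velocities across the search range while
    staying clear of the front-surface echo.
    """
    t_front = 2.0 * (plate_depth - thickness) / constants.c_w
    c_lo, c_hi = gate_config.velocity_search_range
    earliest = t_front + 2.0 * thickness / c_hi
    latest = t_front + 2.0 * thickness / c_lo
    lo = max(earliest - gate_config.gate_margin, t_front + gate_config.gate_margin)
    return (lo, latest + gate_config.gate_margin)


def _measure_front_surface(
    aline: np.ndarray, sampling_rate: float, plate_depth: float, thickness: float,
    constants: PhysicalConstants, gate_config: GateConfig,
) -> Optional[float]:
    """Front-surface spectral magnitude at f0, or None if below the noise.

    The front-surface arrival 2 (plate_depth - d) / c_w depends only on water
    speed and geometry, so the analysis window is centered there analytically
    rather than by peak search — the echo may sit near the noise envelope.
    Validity requires the magnitude to exceed 5x the expected noise level of
    the windowed DFT (noise s.d. estimated from the whole-trace envelope
    median, Rayleigh statistics).
    """
    t_front = 2.0 * (plate_depth - thickness) / constants.c_w
    idx = int(round(t_front * sampling_rate))
    if idx < 0 or idx >= aline.size:
        return None
    f0 = constants.f0
    A_surface = _windowed_magnitude_at(
        aline, sampling_rate, idx, f0, gate_config.window_periods
    )
    env = _envelope(aline)
    sigma_hat = float(np.median(env)) / np.sqrt(2.0 * np.log(2.0))
    half = int(round(0.5 * gate_config.window_periods / f0 * sampling_rate))
    win = np.hanning(2 * half + 1)
    noise_level = sigma_hat * np.sqrt(np.sum(win**2) / 2.0)
    peak_env = float(np.max(env))
    if A_surface <= max(5.0 * noise_level, 1e-6 * peak_env):
        return None
    return A_surface


def _measure_ensemble(
    ensemble: PulseEchoEnsemble,
    constants: PhysicalConstants,
    thickness: Optional[float],
    gate_config: GateConfig,
) -> list[EchoMeasurement]:
    """Per-repeat echo measurements; front-surface gate only for sample-in."""
    out = []
    for aline in ensemble.alines:
        if ensemble.condition is Condition.REFERENCE or thickness is None:
            m = locate_plate_echo(
                aline, ensemble.sampling_rate, ensemble.plate_depth, constants,
                gate_config=gate_config,
            )
        else:
            plate_gate = _sample_plate_gate(
                ensemble.plate_depth, thickness, constants, gate_config
            )
            t_plate, A_f = _locate_in_gate(
                aline, ensemble.sampling_rate, plate_gate, constants.f0,
                gate_config.window_periods,
            )
            A_surface = _measure_front_surface(
                aline, ensemble.sampling_rate, ensemble.plate_depth, thickness,
                constants, gate_config,
            )
            m = EchoMeasurement(t_plate=t_plate, A_f=A_f, A_surface=A_surface)
        out.append(m)
    return out


def estimate_time_shift(
    reference: PulseEchoEnsemble,
    sample_in: PulseEchoEnsemble,
    constants: PhysicalConstants,
    thickness: float,
    gate_config: GateConfig = GateConfig(),
) -> tuple[np.ndarray, float]:
    """Per-repeat substitution time shifts and their mean, seconds.

    dT_i = t_plate(reference_i) - t_plate(sample_in_i); positive when the
    sample is faster than water.  Repeats are paired index-wise; if the two
    ensembles have different repeat counts the excess is ignored.
    """
    if reference.sampling_rate != sample_in.sampling_rate:
        raise IncompatibleEnsembleError(
            f"sampling rates differ: {reference.sampling_rate} vs "
            f"{sample_in.sampling_rate}"
        )
    ref_meas = _measure_ensemble(reference, constants, None, gate_config)
    sam_meas = _measure_ensemble(sample_in, constants, thickness, gate_config)
    n = min(len(ref_meas), len(sam_meas))
    shifts = np.array(
        [ref_meas[i].t_plate - sam_meas[i].t_plate for i in range(n)]
    )
    return shifts, float(shifts.mean())


def estimate_velocity(
    delta_T: float, thickness: float, constants: PhysicalConstants
) -> float:
    """Sample sound speed from the substitution shift: c_s = 1/(1/c_w - dT/2d).

    Non-physical results (non-positive slowness, or speed outside the
    plausible range) are flagged with a warning but still returned.
    """
    if thickness <= 0:
        raise InvalidInputError("thickness must be positive")
    slowness = 1.0 / constants.c_w - delta_T / (2.0 * thickness)
    if slowness <= 0:
        warnings.warn(
            f"non-physical slowness {slowness:.3g} s/m; time shift too large "
            "for this thickness",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
        return float("inf") if slowness == 0 else 1.0 / slowness
    c_s = 1.0 / slowness
    lo, hi = PLAUSIBLE_VELOCITY_RANGE
    if not (lo <= c_s <= hi):
        warnings.warn(
            f"estimated velocity {c_s:.1f} m/s outside plausible range "
            f"[{lo:.0f}, {hi:.0f}]",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
    return c_s


def estimate_attenuation(A_f, A0_f, thickness: float):
    """Attenuation coefficient alpha = -(20 / 2d) log10(A_f / A0_f), dB/cm.

    ``A_f``/``A0_f`` may be scalars or per-repeat arrays (paired index-wise);
    ``thickness`` is in meters, the result in dB/cm at the working frequency.
    """
    A_f = np.asarray(A_f, dtype=float)
    A0_f = np.asarray(A0_f, dtype=float)
    if np.any(A_f <= 0) or np.any(A0_f <= 0):
        raise InvalidInputError("spectral magnitudes must be positive")
    if thickness <= 0:
        raise InvalidInputError("thickness must be positive")
    d_cm = m_to_cm(thickness)
    alpha = -(20.0 / (2.0 * d_cm)) * np.log10(A_f / A0_f)
    return float(alpha) if alpha.ndim == 0 else alpha


def estimate_backscatter(A_surface, A0_f):
    """Surface backscatter level relative to the plate echo, dB.

    Returns ``(u_table, u_raw)``: ``u_raw`` is the plain -20 log10 ratio
    (positive when the surface echo is the weaker), and ``u_table`` is the
    same magnitude reported as a negative number — the level of the surface
    echo below the plate echo, the sign convention used in material tables.
    """
    A_surface = np.asarray(A_surface, dtype=float)
    A0_f = np.asarray(A0_f, dtype=float)
    if np.any(A_surface <= 0) or np.any(A0_f <= 0):
        raise InvalidInputError("spectral magnitudes must be positive")
    u_raw = -20.0 * np.log10(A_surface / A0_f)
    u_table = -np.abs(u_raw)
    if u_raw.ndim == 0:
        return float(u_table), float(u_raw)
    return u_table, u_raw


def impedance(c_s: float, rho: float) -> float:
    """Characteristic acoustic impedance Z = c_s rho, kg m^-2 s^-1."""
    if c_s <= 0 or rho <= 0:
        raise InvalidInputError("velocity and density must be positive")
    return c_s * rho


def reflection_transmission(
    Z2: float, constants: PhysicalConstants
) -> tuple[float, float, float, float]:
    """Planar-interface coefficients (r, t, R, T) against the water reference.

    r = (Z1 - Z2)/(Z1 + Z2), t = 2 Z2/(Z1 + Z2), R = r^2,
    T = 4 Z1 Z2/(Z1 + Z2)^2; R + T = 1 and t = 1 - r identically.
    """
    if Z2 <= 0:
        raise InvalidInputError("impedance must be positive")
    Z1 = constants.Z1
    s = Z1 + Z2
    r = (Z1 - Z2) / s
    t = 2.0 * Z2 / s
    R = ((Z1 - Z2) / s) ** 2
    T = 4.0 * Z1 * Z2 / s**2
    return r, t, R, T


def characterize(
    sample: AcousticSample,
    reference: PulseEchoEnsemble,
    sample_in: PulseEchoEnsemble,
    constants: Optional[PhysicalConstants] = None,
    gate_config: GateConfig = GateConfig(),
) -> AcousticProperties:
    """Full substitution-method characterization of one sample.

    Chains echo measurement, velocity/attenuation/backscatter estimation, the
    density-based impedance and the interface coefficients.  All spectral and
    timing quantities are estimated on each repeat and then averaged; the
    per-repeat standard deviations are reported in the ``*_sd`` fields.
    """
    constants = constants or PhysicalConstants()
    if reference.sampling_rate != sample_in.sampling_rate:
        raise IncompatibleEnsembleError("ensembles have different sampling rates")
    d = sample.thickness

    try:
        ref_meas = _measure_ensemble(reference, constants, None, gate_config)
        sam_meas = _measure_ensemble(sample_in, constants, d, gate_config)
    except DetectionError as err:
        raise DetectionError(f"echo measurement stage: {err}") from err

    n = min(len(ref_meas), len(sam_meas))
    shifts = np.array([ref_meas[i].t_plate - sam_meas[i].t_plate for i in range(n)])
    A0 = np.array([m.A_f for m in ref_meas[:n]])
    A = np.array([m.A_f for m in sam_meas[:n]])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonPhysicalResultWarning)
        c_per = np.array([estimate_velocity(dt, d, constants) for dt in shifts])
    c_s = float(c_per.mean())
    lo, hi = PLAUSIBLE_VELOCITY_RANGE
    if not (lo <= c_s <= hi):
        warnings.warn(
            f"mean velocity {c_s:.1f} m/s outside plausible range",
            NonPhysicalResultWarning,
            stacklevel=2,
        )

    alpha_per = estimate_attenuation(A, A0, d)
    alpha = float(np.mean(alpha_per))

    surf = [
        (m.A_surface, A0[i])
        for i, m in enumerate(sam_meas[:n])
        if m.A_surface is not None
    ]
    if surf:
        As = np.array([s for s, _ in surf])
        A0s = np.array([a for _, a in surf])
        u_table_per, u_raw_per = estimate_backscatter(As, A0s)
        u_table = float(np.mean(u_table_per))
        u_raw = float(np.mean(u_raw_per))
        u_sd = float(np.std(u_table_per, ddof=1)) if len(surf) > 1 else 0.0
    else:
        warnings.warn(
            "no front-surface echo detected in any repeat; backscatter "
            "reported as NaN",
            NonPhysicalResultWarning,
            stacklevel=2,
        )
        u_table = u_raw = float("nan")
        u_sd = 0.0

    rho = density(sample)
    Z = impedance(c_s, rho)
    r, t, R, T = reflection_transmission(Z, constants)

    return AcousticProperties(
        name=sample.name,
        c_s=c_s,
        alpha=alpha,
        u=u_table,
        u_raw=u_raw,
        rho=rho,
        Z=Z,
        r=r,
        t=t,
        R=R,
        T=T,
        c_s_sd=float(np.std(c_per, ddof=1)) if n > 1 else 0.0,
        alpha_sd=float(np.std(alpha_per, ddof=1)) if n > 1 else 0.0,
        u_sd=u_sd,
    )
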