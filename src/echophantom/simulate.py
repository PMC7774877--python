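"""Forward simulation of the water-bath pulse-echo substitution experiment.

Generates ensembles of RF A-lines from a steel plate at known depth, with and
without a sample resting on the plate, so the estimation chain can be exercised
against known ground truth.  The model is 1-D single-path propagation:

* the transmit pulse is a Gaussian-enveloped sinusoid at the working frequency;
* the plate is an ideal reflector normalised to unit echo amplitude;
* a sample of thickness ``d`` advances (or retards) the plate echo by
  ``dT = 2 d (1/c_w - 1/c_s)`` and attenuates it by ``10^(-alpha(f) 2d / 20)``
  with attenuation linear in frequency, ``alpha(f) = alpha(f0) f/f0``;
* the front surface reflects a pressure fraction set by the water/sample
  impedance mismatch (or an explicit reflectivity override);
* optionally, the front interface also removes two-way transmitted energy and
  weak scatterers inside the sample add speckle.

Echo delays are synthesised as frequency-domain phase shifts, so sub-sample
time shifts are represented exactly rather than rounded to the grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .core import (
    AcousticSample,
    Condition,
    GeometryError,
    InvalidInputError,
    PhysicalConstants,
    PulseEchoEnsemble,
    db_per_cm_to_db_per_m,
)

__all__ = [
    "SimulationConfig",
    "generate_pulse",
    "pulse_sigma_t",
    "delta_T",
    "two_way_amplitude_ratio",
    "front_surface_reflection",
    "simulate_reference",
    "simulate_with_sample",
    "generate_ensemble_pair",
]

DEFAULT_SEED = 20201216


@dataclass(frozen=True)
class SimulationConfig:
    """Apparatus and acquisition settings for one simulated experiment.

    ``pulse_fractional_bandwidth`` is the -6 dB (half-amplitude) two-sided
    fractional bandwidth of the pulse spectrum.  ``noise_snr`` is the additive
    white-noise level in dB relative to the unit reference plate echo;
    ``numpy.inf`` disables noise.  ``trace_duration`` of ``None`` sizes the
    record to twice the nominal plate round trip, which accommodates plate
    echoes retarded by slow samples.
    """

    sampling_rate: float = 50e6          # Hz
    pulse_center_freq: float = 1.5e6     # Hz
    pulse_fractional_bandwidth: float = 0.6
    plate_depth: float = 0.03            # m
    noise_snr: float = 40.0              # dB re plate echo
    n_repeats: int = 100
    rng_seed: int = DEFAULT_SEED
    include_interface_loss: bool = False
    include_speckle: bool = False
    scatterers_per_mm: float = 5.0
    speckle_amplitude: float = 0.02      # scatterer amplitude s.d., re plate echo
    trace_duration: Optional[float] = None  # s

    def __post_init__(self) -> None:
        if self.sampling_rate < 10.0 * self.pulse_center_freq:
            raise InvalidInputError(
                "sampling_rate must be at least 10x pulse_center_freq "
                f"({self.sampling_rate:.3g} < 10 x {self.pulse_center_freq:.3g})"
            )
        if self.n_repeats < 1:
            raise InvalidInputError("n_repeats must be >= 1")
        if self.plate_depth <= 0:
            raise InvalidInputError("plate_depth must be positive")
        if not (0 < self.pulse_fractional_bandwidth < 2):
            raise InvalidInputError("pulse_fractional_bandwidth must be in (0, 2)")

    @property
    def duration(self) -> float:
        if self.trace_duration is not None:
            return self.trace_duration
        # twice the nominal round trip: covers echoes retarded by slow samples
        return 4.0 * self.plate_depth / 1447.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def pulse_sigma_t(config: SimulationConfig) -> float:
    """Temporal envelope s.d. (s) for the configured fractional bandwidth.

    A Gaussian envelope exp(-t^2 / 2 sigma_t^2) has half-amplitude spectral
    full width 2 sqrt(2 ln 2) / (2 pi sigma_t); equating that to
    ``bw * f0`` gives sigma_t.
    """
    bw_hz = config.pulse_fractional_bandwidth * config.pulse_center_freq
    return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bw_hz)


def generate_pulse(config: SimulationConfig) -> np.ndarray:
    """Sampled transmit pulse: Gaussian-enveloped sinusoid, peak amplitude 1.

    Returned on a symmetric time grid spanning +-5 envelope s.d. around the
    envelope peak.
    """
    sigma_t = pulse_sigma_t(config)
    half = int(np.ceil(5.0 * sigma_t * config.sampling_rate))
    t = np.arange(-half, half + 1) / config.sampling_rate
    return np.cos(2.0 * np.pi * config.pulse_center_freq * t) * np.exp(
        -0.5 * (t / sigma_t) ** 2
    )


def _pulse_spectrum(config: SimulationConfig, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """One-sided pulse magnitude spectrum on the rfft grid and its peak norm.

    Returns (freqs, spectrum, norm) where ``norm`` is the envelope-peak
    amplitude of a unit-spectrum echo after irfft, so that dividing traces by
    it makes an unscaled echo have envelope peak exactly 1.
    """
    sigma_t = pulse_sigma_t(config)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    a = 2.0 * (np.pi * sigma_t) ** 2
    spectrum = np.exp(-a * (freqs - config.pulse_center_freq) ** 2)
    norm = 2.0 * spectrum.sum() / n
    return freqs, spectrum, norm


def delta_T(thickness: float, c_s: float, constants: PhysicalConstants) -> float:
    """Closed-form substitution time shift 2 d (1/c_w - 1/c_s), s.

    Positive when the sample is faster than water (plate echo arrives earlier).
    """
    return 2.0 * thickness * (1.0 / constants.c_w - 1.0 / c_s)


def two_way_amplitude_ratio(alpha_db_cm: float, thickness: float) -> float:
    """Amplitude ratio 10^(-alpha 2d / 20) for a two-way pass through ``d`` m."""
    loss_db = db_per_cm_to_db_per_m(alpha_db_cm) * 2.0 * thickness
    return 10.0 ** (-loss_db / 20.0)


def front_surface_reflection(sample: AcousticSample, constants: PhysicalConstants) -> float:
    """Pressure reflection at the water->sample interface.

    Uses the explicit ``surface_reflectivity`` override when set, otherwise
    (Z2 - Z1)/(Z2 + Z1) from the sample's true impedance.
    """
    if sample.surface_reflectivity is not None:
        return float(sample.surface_reflectivity)
    if sample.true_velocity is None or sample.true_density is None:
        raise InvalidInputError(
            f"sample {sample.name!r} needs surface_reflectivity or "
            "true_velocity + true_density"
        )
    Z2 = sample.true_velocity * sample.true_density
    return (Z2 - constants.Z1) / (Z2 + constants.Z1)


def _interface_transmission(sample: AcousticSample, constants: PhysicalConstants) -> float:
    """Two-way pressure transmission product t_ws * t_sw through the front face."""
    Z2 = (sample.true_velocity or 0.0) * (sample.true_density or 0.0)
    if Z2 <= 0:
        raise InvalidInputError("interface loss requires true_velocity and true_density")
    Z1 = constants.Z1
    return (2.0 * Z2 / (Z1 + Z2)) * (2.0 * Z1 / (Z1 + Z2))


def _attenuation_filter(
    freqs: np.ndarray, alpha_db_cm_at_f0: float, f0: float, path_m: float
) -> np.ndarray:
    """Zero-phase amplitude filter for a one-way path with alpha linear in f."""
    alpha_f = alpha_db_cm_at_f0 * np.abs(freqs) / f0      # dB/cm at each f
    loss_db = db_per_cm_to_db_per_m(alpha_f) * path_m
    return 10.0 ** (-loss_db / 20.0)


def _synthesize(
    config: SimulationConfig,
    echoes: list[tuple[float, float, Optional[np.ndarray]]],
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    """Build the (n_repeats, n_samples) trace array from (delay, amp, filter) echoes."""
    n = config.n_samples
    freqs, spectrum, norm = _pulse_spectrum(config, n)
    total = np.zeros(freqs.shape, dtype=complex)
    for t_echo, amp, filt in echoes:
        contrib = spectrum * amp * np.exp(-2j * np.pi * freqs * t_echo)
        if filt is not None:
            contrib = contrib * filt
        total += contrib
    clean = np.fft.irfft(total, n) / norm
    traces = np.tile(clean, (config.n_repeats, 1))
    if np.isfinite(config.noise_snr):
        sigma = 10.0 ** (-config.noise_snr / 20.0)
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        traces = traces + rng.normal(0.0, sigma, size=traces.shape)
    return traces


def simulate_reference(
    config: SimulationConfig,
    constants: Optional[PhysicalConstants] = None,
    rng: Optional[np.random.Generator] = None,
) -> PulseEchoEnsemble:
    """Plate-only acquisition: one unit-amplitude echo at the water round trip."""
    constants = constants or PhysicalConstants()
    t_plate = 2.0 * config.plate_depth / constants.c_w
    traces = _synthesize(config, [(t_plate, 1.0, None)], rng)
    return PulseEchoEnsemble(
        alines=traces,
        sampling_rate=config.sampling_rate,
        condition=Condition.REFERENCE,
        plate_depth=config.plate_depth,
        pulse_center_freq=config.pulse_center_freq,
        metadata={"rng_seed": config.rng_seed, "noise_snr": config.noise_snr},
    )


def simulate_with_sample(
    sample: AcousticSample,
    config: SimulationConfig,
    constants: Optional[PhysicalConstants] = None,
    rng: Optional[np.random.Generator] = None,
) -> PulseEchoEnsemble:
    """Sample-on-plate acquisition.

    The A-line contains the front-surface echo, the shifted and attenuated
    plate echo, and (optionally) speckle from scatterers inside the sample.
    """
    constants = constants or PhysicalConstants()
    if sample.true_velocity is None or sample.true_attenuation_at_f0 is None:
        raise InvalidInputError(
            f"sample {sample.name!r} lacks ground-truth velocity/attenuation"
        )
    d = sample.thickness
    if d >= config.plate_depth:
        raise GeometryError(
            f"sample thickness {d} m must be less than plate depth "
            f"{config.plate_depth} m"
        )
    c_s = sample.true_velocity
    alpha0 = sample.true_attenuation_at_f0
    f0 = config.pulse_center_freq
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)

    t_plate_ref = 2.0 * config.plate_depth / constants.c_w
    t_front = 2.0 * (config.plate_depth - d) / constants.c_w
    t_plate = t_plate_ref - delta_T(d, c_s, constants)

    r_s = front_surface_reflection(sample, constants)
    trans = _interface_transmission(sample, constants) if config.include_interface_loss else 1.0

    echoes: list[tuple[float, float, Optional[np.ndarray]]] = [
        (t_front, r_s, None),
        (t_plate, trans, _attenuation_filter(freqs, alpha0, f0, 2.0 * d)),
    ]

    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if config.include_speckle:
        n_scat = max(int(round(config.scatterers_per_mm * d * 1e3)), 0)
        depths = rng.uniform(0.0, d, size=n_scat)
        amps = rng.normal(0.0, config.speckle_amplitude, size=n_scat)
        for z, a in zip(depths, amps):
            t_sc = t_front + 2.0 * z / c_s
            amp = a * (trans if config.include_interface_loss else 1.0)
            echoes.append((t_sc, amp, _attenuation_filter(freqs, alpha0, f0, 2.0 * z)))

    traces = _synthesize(config, echoes, rng)
    return PulseEchoEnsemble(
        alines=traces,
        sampling_rate=config.sampling_rate,
        condition=Condition.SAMPLE_IN,
        plate_depth=config.plate_depth,
        pulse_center_freq=config.pulse_center_freq,
        metadata={
            "rng_seed": config.rng_seed,
            "noise_snr": config.noise_snr,
            "sample_name": sample.name,
            "thickness": d,
        },
    )


def generate_ensemble_pair(
    sample: AcousticSample,
    config: SimulationConfig,
    constants: Optional[PhysicalConstants] = None,
) -> tuple[PulseEchoEnsemble, PulseEchoEnsemble, dict]:
    """Reference + sample-in ensembles with a ground-truth sidecar record.

    Child RNG streams are spawned deterministically from ``config.rng_seed``,
    so the same seed always reproduces the identical pair bit for bit.
    """
    constants = constants or PhysicalConstants()
    seq = np.random.SeedSequence(config.rng_seed)
    ref_seq, sam_seq = seq.spawn(2)
    reference = simulate_reference(config, constants, np.random.default_rng(ref_seq))
    sample_in = simulate_with_sample(sample, config, constants, np.random.default_rng(sam_seq))
    sidecar = {
        "sample": {
            "name": sample.name,
            "thickness": sample.thickness,
            "mass": sample.mass,
            "volume": sample.volume,
            "true_velocity": sample.true_velocity,
            "true_attenuation_at_f0": sample.true_attenuation_at_f0,
            "true_density": sample.true_density,
            "surface_reflectivity": sample.surface_reflectivity,
        },
        "config": asdict(config),
        "constants": {"c_w": constants.c_w, "Z1": constants.Z1, "f0": constants.f0},
    }
    reference.metadata["ground_truth"] = sidecar
    sample_in.metadata["ground_truth"] = sidecar
    return reference, sample_in, sidecar
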