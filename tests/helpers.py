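"""Shared helpers for the test suite."""

import numpy as np
from scipy.signal import hilbert

from echophantom.core import AcousticSample


def envelope_peak_time(trace, sampling_rate):
    """Sub-sample envelope peak via a parabola on the log envelope."""
    env = np.abs(hilbert(trace))
    i = int(np.argmax(env))
    l0, l1, l2 = np.log(env[i - 1 : i + 2])
    return (i + 0.5 * (l0 - l2) / (l0 - 2 * l1 + l2)) / sampling_rate


def make_sample(c_s, alpha, rho=1000.0, d=0.010, reflectivity=0.1):
    """Ground-truth specimen with a nominal 10 ml volume."""
    return AcousticSample(
        name="test",
        thickness=d,
        mass=rho * 1e-5,
        volume=1e-5,
        true_velocity=c_s,
        true_attenuation_at_f0=alpha,
        true_density=rho,
        surface_reflectivity=reflectivity,
    )
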