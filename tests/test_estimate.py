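from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from echophantom.core import (
    DetectionError,
    IncompatibleEnsembleError,
    InvalidInputError,
    NonPhysicalResultWarning,
    PhysicalConstants,
    RoundingPolicy,
)
from echophantom.estimate import (
    GateConfig,
    characterize,
    estimate_attenuation,
    estimate_backscatter,
    estimate_time_shift,
    estimate_velocity,
    impedance,
    locate_plate_echo,
    reflection_transmission,
)
from echophantom.simulate import (
    SimulationConfig,
    delta_T,
    generate_ensemble_pair,
    simulate_reference,
    simulate_with_sample,
)
from helpers import make_sample


def oracle_attenuation(ref_trace, sam_trace, sampling_rate, f0, thickness_m,
                       plate_gate, window_periods=6.0):
    """Brute-force attenuation: direct-summation windowed DFTs + log formula.

    Independent of the estimator code path: its own envelope/argmax gating,
    its own explicit DFT sums, its own dB arithmetic.
    """
    half = int(round(0.5 * window_periods / f0 * sampling_rate))

    def mag_at_f0(trace, lo_t, hi_t):
        env = np.abs(hilbert(trace))
        lo = int(np.floor(lo_t * sampling_rate))
        hi = int(np.ceil(hi_t * sampling_rate)) + 1
        center = lo + int(np.argmax(env[lo:hi]))
        acc = 0.0 + 0.0j
        for m in range(max(center - half, 0), min(center + half + 1, trace.size)):
            w = 0.5 - 0.5 * np.cos(
                2.0 * np.pi * (m - (center - half)) / (2 * half)
            )
            acc += trace[m] * w * np.exp(-2j * np.pi * f0 * m / sampling_rate)
        return abs(acc)

    A0 = mag_at_f0(ref_trace, *plate_gate[0])
    A = mag_at_f0(sam_trace, *plate_gate[1])
    d_cm = thickness_m * 100.0
    return -(20.0 / (2.0 * d_cm)) * np.log10(A / A0)


class TestLocatePlateEcho:
    def test_noise_free_reference_arrival(self, quiet_config, constants):
        ens = simulate_reference(quiet_config, constants)
        meas = locate_plate_echo(
            ens.alines[0], ens.sampling_rate, ens.plate_depth, constants
        )
        expected = 2.0 * quiet_config.plate_depth / constants.c_w
        assert abs(meas.t_plate - expected) <= 0.1 / ens.sampling_rate

    def test_imposed_shift_recovered_to_subsample(self, quiet_config, constants):
        # move the plate by 37 um: imposed delay 2*dz/c_w ~ 51 ns (2.6 samples)
        dz = 37e-6
        shifted = replace(quiet_config, plate_depth=quiet_config.plate_depth + dz)
        e1 = simulate_reference(quiet_config, constants)
        e2 = simulate_reference(shifted, constants)
        m1 = locate_plate_echo(e1.alines[0], e1.sampling_rate, e1.plate_depth, constants)
        m2 = locate_plate_echo(e2.alines[0], e2.sampling_rate, e1.plate_depth, constants)
        imposed = 2.0 * dz / constants.c_w
        assert abs((m2.t_plate - m1.t_plate) - imposed) < 0.1 / e1.sampling_rate

    def test_all_zero_trace_raises(self, quiet_config, constants):
        trace = np.zeros(4096)
        with pytest.raises(DetectionError):
            locate_plate_echo(trace, 50e6, 0.03, constants)


class TestTimeShift:
    def test_identical_ensembles_give_zero(self, quiet_config, constants):
        ens = simulate_reference(quiet_config, constants)
        shifts, mean = estimate_time_shift(ens, ens, constants, thickness=0.01)
        assert mean == 0.0
        assert np.all(shifts == 0.0)

    def test_fast_sample_shift_matches_forward_model(self, constants):
        # ~198 ns advance for a 1 cm slab at 1468 m/s; the repeat-averaged
        # estimate lands within a few ns of the closed form at 40 dB SNR
        cfg = SimulationConfig(noise_snr=40.0, n_repeats=100, rng_seed=11)
        sample = make_sample(c_s=1468.0, alpha=6.57, d=0.010)
        ref, sam, _ = generate_ensemble_pair(sample, cfg, constants)
        _, mean = estimate_time_shift(ref, sam, constants, thickness=0.010)
        assert mean == pytest.approx(delta_T(0.010, 1468.0, constants), abs=4e-9)

    def test_slow_sample_gives_negative_shift(self, quiet_config, constants):
        sample = make_sample(c_s=1038.0, alpha=1.0, d=0.010)
        ref = simulate_reference(quiet_config, constants)
        sam = simulate_with_sample(sample, quiet_config, constants)
        _, mean = estimate_time_shift(ref, sam, constants, thickness=0.010)
        assert mean < 0

    def test_mismatched_sampling_rates_rejected(self, quiet_config, constants):
        e1 = simulate_reference(quiet_config, constants)
        e2 = simulate_reference(
            replace(quiet_config, sampling_rate=25e6), constants
        )
        with pytest.raises(IncompatibleEnsembleError):
            estimate_time_shift(e1, e2, constants, thickness=0.01)


class TestVelocity:
    def test_zero_shift_returns_water_speed(self, constants):
        assert estimate_velocity(0.0, 0.01, constants) == pytest.approx(1447.0)

    def test_algebraic_inversion(self, constants):
        c = estimate_velocity(197.8e-9, 0.01, constants)
        assert c == pytest.approx(1468.1, abs=0.2)

    def test_negative_shift_slower_than_water(self, constants):
        assert estimate_velocity(-2e-6, 0.01, constants) < constants.c_w

    def test_nonphysical_result_warned_but_returned(self, constants):
        # a huge advance implies negative slowness
        with pytest.warns(NonPhysicalResultWarning):
            c = estimate_velocity(2e-5, 0.01, constants)
        assert c < 0

    def test_inverse_of_forward_delay_closed_form(self, constants):
        for c_true in (900.0, 1300.0, 1800.0, 2200.0):
            dt = delta_T(0.012, c_true, constants)
            assert estimate_velocity(dt, 0.012, constants) == pytest.approx(
                c_true, rel=1e-12
            )


class TestAttenuation:
    def test_transparent_ratio_gives_zero(self):
        assert estimate_attenuation(1.0, 1.0, 0.01) == 0.0

    def test_factor_ten_over_one_cm_is_ten_db_cm(self):
        assert estimate_attenuation(0.1, 1.0, 0.01) == pytest.approx(10.0)

    def test_per_repeat_arrays_supported(self):
        out = estimate_attenuation(np.array([0.1, 0.1]), np.array([1.0, 1.0]), 0.01)
        assert out == pytest.approx([10.0, 10.0])

    @pytest.mark.parametrize("A,A0", [(0.0, 1.0), (1.0, 0.0), (-0.1, 1.0)])
    def test_nonpositive_magnitudes_rejected(self, A, A0):
        with pytest.raises(InvalidInputError):
            estimate_attenuation(A, A0, 0.01)

    def test_monotone_in_true_attenuation(self, quiet_config, constants):
        estimates = []
        for alpha in (2.0, 6.0, 12.0):
            sample = make_sample(c_s=1500.0, alpha=alpha, d=0.010)
            ref = simulate_reference(quiet_config, constants)
            sam = simulate_with_sample(sample, quiet_config, constants)
            props = characterize(sample, ref, sam, constants)
            estimates.append(props.alpha)
        assert estimates[0] < estimates[1] < estimates[2]


class TestBackscatter:
    def test_equal_magnitudes_zero_db(self):
        table, raw = estimate_backscatter(1.0, 1.0)
        assert table == 0.0 and raw == 0.0

    def test_half_amplitude_six_db(self):
        table, raw = estimate_backscatter(0.5, 1.0)
        assert raw == pytest.approx(6.0206, abs=1e-3)
        assert table == pytest.approx(-6.0206, abs=1e-3)

    def test_simulated_surface_level_recovered(self, constants):
        # reflectivity set to -22.5 dB re the plate echo
        cfg = SimulationConfig(noise_snr=np.inf, n_repeats=1)
        sample = make_sample(
            c_s=1468.0, alpha=6.57, d=0.010, reflectivity=10 ** (-22.5 / 20)
        )
        ref = simulate_reference(cfg, constants)
        sam = simulate_with_sample(sample, cfg, constants)
        props = characterize(sample, ref, sam, constants)
        assert props.u == pytest.approx(-22.5, abs=0.1)
        assert props.u_raw == pytest.approx(22.5, abs=0.1)

    def test_zero_magnitude_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_backscatter(0.0, 1.0)


class TestImpedanceAndInterface:
    @pytest.mark.parametrize(
        "c,rho,expected_1e6",
        [(1468.0, 1082.0, 1.59), (2039.0, 1100.0, 2.24), (1000.0, 1000.0, 1.00)],
    )
    def test_impedance_with_rounding_policy(self, c, rho, expected_1e6):
        policy = RoundingPolicy()
        assert policy.round_impedance(impedance(c, rho)) / 1e6 == pytest.approx(
            expected_1e6
        )

    def test_matched_media(self, constants):
        r, t, R, T = reflection_transmission(constants.Z1, constants)
        assert (r, t, R, T) == (0.0, 1.0, 0.0, 1.0)

    def test_stiff_material_coefficients(self, constants):
        # frozen from direct evaluation of the interface formulas
        r, t, R, T = reflection_transmission(2.24e6, constants)
        assert r == pytest.approx(-0.2043011, abs=1e-6)
        assert t == pytest.approx(1.2043011, abs=1e-6)
        assert R == pytest.approx(0.0417389, abs=1e-6)
        assert T == pytest.approx(0.9582611, abs=1e-6)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(Z2=st.floats(1e4, 1e8))
    def test_conservation_identities(self, Z2):
        r, t, R, T = reflection_transmission(Z2, PhysicalConstants())
        assert abs(R + T - 1.0) < 1e-9
        assert abs((1.0 - r) - t) < 1e-9


class TestCharacterize:
    def test_transparent_sample_null_case(self, quiet_config, constants):
        rho_match = constants.Z1 / constants.c_w
        from echophantom.core import AcousticSample

        sample = AcousticSample(
            name="water",
            thickness=0.01,
            mass=rho_match * 1e-5,
            volume=1e-5,
            true_velocity=constants.c_w,
            true_attenuation_at_f0=1e-12,
            true_density=rho_match,
        )
        ref = simulate_reference(quiet_config, constants)
        sam = simulate_with_sample(sample, quiet_config, constants)
        with pytest.warns(NonPhysicalResultWarning):
            props = characterize(sample, ref, sam, constants)
        assert props.c_s == pytest.approx(constants.c_w, rel=1e-4)
        assert abs(props.alpha) < 0.05
        assert np.isnan(props.u)

    def test_soft_elastomer_chain(self, layfomm_sample, constants):
        cfg = SimulationConfig(noise_snr=40.0, n_repeats=50, rng_seed=21)
        ref, sam, _ = generate_ensemble_pair(layfomm_sample, cfg, constants)
        props = characterize(layfomm_sample, ref, sam, constants)
        assert props.c_s == pytest.approx(1468.0, rel=5e-3)
        assert props.alpha == pytest.approx(6.57, rel=0.03)
        policy = RoundingPolicy()
        assert policy.round_impedance(props.Z) / 1e6 == pytest.approx(1.59)

    def test_seed_fixed_run_is_deterministic(self, layfomm_sample, constants):
        cfg = SimulationConfig(noise_snr=40.0, n_repeats=5, rng_seed=77)
        ref, sam, _ = generate_ensemble_pair(layfomm_sample, cfg, constants)
        p1 = characterize(layfomm_sample, ref, sam, constants)
        p2 = characterize(layfomm_sample, ref, sam, constants)
        assert p1 == p2

    def test_interface_loss_bias_matches_analytic(self, constants):
        # simulating interface loss but not correcting for it inflates the
        # attenuation estimate by -(20/2d) log10(t_ws t_sw)
        d = 0.010
        sample = make_sample(c_s=1600.0, alpha=4.0, rho=1300.0, d=d, reflectivity=0.0)
        cfg = SimulationConfig(noise_snr=np.inf, n_repeats=1)
        ref = simulate_reference(cfg, constants)
        sam_plain = simulate_with_sample(sample, cfg, constants)
        sam_loss = simulate_with_sample(
            sample, replace(cfg, include_interface_loss=True), constants
        )
        a_plain = characterize(sample, ref, sam_plain, constants).alpha
        a_loss = characterize(sample, ref, sam_loss, constants).alpha
        Z2 = 1600.0 * 1300.0
        t_ws = 2 * Z2 / (constants.Z1 + Z2)
        t_sw = 2 * constants.Z1 / (constants.Z1 + Z2)
        analytic_bias = -(20.0 / (2.0 * d * 100)) * np.log10(t_ws * t_sw)
        assert a_loss > a_plain
        assert (a_loss - a_plain) == pytest.approx(analytic_bias, rel=1e-6)

    def test_velocity_inversion_grid_error_below_0p1_percent(self, constants):
        cfg = SimulationConfig(noise_snr=np.inf, n_repeats=1, plate_depth=0.04)
        ref = simulate_reference(cfg, constants)
        for c_true in (900.0, 1100.0, 1447.0, 1700.0, 2000.0, 2200.0):
            for d in (0.002, 0.010, 0.020, 0.030):
                sample = make_sample(c_s=c_true, alpha=0.5, d=d, reflectivity=0.0)
                sam = simulate_with_sample(sample, cfg, constants)
                shifts, mean = estimate_time_shift(ref, sam, constants, thickness=d)
                c_hat = estimate_velocity(mean, d, constants)
                assert abs(c_hat - c_true) / c_true < 1e-3

    def test_attenuation_equals_bruteforce_oracle(self, constants):
        # estimator vs independent direct-summation spectral oracle,
        # random noise-free cases, agreement to 1e-6 dB/cm
        rng = np.random.default_rng(2020)
        gc = GateConfig()
        for _ in range(10):
            c_true = rng.uniform(1000.0, 2100.0)
            alpha = rng.uniform(1.0, 12.0)
            d = rng.uniform(0.004, 0.020)
            sample = make_sample(c_s=c_true, alpha=alpha, d=d, reflectivity=0.05)
            cfg = SimulationConfig(noise_snr=np.inf, n_repeats=1)
            ref = simulate_reference(cfg, constants)
            sam = simulate_with_sample(sample, cfg, constants)
            props = characterize(sample, ref, sam, constants, gc)
            nominal = 2.0 * cfg.plate_depth / constants.c_w
            t_front = 2.0 * (cfg.plate_depth - d) / constants.c_w
            c_lo, c_hi = gc.velocity_search_range
            ref_gate = (nominal - gc.gate_halfwidth, nominal + gc.gate_halfwidth)
            sam_gate = (
                max(t_front + 2 * d / c_hi - gc.gate_margin, t_front + gc.gate_margin),
                t_front + 2 * d / c_lo + gc.gate_margin,
            )
            expected = oracle_attenuation(
                ref.alines[0], sam.alines[0], cfg.sampling_rate, constants.f0,
                d, (ref_gate, sam_gate), gc.window_periods,
            )
            assert props.alpha == pytest.approx(expected, abs=1e-6)
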