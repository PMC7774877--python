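# Methods

## Scope and model

`echophantom` characterizes candidate phantom materials two ways: acoustically,
by the water-bath pulse-echo substitution method, and mechanically, by tensile
stress–strain regression; both are then scored against cardiac-tissue
reference values. Because the measurement chain is the deliverable, the bench
apparatus is replaced by a forward simulator whose ground truth is known
exactly, which makes every stage of the chain verifiable end to end.

## Forward RF model

Propagation is one-dimensional single-path; no beamforming, diffraction,
focusing or nonlinearity is modeled. A trace is synthesized in the frequency
domain as a sum of echoes, each a Gaussian-spectrum pulse centered at the
working frequency f₀ with a delay applied as a phase ramp. Synthesis in the
frequency domain means sub-sample delays are represented exactly — relevant
because realistic substitution shifts (~100–200 ns) span only a few samples
at the default 50 MHz sampling rate.

For a reference acquisition the trace holds one unit-amplitude plate echo at
the water round trip 2D/c_w (plate depth D). With a sample of thickness d on
the plate, the trace holds:

1. a front-surface echo at 2(D−d)/c_w with pressure-reflection amplitude
   (Z₂−Z₁)/(Z₂+Z₁), or an explicit reflectivity override — the override is
   how specimens reproduce a *measured* surface backscatter level, which in
   a porous printed material is not determined by bulk impedance alone;
2. the plate echo advanced by ΔT = 2d(1/c_w − 1/c_s) and filtered by the
   zero-phase attenuation response 10^(−α(f)·2d/20), with α(f) = α(f₀)·f/f₀
   (attenuation linear in frequency, consistent with how the tissue
   reference is frequency-scaled);
3. optionally, weak scatterers (uniform positions, Gaussian amplitudes,
   default 5/mm) inside the sample, and the two-way front-interface
   transmission product t_ws·t_sw applied to anything crossing the surface.

Sign convention: ΔT ≡ t_reference − t_sample-in, so a sample faster than
water gives ΔT > 0 and the velocity relation returns c_s > c_w — the
convention under which the substitution formula is self-consistent.

White Gaussian noise is added per repeat at a configured SNR in dB relative
to the unit plate echo; the default acquisition is 100 repeats at 40 dB, a
realistic single-acquisition noise floor for a bench pulse-echo rig. The
default seed is 20201216 and every ensemble stores its seed and ground truth
in metadata. Interface loss and speckle default to off because the
estimation equations do not correct for either; enabling interface loss
demonstrates the known estimator bias (see below).

What the simulator does **not** emulate: transducer impulse response and
angular sensitivity, diffraction and focusing gain, phase aberration, plate
reverberations, multiple internal reflections inside the sample, and
physical backscatter microstructure. Passing recovery tests therefore shows
the estimator chain is correct for the modeled physics; it does not
establish accuracy bounds for bench data, where gate placement and
diffraction corrections dominate the error budget.

## Estimation chain

Echo arrival is the analytic-signal (Hilbert) envelope peak, refined by a
quadratic fit to the **log** envelope over the contiguous above-half-maximum
region. For a Gaussian envelope the log is exactly quadratic, so the fit is
exact in the noise-free limit; using the full half-maximum region (~50
samples) rather than three points keeps the vertex stable under noise —
per-repeat timing jitter at 40 dB SNR is ~7 ns, and the 100-repeat mean is
accurate to a few ns.

Spectral magnitudes A_f are read from a Hann-tapered gate centered on the
detected plate-echo peak (or, for the front-surface echo, on its
analytically known arrival), evaluated by an exact single-frequency DFT at
f₀ rather than at the nearest FFT bin; this removes bin-quantization error
and makes the estimator directly comparable to a brute-force spectral
oracle. The gate is 6 carrier periods long (configurable): long enough that
window-induced spectral smearing biases the attenuation estimate by under
1 % for the materials of interest, short enough to exclude neighboring
echoes for the thinnest (2.5 mm) specimen.

Gates: the reference plate echo is searched ±2 µs around its nominal
arrival; the sample-in plate echo is searched over the arrival interval
implied by a velocity search range of 500–4000 m/s, which accommodates both
slow silicones (echo retarded by several µs) and stiff photopolymers (echo
advanced). Detection requires the envelope peak to exceed 6× the whole-trace
median envelope; an all-zero or echo-free gate raises a detection error. The
front-surface magnitude is instead measured at its known arrival and
declared absent when below 5× the expected windowed-DFT noise level —
surface echoes sit near the noise envelope for well-matched materials, where
peak search would fail.

Estimates (velocity, attenuation, backscatter) are computed per repeat and
then averaged — not estimated from an averaged trace — and the per-repeat
standard deviation is reported. Impedance uses the mean velocity times the
mass/volume density. No diffraction or interface-loss correction is applied,
matching the substitution method as commonly practiced; consequently, when
interface loss is simulated, the attenuation estimate is biased high by
exactly −(20/2d)·log₁₀(t_ws·t_sw), a property the test suite asserts
analytically.

Non-physical results (negative slowness, velocity outside 500–4000 m/s) are
returned but flagged with a warning, so a batch run surfaces bad specimens
without aborting.

## Stiffness

Young's modulus is the ordinary least-squares slope of engineering stress on
engineering strain over a fit window, default 2–10 % strain — a standard
low-strain linear regime for soft elastomers; an intercept is retained so a
toe region below the window does not bias the slope. Stress uses the initial
4 mm × 10 mm cross-section (no true-stress correction). The synthetic
generator produces a linear curve (optionally with a C1-continuous quadratic
toe) with 2 % multiplicative Gaussian noise, 20 repeats per material. Shore A
hardness is carried as a pass-through column, never converted to modulus.

Comparison to myocardium uses the modulus range 0.18–0.28 MPa; error bands
are 100·|E_bound − E|/E_bound for each bound, i.e. relative to the tissue
bound — the form that reproduces conventional phantom-error statements —
and material pairs are compared by the modulus ratio.

## Comparison tables and rounding

The acoustic comparison scores each material by 100·|x − x_tissue|/x_tissue.
The tissue attenuation reference (0.5 dB/cm at 1 MHz) is scaled linearly in
frequency to the working frequency (0.75 dB/cm at 1.5 MHz) before
differencing; the impedance reference is 1.67 × 10⁶ kg·m⁻²·s⁻¹. Impedance
differences are computed from impedances rounded to 2 decimals in 10⁶ units:
published material tables round before differencing, and reproducing their
percentages requires differencing the rounded values. The rounding policy
(velocities to integer m/s, impedance 2-dp, attenuation percentages to
integers, impedance percentages to 2-dp) is a named object pinned by the
reproduction tests. One known discrepancy is asserted rather than hidden:
the softest silicone's tabulated attenuation (3.52 dB/cm) yields a 369 %
difference, while 303 % circulates alongside it; the recomputed value is the
one this package reports.

## Simulated study conditions

Specimen ground truth comes from the packaged acoustic table; front-surface
reflectivity is set to the tabulated backscatter level (10^(−|u|/20)).
Specimen thicknesses are a protocol choice (each material at a different
thickness): 10 mm for the three porous filaments, 2.5 mm for the strongly
attenuating photopolymer, 12 and 15 mm for the silicones, keeping two-way
insertion loss in the 10–15 dB range — deep enough to measure, shallow
enough to keep the attenuated plate echo far above the noise floor. Specimen
volume is nominally 10 ml. Acceptance-level runs use 100 acquisitions per
condition and 20 tension repeats per material; the full acceptance script
completes in seconds on one CPU.

## Numerical choices and edge cases

- Trace length defaults to twice the nominal plate round trip so plate
  echoes retarded by slow samples stay in-record; echoes are synthesized
  mid-trace, keeping circular-convolution wrap-around in the Gaussian tails
  below 10⁻⁹.
- Pulse fractional bandwidth is defined at half-amplitude (−6 dB) of the
  spectrum, default 0.6.
- The simulator requires sampling ≥ 10× f₀ and plate depth greater than
  sample thickness; violations raise typed errors.
- Repeats are paired index-wise between the two conditions when differencing
  arrival times.
- Sample densities outside 800–2000 kg/m³ warn (plausibility guard for
  tissue-mimicking inputs) without rejecting the input.

## Limitations

Single-frequency attenuation only (no spectral-slope fit), plate-relative
backscatter only (no calibrated backscatter coefficient), no viscoelasticity
or hysteresis in the tension model, and no uncertainty propagation into the
comparison percentages (point values, as conventionally reported). The water
reference impedance (1.48 × 10⁶) and water sound speed (1447 m/s) are kept
as independent constants and never reconciled through an implied water
density.
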