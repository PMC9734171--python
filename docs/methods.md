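# Methods

`paesim` simulates and processes the detection chain of an
optical-resolution photoacoustic endoscope whose ultrasound detector is a
dual-polarization fiber laser read out by heterodyne phase demodulation.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not establish.

## Sensor model

A short linear-cavity fiber laser of round-trip optical path `L_opt`
satisfies the resonance condition `(ω₀/c)·L_opt = 2πm`.  An acoustic
pressure `p` modulates the path length fractionally, `dL_opt/dp = S_m·L_opt`
with `S_m` in Pa⁻¹, so the lasing frequency shifts by `dω₀ = −ω₀·S_m·p`.
Integrating the frequency shift converts a tone `p = −p₀cos(Ωt)` into a
phase modulation

    Δθ(t) = p₀ · S_m(Ω) · G(Ω) · sin(Ωt),    G(Ω) = ω₀/Ω,

i.e. the acoustic response is amplified by the optical/acoustic frequency
ratio — `G ≈ 2×10⁷` for a 200 THz carrier and 10 MHz ultrasound.  The two
orthogonal polarization modes lase at slightly different frequencies (beat
`ω_b ≈ 2π×1.74 GHz`) and see *opposite* phase shifts under the
torsional-radial acoustic deformation, so the photodetector beat carries the
doubled modulation and the phase response is

    Θ(Ω) = 2·S_m(Ω)·G(Ω)   [rad/Pa].

`pressure_to_phase` implements the transduction in the frequency domain:
each spectral component is scaled by `S_m(Ω)·G(Ω)` and rotated by +π/2 (the
sine/cosine quadrature of the frequency-to-phase integration); DC maps to
zero.

**S_m model.** The mechanical response of the fiber is represented by a
single-pole (second-order) resonance with unit low-frequency gain,

    S_m(Ω) = S_m,base · |1 − (Ω/Ω_r)² + iΩ/(Q·Ω_r)|⁻¹,

peaking at `f_res = 22 MHz` with `|H| = Q` on resonance (default `Q = 5`).
This is a deliberate parameterization, not a finite-element model of the
torsional-radial mode: it reproduces the characteristic two-peak shape of
`Θ(Ω)` (gain roll-up toward low frequencies plus the mechanical resonance)
without claiming the exact measured curve.

**Choice of `S_m,base`.** The default is `2×10⁻¹² Pa⁻¹` (≈ 2×10⁻⁶ per MPa,
typical of bare silica sensors).  This value makes the pieces of the model
mutually consistent: with the quadrature phase-noise density
`N_q = 1.5×10⁻⁷ rad·Hz^(−1/2)` it yields an in-band phase response of
~1×10⁻⁴ rad/Pa and a noise-equivalent pressure density of ~1.5 mPa·Hz^(−1/2),
and it puts the onset of large phase excursions (2Δθ ~ rad) in the tens of
kPa, consistent with a ~50 kPa linear range for a wide-band arctangent
receiver.

**Carrier synthesis.** Simulating a 1.74 GHz carrier would waste samples;
the beat is synthesized directly at a configurable intermediate frequency
(default 50 MHz at 250 MS/s), mirroring a downshift-to-baseband receiver.
`ω_b` is retained in `SensorSpec` as metadata.  The carrier is

    v(t) = A(t)·cos(2πf_IF·t + 2Δθ(t) + θ₀),

with `A(t)` carrying the laser intensity noise — a relaxation-oscillation
tone at 1.7 MHz of configurable depth plus white amplitude noise — and the
phase carrying white quadrature noise of density `N_q` (an optional 1/f
excess below a corner frequency is off by default).  `θ₀` is uniform on
[0, 2π); every stochastic operation takes an explicit seed.

## Demodulation

The receiver mixes with cos/sin at `f_IF`, low-passes both paths with a
linear-phase FIR applied forward–backward (zero phase, so pulse arrival
times — hence depth maps — are not biased), and takes `arctan2(Q, I)`.
The filter transient (one filter length per edge) is trimmed; a least-squares
linear ramp (residual IF mismatch) is removed.  Because the arctangent is
exact in the carrier amplitude, intensity noise and slow common-mode carrier
drift are rejected to numerical precision — the simulated rejection of a 10%
relaxation-oscillation tone is far beyond the 40 dB requirement.

Two practical constraints are worth recording.  First, the nominal 200 MHz
demodulation bandwidth is capped at Nyquist when applied; in a direct
digital mixer the cutoff must additionally reject the image at `2·f_IF`, so
pipeline helpers default to a cutoff of `0.7·f_IF`.  Second,
`simulate_measurement` upsamples the record when the sample rate is below
`4.5·f_IF`; at lower rates the `2f_IF` mixing image aliases *into* the
demodulation band and corrupts the recovered phase.

Pressure calibration divides the demodulated phase spectrum by `Θ(Ω)` inside
the analysis band (default 3–30 MHz) and zeroes everything outside — masked
rather than extrapolated, to avoid fabricating out-of-band pressure.

## Calibration workflow

The response spectrum is measured hydrophone-style: a broadband planar pulse
is recorded simultaneously as the sensor's (doubled) phase trace `d(t)` and
a reference voltage trace converted to pressure via the hydrophone
sensitivity (`S_n = 55 mV/MPa`) and amplifier gain (41 dB); the ratio
`|D(Ω)|/|P(Ω)|` is formed per FFT bin, with bins masked (not divided) where
the reference spectrum falls below a floor fraction of its in-band peak.
Phase noise is estimated from a signal-free 2 ms record by Welch's method
with 1400-sample segments, Hann window and 512-sample overlap (the defaults
are exactly these; all three are configurable, as is the sample rate, which
fixes the bin width).  Then

    NEPD(Ω) = N_q(Ω)/Θ(Ω),    NEP_rms = sqrt(∫_band NEPD(f)² df).

The integral runs over ordinary frequency in Hz.  This is a documented
convention: a flat 1.5 mPa·Hz^(−1/2) density over 3–30 MHz then integrates
to 7.79 Pa (≈ 8 Pa), which is the only reading consistent with a per-√Hz
density.  One-sided PSDs are used throughout.

A closed-form utility compares resonator-type (intensity-readout) sensors:
`NEPD = (4√3·N_i/(9Q_c) + N_q/G)/S_m`, which with `N_i = 0` reduces to the
heterodyne expression `N_q/Θ` with `Θ = G·S_m`.

## Phantoms and the forward model

Vessel phantoms are collections of cylindrical segments (polyline
centerline, radius, per-vessel sO₂ and relative hemoglobin concentration
`c_hb`) in a slab: sinuous trunks alternating artery (sO₂ 0.92–0.98) and
vein (0.58–0.72), side branches inheriting the trunk's class, and short thin
capillaries (0.74–0.88).  The default scene is an 0.8 mm slab with three
trunks at 0.12–0.3 mm depth — small enough to image densely in seconds,
large enough to give each vessel tens of centerline pixels.  An
"inflamed" frame is built by adding blood-rich small vessels
(`add_capillaries`), which raises vessel density and mean sO₂ the way
hyperemia does.

The optical-acoustic forward model is deliberately geometric: a Gaussian
beam of lateral intensity FWHM `w(z) = w₀·sqrt(1+((z−z_f)/z_R)²)` deposits
energy in absorbers; each depth sample radiates a bipolar Gaussian-derivative
pulse (default 30 ns width — the emitted waveform is not otherwise
specified) arriving at `t = z/c` with `c = 1500 m/s` (water coupling); the
unfocused sensor sums them.  Absorption is
`μ_a(λ) = ε_HbO₂(λ)·sO₂·c_hb + ε_Hb(λ)·(1−sO₂)·c_hb` with extinction values
at 532/558 nm from the standard tabulated hemoglobin compilation; their
absolute scale cancels in sO₂.  The two wavelength responses share one
record, separated by the pulse interleave delay (1500 ns; 2300 ns for the
rotational-endoscopy configuration).

`w₀ = 7.4 µm` is the system lateral resolution; `z_R` defaults to 120 µm so
that `w(±300 µm) ≈ 20 µm`, matching the measured depth-dependent resolution
of a real low-NA probe rather than the tighter ideal-diffraction value — the
beam profile and its growth law are configuration, not derivation.

Numerical choices: lateral integration uses a Gaussian quadrature grid in
units of the local beam sigma (7×7 points to ±2.2σ by default — adequate for
smooth vessels since the two-wavelength ratio cancels geometry exactly); the
blade edge instead uses the closed-form Gaussian/half-plane overlap
`Φ(d/σ(z))`, because a hard per-point membership test quantizes the edge
profile, and the sheet is deposited on the single nearest depth sample so
the measured edge reflects one well-defined beam width.  Segments are pruned
per A-line by bounding box before distance evaluation.

## Image formation

Records are split at the interleave boundary; the arrival time is the
envelope peak (analytic-signal magnitude) of the 532 nm channel
(configurable); depth = arrival × c.  Per-wavelength amplitudes are measured
in a gate of ±90 ns around the arrival.  Two amplitude metrics are kept:

* `amp_pp` — gated peak-to-peak, the conventional C_Hb surrogate;
* `amp_rms` — `sqrt(mean(x²) − σ_noise²)` over the gate.

sO₂ unmixing uses `amp_rms`.  The reason is statistical, not cosmetic: the
peak-to-peak of a noisy record is biased upward by the noise extremes, by the
same *absolute* amount at both wavelengths, which drags the amplitude ratio
toward unity and biases high sO₂ values low by up to ~0.08 at 20 dB SNR.
The noise-compensated energy estimate is unbiased and brings the per-vessel
error within ±0.05 under the same conditions.

Detection uses the mean gate envelope against `k·σ_noise` (default `k = 3`):
a noise-only gate has mean envelope ≈ 1.3σ and is rejected, while a pulse at
20 dB SNR clears the threshold comfortably.  Unmixing solves the 2×2
extinction system for the two concentrations, clips sO₂ to [0, 1], masks
pixels where both amplitudes vanish, and rejects a singular extinction
matrix.

Scan geometry: rotational mode maps an A-line index to an arc-length lateral
coordinate `working_distance × angle_step` (2.75 mm and 0.1° give 4.80 µm ≈
5 µm) and a B-scan index to a pullback row pitch `pullback_speed/bscan_rate`
(10 µm at 10 µm/s and 1 Hz); raster mode is a row-major grid.  Where the
nominal angular coverage in a configuration disagrees with
`alines_per_bscan × angle_step`, the geometry object trusts the configured
numbers.

Edge resolution: the blade-scan amplitude profile is differentiated to a
line-spread function and a Gaussian is fitted.  The central-difference
derivative convolves the LSF with a 2·pitch boxcar; its known variance
contribution `pitch²/3` is subtracted from the fitted variance, floored at
the `pitch²/12` sampling limit (a delta-like LSF therefore reports the scan
step, not zero).  The lateral quadrature for this measurement extends to
3.5σ — tighter truncation clips the Gaussian tails and biases the fitted
width low by several percent.

## Vessel statistics

C_Hb maps are thresholded and cleaned of components below 9 px
(8-connectivity).  `segment_vessels` defaults to an automatic bimodal (Otsu)
split; for the synthetic time-lapse comparison the default policy is instead
a *fixed* threshold at 15% of the baseline frame's 99th-percentile
amplitude, reused for every frame.  Two reasons: on a sparse map with an
empty background Otsu lands inside the vessel amplitude distribution and
drops dim vessels, and a per-frame automatic threshold makes a density
*change* partly an artifact of threshold drift.  Skeletonization thins the
mask to 1 px centerlines; junction pixels (≥3 skeleton neighbors,
8-connected) are removed, branches shorter than 3 px dropped, and per branch
the diameter is twice the mean distance-transform value along the
centerline, with C_Hb/sO₂ means sampled on centerline pixels.  Vessel
density is the vessel-pixel fraction of the ROI; a count-based alternative
is available.  Repeated-measures ANOVA is delegated to statsmodels and only
smoke-tested — the descriptive metrics are the contribution here.

## Validation experiments and their scope

`paesim.validation` packages five seeded end-to-end experiments (also run by
`scripts/acceptance.py`): detection-chain round trip (<1% rms, AM rejection
≥40 dB), calibration-loop noise-density recovery (within 10% via the
NEPD·Θ identity), blade-edge FWHM recovery (within 5% at focus and ±300 µm),
per-vessel sO₂ recovery (±0.05 at 20 dB SNR; <2 pp spread across ∓200 µm
focal offsets), and vessel statistics (Dice ≥0.9 against the rasterized
phantom; a programmed ~24% density increase recovered within 2 pp).  Imaging
experiments use an 80×80 raster over 0.8 mm — sizes chosen so a full
validation run completes in about a minute while every vessel spans enough
pixels for stable statistics.

What passing these does *not* show: the forward model has no acoustic
propagation (no diffraction, attenuation or heterogeneity), no optical
scattering or wavelength-dependent fluence decay with depth, no motion, and
additive white noise only.  Real-tissue effects — spectral coloring of the
fluence, acoustic reverberation (the reason the in-vivo interleave is
2300 ns), peristaltic motion — are outside the simulated conditions, so the
recovery numbers characterize the processing chain, not in-vivo accuracy.
The model's own NEPD (~1.3 mPa·Hz^(−1/2) in band, rms NEP ~10 Pa over
3–30 MHz) depends on the parameterized `S_m` resonance and is reported as a
model output, not a reproduction of a measured curve.
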