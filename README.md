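# paesim

Simulation and processing suite for optical-resolution photoacoustic
endoscopy (PAE) with an optical-heterodyne **laser ultrasound sensor**:
the full detection chain from acoustic pressure to functional sO₂ maps,
exercisable end to end on synthetic phantoms.

It is aimed at instrument builders and image-analysis developers who want a
reproducible software twin of this detection scheme — to study receiver
design (demodulation bandwidth, noise budgets, linearity), to validate
processing code against known ground truth, or to generate realistic
synthetic datasets for vessel-analysis pipelines.

## The model in brief

A short fiber-laser cavity with round-trip optical path `L_opt` obeys the
resonance condition `(ω₀/c)·L_opt = 2πm`.  Ultrasound modulates the path
fractionally, `dL_opt/dp = S_m·L_opt`, so a tone `p = −p₀cos(Ωt)` phase-
modulates the laser by

```
Δθ(t) = p₀ · S_m(Ω) · G(Ω) · sin(Ωt),        G(Ω) = ω₀/Ω
```

with a gain factor `G ≈ 2×10⁷` at a 200 THz carrier and 10 MHz ultrasound.
The two polarization modes (beat `ω_b ≈ 2π × 1.74 GHz`) see opposite shifts
±Δθ, so I/Q demodulation of the beat — `arctan(Q/I)` — reads the doubled
modulation `2Δθ(t)` with a phase response `Θ(Ω) = 2·S_m(Ω)·G(Ω)`.
Sensitivity is characterized by the noise-equivalent pressure density
`NEPD(Ω) = N_q(Ω)/Θ(Ω)` and its band integral, the rms NEP.  Imaging adds a
focused dual-wavelength (532/558 nm) excitation beam, per-A-line feature
extraction, linear spectral unmixing of oxy-/deoxyhemoglobin into sO₂, map
assembly over raster or rotational+pullback scans, and skeleton-based
vessel statistics.

Modules: `sensor` (pressure→phase→carrier), `demod` (I/Q receiver,
calibration inversion), `calibration` (response spectrum, Welch noise,
NEPD/NEP), `phantom` (vasculature and blade-edge phantoms, forward model),
`imaging` (demux, features, sO₂, maps, resolution), `vessels`
(segmentation, skeleton metrics, time-lapse statistics), plus YAML config,
HDF5/CSV/TIFF I/O and a `paesim` command-line interface
(`calibrate`, `edge-resolution`, `simulate-scan`, `process-scan`).

## Worked example

```python
import math
from paesim import (SensorSpec, OpticalModel, ScanGeometry, gain_factor,
                    phase_response_spectrum, run_calibration,
                    make_vessel_phantom, make_blade_edge,
                    measure_edge_resolution, simulate_scan)

spec = SensorSpec()
print(f"gain factor at 10 MHz     : {gain_factor(spec, 2*math.pi*10e6):.3g}")
print(f"phase response at 10 MHz  : {phase_response_spectrum(spec, 2*math.pi*10e6):.3g} rad/Pa")

cal = run_calibration(spec, rng_seed=0)
print(f"in-band NEPD (5-25 MHz)   : {cal['nepd_inband_mpa']:.2f} mPa Hz^-1/2")
print(f"rms NEP (3-30 MHz)        : {cal['rms_nep_pa']:.1f} Pa")

optical = OpticalModel()
blade = make_blade_edge(depth=optical.focus_depth)
print(f"edge FWHM at focus        : {measure_edge_resolution(blade, optical)*1e6:.2f} um")

phantom = make_vessel_phantom(rng_seed=7)
geometry = ScanGeometry(mode="raster", raster_range=(0.8e-3, 0.8e-3),
                        raster_pixels=(60, 60))
maps = simulate_scan(phantom, geometry, optical, rng_seed=7)
so2 = maps.so2_map[maps.mask]
print(f"scan: {int(maps.mask.sum())} vessel pixels, "
      f"sO2 range {so2.min():.2f}-{so2.max():.2f}")
```

prints

```
gain factor at 10 MHz     : 1.93e+07
phase response at 10 MHz  : 9.67e-05 rad/Pa
in-band NEPD (5-25 MHz)   : 1.33 mPa Hz^-1/2
rms NEP (3-30 MHz)        : 10.0 Pa
edge FWHM at focus        : 7.42 um
scan: 1147 vessel pixels, sO2 range 0.69-0.99
```

Reading the numbers: the 193 THz/10 MHz frequency ratio gives the 1.93×10⁷
transduction gain; with the default acoustic modulation coefficient and
quadrature noise density the calibrated chain sits at ~1.3 mPa·Hz^(−1/2)
noise-equivalent pressure in band (rms NEP ~10 Pa over 3–30 MHz); the
blade-edge pipeline recovers the configured 7.4 µm beam waist; and the
simulated raster scan produces sO₂ maps spanning venous (~0.6–0.7) to
arterial (~0.95+) saturations, matching the phantom's per-vessel truth.

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices, and their limits.

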