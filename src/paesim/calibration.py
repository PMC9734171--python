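"""Sensitivity calibration: acoustic response, phase noise, NEPD and rms NEP.

The calibration workflow mirrors a hydrophone-referenced measurement: the
sensor's phase record d(t) and a reference hydrophone voltage for the same
planar ultrasound pulse are Fourier transformed, and the response spectrum
|D(Omega)|/|P(Omega)| (rad/Pa) is formed in band.  The quadrature phase-noise
density N_q is estimated from a signal-free phase record by Welch's method
(1400-sample segments, Hann window, 512-sample overlap by default).  Their
ratio

    NEPD(Omega) = N_q(Omega) / Theta(Omega)     [Pa·Hz^-1/2]

is the noise-equivalent pressure density, and its band integral

    NEP_rms = sqrt( ∫_band NEPD(f)^2 df )       [Pa]

the root-mean-square noise-equivalent pressure.  The integral runs over
ordinary frequency f in Hz — the only convention under which a flat
1.5 mPa·Hz^-1/2 density over 3–30 MHz integrates to ~8 Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trace import SpectralDensity, TimeTrace

__all__ = [
    "HydrophoneSpec",
    "NepdSpectrum",
    "response_spectrum",
    "welch_phase_noise",
    "nepd_spectrum",
    "rms_nep",
    "resonator_nepd",
    "planar_pulse",
    "run_calibration",
]


@dataclass
class HydrophoneSpec:
    """Reference needle hydrophone: sensitivity, amplifier gain, averaging."""

    Sn: float = 55e-9          # V/Pa (55 mV/MPa)
    gain_db: float = 41.0      # post-amplifier gain
    n_averages: int = 8000     # pulse-trace averages
    noise_rms: float = 768.0   # Pa, its own rms NEP (for comparison)

    def __post_init__(self) -> None:
        if not self.Sn > 0:
            raise ValueError("Sn must be positive")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    def voltage_to_pressure(self, v: TimeTrace) -> TimeTrace:
        """Undo amplifier gain and sensitivity: Pa = V / (Sn·10^(gain/20))."""
        if v.unit != "V":
            raise ValueError("expected a voltage trace")
        scale = self.Sn * 10.0 ** (self.gain_db / 20.0)
        return v.with_samples(v.samples / scale, unit="Pa")


@dataclass
class NepdSpectrum:
    """Noise-equivalent pressure density on a frequency grid (Pa·Hz^-1/2)."""

    freqs: np.ndarray
    nepd: np.ndarray
    band: tuple[float, float]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.nepd = np.asarray(self.nepd, dtype=float)
        if self.freqs.shape != self.nepd.shape:
            raise ValueError("freqs and nepd must be congruent")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.nepd[np.isfinite(self.nepd)] < 0):
            raise ValueError("nepd must be non-negative")


def response_spectrum(
    sensor_phase: TimeTrace,
    hydro_voltage: TimeTrace,
    hspec: HydrophoneSpec,
    band: tuple[float, float] = (3e6, 30e6),
    floor_frac: float = 0.05,
) -> SpectralDensity:
    """Calibrated acoustic response |D(Omega)|/|P(Omega)| in rad/Pa.

    Both traces must cover the same pulse event at the same sample rate and
    length.  Bins where the reference pressure spectrum falls below
    ``floor_frac`` of its in-band maximum are masked (NaN), not divided —
    a near-zero reference would fabricate response values.
    """
    if sensor_phase.unit != "rad":
        raise ValueError("sensor_phase must be in rad")
    if len(sensor_phase) != len(hydro_voltage) or \
            sensor_phase.sample_rate != hydro_voltage.sample_rate:
        raise ValueError("traces must share length and sample rate")
    pressure = hspec.voltage_to_pressure(hydro_voltage)
    n = len(sensor_phase)
    f = np.fft.rfftfreq(n, d=sensor_phase.dt)
    d_spec = np.abs(np.fft.rfft(sensor_phase.samples))
    p_spec = np.abs(np.fft.rfft(pressure.samples))
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError("analysis band contains no frequency bins")
    floor = floor_frac * p_spec[sel].max()
    ratio = np.full(sel.sum(), np.nan)
    ok = p_spec[sel] > floor
    ratio[ok] = d_spec[sel][ok] / p_spec[sel][ok]
    return SpectralDensity(f[sel], ratio, "rad/Pa")


def welch_phase_noise(
    nq_trace: TimeTrace,
    nperseg: int = 1400,
    noverlap: int = 512,
    window: str = "hann",
) -> SpectralDensity:
    """Phase-noise amplitude density by Welch's method (rad·Hz^-1/2).

    Square root of the one-sided Welch PSD with the stated segment length,
    overlap and window (defaults 1400 / 512 / Hann).
    """
    if nq_trace.unit != "rad":
        raise ValueError("expected a phase trace (rad)")
    if len(nq_trace) < nperseg:
        raise ValueError(
            f"trace of {len(nq_trace)} samples is shorter than one "
            f"{nperseg}-sample segment")
    f, psd = sps.welch(nq_trace.samples, fs=nq_trace.sample_rate,
                       window=window, nperseg=nperseg, noverlap=noverlap)
    return SpectralDensity(f[1:], np.sqrt(psd[1:]), "rad·Hz^-1/2")


def nepd_spectrum(noise: SpectralDensity, theta: SpectralDensity,
                  band: tuple[float, float] = (3e6, 30e6)) -> NepdSpectrum:
    """NEPD(Omega) = N_q(Omega)/Theta(Omega), on the noise grid.

    ``theta`` is interpolated onto the noise grid over their overlap; bins
    where ``theta`` is masked stay masked.
    """
    lo = max(noise.freqs[0], theta.freqs[0])
    hi = min(noise.freqs[-1], theta.freqs[-1])
    if lo >= hi:
        raise ValueError("noise and response grids do not overlap")
    sel = (noise.freqs >= lo) & (noise.freqs <= hi)
    f = noise.freqs[sel]
    th = theta.interp_to(f)
    nepd = np.where(np.isfinite(th) & (th > 0), noise.values[sel] / th, np.nan)
    return NepdSpectrum(f, nepd, band)


def rms_nep(nepd: NepdSpectrum, band: tuple[float, float] | None = None) -> float:
    """Band-integrated rms noise-equivalent pressure in Pa.

    sqrt of the trapezoidal integral of NEPD(f)^2 over the band, with f in
    Hz; the band edges are interpolated onto the grid.  Raises if the band
    extends outside the grid span.
    """
    lo, hi = band if band is not None else nepd.band
    if lo < nepd.freqs[0] or hi > nepd.freqs[-1] or lo >= hi:
        raise ValueError("integration band outside the NEPD grid span")
    inner = (nepd.freqs > lo) & (nepd.freqs < hi)
    f = np.concatenate(([lo], nepd.freqs[inner], [hi]))
    good = np.isfinite(nepd.nepd)
    if good.sum() < 2:
        raise ValueError("too few unmasked NEPD bins to integrate")
    vals = np.interp(f, nepd.freqs[good], nepd.nepd[good])
    return float(np.sqrt(np.trapezoid(vals**2, f)))


def planar_pulse(p0: float = 1e3, center_freq: float = 12e6,
                 sample_rate: float = 250e6, duration: float = 20e-6,
                 arrival: float | None = None) -> TimeTrace:
    """Broadband planar ultrasound pulse: Gaussian-windowed bipolar burst.

    A Gaussian-derivative pulse whose spectrum peaks at ``center_freq`` and
    spans the 3–30 MHz analysis band, with peak amplitude ``p0`` (Pa).
    """
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    t0 = arrival if arrival is not None else duration / 2.0
    tau = 1.0 / (2.0 * np.pi * center_freq)
    g = -(t - t0) * np.exp(-((t - t0) ** 2) / (2.0 * tau**2))
    g *= p0 / np.abs(g).max()
    return TimeTrace(g, sample_rate, "Pa")


def run_calibration(
    spec,
    hspec: HydrophoneSpec | None = None,
    rng_seed: int = 0,
    band: tuple[float, float] = (3e6, 30e6),
    sample_rate: float = 250e6,
    noise_duration: float = 2e-3,
    pulse_p0: float = 1e3,
) -> dict:
    """Full sensitivity-calibration workflow on simulated records.

    Simulates a planar reference pulse, forms the sensor's doubled phase
    record and the hydrophone voltage record for the same event, computes
    the calibrated response spectrum, estimates the phase-noise density from
    a signal-free record (Welch), and combines them into the NEPD spectrum
    and its band-integrated rms NEP.  Returns a dict with the spectra
    (``theta``, ``noise``, ``nepd``) and scalars (``rms_nep_pa``,
    ``nepd_inband_mpa``), all seeded through ``rng_seed``.
    """
    from .sensor import pressure_to_phase

    hspec = hspec or HydrophoneSpec()
    rng = np.random.default_rng(rng_seed)

    p = planar_pulse(p0=pulse_p0, sample_rate=sample_rate)
    dtheta = pressure_to_phase(spec, p)
    sensor_phase = dtheta.with_samples(2.0 * dtheta.samples)  # doubled readout
    scale = hspec.Sn * 10.0 ** (hspec.gain_db / 20.0)
    hydro = p.with_samples(p.samples * scale, unit="V")

    theta = response_spectrum(sensor_phase, hydro, hspec, band=band)

    n_noise = int(round(noise_duration * sample_rate))
    sigma = spec.Nq_density * np.sqrt(sample_rate / 2.0)
    nq_trace = TimeTrace(rng.normal(0.0, sigma, n_noise), sample_rate, "rad")
    noise = welch_phase_noise(nq_trace)

    nepd = nepd_spectrum(noise, theta, band=band)
    # the Welch grid's first bin may sit just above the nominal band edge
    int_band = (max(band[0], nepd.freqs[0]), min(band[1], nepd.freqs[-1]))
    rms = rms_nep(nepd, band=int_band)
    inband = nepd.nepd[(nepd.freqs >= 5e6) & (nepd.freqs <= 25e6)]
    inband = inband[np.isfinite(inband)]
    return {
        "theta": theta,
        "noise": noise,
        "nepd": nepd,
        "rms_nep_pa": rms,
        "nepd_inband_mpa": float(np.mean(inband) * 1e3) if inband.size else float("nan"),
        "band": band,
    }


def resonator_nepd(Ni: float, Nq: float, Qc: float, G: float, Sm: float) -> float:
    """Sensitivity of a resonator-type (slope-detection) optical sensor.

    NEPD = (4·sqrt(3)·N_i/(9·Q_c) + N_q/G) / S_m, in Pa·Hz^-1/2 — the
    closed-form comparison between intensity-readout resonator sensors and
    the heterodyne phase readout (which with N_i = 0 reduces to
    N_q/(G·S_m) = N_q/Theta with Theta = G·S_m).
    """
    if not (Qc > 0 and G > 0 and Sm > 0):
        raise ValueError("Qc, G and Sm must be positive")
    if Ni < 0 or Nq < 0:
        raise ValueError("noise densities must be non-negative")
    return (4.0 * np.sqrt(3.0) * Ni / (9.0 * Qc) + Nq / G) / Sm
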