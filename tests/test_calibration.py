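"""Calibration workflow: response spectrum, Welch noise, NEPD, rms NEP."""

import math

import numpy as np
import pytest

from paesim import (HydrophoneSpec, NepdSpectrum, SensorSpec, SpectralDensity,
                    TimeTrace, nepd_spectrum, phase_response_spectrum,
                    planar_pulse, pressure_to_phase, resonator_nepd,
                    response_spectrum, rms_nep, run_calibration,
                    welch_phase_noise)

FS = 250e6
TWO_PI = 2 * math.pi


class TestResponseSpectrum:
    def _records(self, spec, hspec, p0=1e3):
        p = planar_pulse(p0=p0, sample_rate=FS)
        dth = pressure_to_phase(spec, p)
        sensor = dth.with_samples(2 * dth.samples)
        scale = hspec.Sn * 10 ** (hspec.gain_db / 20)
        hydro = p.with_samples(p.samples * scale, unit="V")
        return sensor, hydro

    def test_self_consistency_recovers_theta(self, quiet_spec):
        """Phase record built from the hydrophone's own pressure recovers
        Theta(Omega) within 2% across the band."""
        hspec = HydrophoneSpec()
        sensor, hydro = self._records(quiet_spec, hspec)
        est = response_spectrum(sensor, hydro, hspec)
        good = np.isfinite(est.values)
        truth = phase_response_spectrum(quiet_spec,
                                        TWO_PI * est.freqs[good])
        np.testing.assert_allclose(est.values[good], truth, rtol=0.02)

    def test_gain_db_unit_propagation(self, quiet_spec):
        """+6.02 dB of amplifier gain halves the inferred pressure and
        doubles the response ratio."""
        h1 = HydrophoneSpec(gain_db=41.0)
        sensor, hydro = self._records(quiet_spec, h1)
        r1 = response_spectrum(sensor, hydro, h1)
        h2 = HydrophoneSpec(gain_db=41.0 + 20 * math.log10(2))
        r2 = response_spectrum(sensor, hydro, h2)
        good = np.isfinite(r1.values) & np.isfinite(r2.values)
        np.testing.assert_allclose(r2.values[good], 2 * r1.values[good],
                                   rtol=1e-9)

    def test_sqrt_n_averaging_law(self, rng):
        """Averaging M independent noisy pulse records shrinks the residual
        noise rms like 1/sqrt(M)."""
        n = 4096
        sigma = 50.0
        m = 64
        traces = rng.normal(0, sigma, (m, n))
        single_rms = np.sqrt(np.mean(traces[0] ** 2))
        avg_rms = np.sqrt(np.mean(traces.mean(axis=0) ** 2))
        assert avg_rms / single_rms == pytest.approx(1 / math.sqrt(m),
                                                     rel=0.25)

    def test_weak_reference_bins_masked(self, quiet_spec):
        hspec = HydrophoneSpec()
        sensor, hydro = self._records(quiet_spec, hspec)
        est = response_spectrum(sensor, hydro, hspec, floor_frac=0.5)
        assert np.isnan(est.values).any()
        assert np.isfinite(est.values).any()


class TestWelchPhaseNoise:
    def test_white_noise_density_recovered(self, rng):
        """Known white density d recovered within 10% in band (2 ms)."""
        d = 1.5e-7
        n = int(2e-3 * FS)
        tr = TimeTrace(rng.normal(0, d * math.sqrt(FS / 2), n), FS, "rad")
        est = welch_phase_noise(tr)
        assert est.band_mean((3e6, 30e6)) == pytest.approx(d, rel=0.10)

    def test_sinusoid_gives_single_peak(self):
        n = int(0.2e-3 * FS)
        t = np.arange(n) / FS
        tr = TimeTrace(1e-3 * np.sin(TWO_PI * 10e6 * t), FS, "rad")
        est = welch_phase_noise(tr)
        i = np.argmax(est.values)
        assert est.freqs[i] == pytest.approx(10e6, rel=0.01)
        away = np.abs(est.freqs - 10e6) > 2e6
        assert est.values[away].max() < 1e-3 * est.values[i]

    def test_parseval_normalization(self, rng):
        n = int(2e-3 * FS)
        tr = TimeTrace(rng.normal(0, 1e-6, n), FS, "rad")
        est = welch_phase_noise(tr)
        integral = np.trapezoid(est.values ** 2, est.freqs)
        assert integral == pytest.approx(tr.samples.var(), rel=0.01)

    def test_short_trace_rejected(self):
        tr = TimeTrace(np.zeros(1000), FS, "rad")
        with pytest.raises(ValueError):
            welch_phase_noise(tr)


class TestNepd:
    def test_pointwise_division(self):
        f = np.linspace(3e6, 30e6, 100)
        noise = SpectralDensity(f, np.full(100, 1.5e-7), "rad·Hz^-1/2")
        theta = SpectralDensity(f, np.full(100, 1e-4), "rad/Pa")
        nepd = nepd_spectrum(noise, theta)
        np.testing.assert_allclose(nepd.nepd, 1.5e-3, rtol=1e-12)

    def test_doubling_theta_halves_nepd(self):
        f = np.linspace(3e6, 30e6, 50)
        noise = SpectralDensity(f, np.full(50, 2e-7), "rad·Hz^-1/2")
        t1 = SpectralDensity(f, np.full(50, 1e-4), "rad/Pa")
        t2 = SpectralDensity(f, np.full(50, 2e-4), "rad/Pa")
        np.testing.assert_allclose(nepd_spectrum(noise, t1).nepd,
                                   2 * nepd_spectrum(noise, t2).nepd)

    def test_identity_nepd_times_theta_is_noise(self, rng):
        f = np.linspace(3e6, 30e6, 64)
        noise = SpectralDensity(f, rng.uniform(1e-7, 3e-7, 64),
                                "rad·Hz^-1/2")
        theta = SpectralDensity(f, rng.uniform(5e-5, 2e-4, 64), "rad/Pa")
        nepd = nepd_spectrum(noise, theta)
        np.testing.assert_allclose(nepd.nepd * theta.values, noise.values,
                                   rtol=1e-9)


class TestRmsNep:
    def _flat(self, value=1.5e-3):
        f = np.linspace(1e6, 40e6, 400)
        return NepdSpectrum(f, np.full(400, value), (3e6, 30e6))

    def test_flat_density_worked_value(self):
        """Flat 1.5 mPa·Hz^-1/2 over 3-30 MHz integrates to 7.79 Pa,
        i.e. 8 Pa to the nearest pascal."""
        rms = rms_nep(self._flat())
        assert rms == pytest.approx(1.5e-3 * math.sqrt(27e6), rel=1e-6)
        assert rms == pytest.approx(7.79, abs=5e-3)
        assert round(rms) == 8

    def test_zero_density(self):
        assert rms_nep(NepdSpectrum(np.linspace(1e6, 40e6, 10),
                                    np.zeros(10), (3e6, 30e6))) == 0.0

    def test_half_band_scaling(self):
        full = rms_nep(self._flat(), band=(3e6, 30e6))
        half = rms_nep(self._flat(), band=(3e6, 16.5e6))
        assert half / full == pytest.approx(math.sqrt(13.5 / 27), rel=1e-9)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            rms_nep(self._flat(), band=(0.5e6, 30e6))


class TestResonatorNepd:
    def test_zero_intensity_noise_limit(self):
        """With Ni = 0 the formula reduces to Nq/(G·Sm)."""
        v = resonator_nepd(Ni=0.0, Nq=1.5e-7, Qc=100.0, G=1.93e7, Sm=1e-12)
        assert v == pytest.approx(1.5e-7 / (1.93e7 * 1e-12), rel=1e-12)
        assert v == pytest.approx(7.77e-3, rel=1e-3)

    def test_monotone_in_qc_and_gain(self):
        base = dict(Ni=1e-6, Nq=1.5e-7, Qc=50.0, G=1e7, Sm=1e-12)
        v0 = resonator_nepd(**base)
        assert resonator_nepd(**{**base, "Qc": 100.0}) < v0
        assert resonator_nepd(**{**base, "G": 2e7}) < v0

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            resonator_nepd(0.0, 1e-7, 0.0, 1e7, 1e-12)


class TestCalibrationLoop:
    def test_end_to_end_noise_density_recovery(self):
        """Full loop: NEPD × Theta reproduces the injected phase-noise
        density within 10% in band."""
        spec = SensorSpec()
        res = run_calibration(spec, rng_seed=5)
        nepd, theta = res["nepd"], res["theta"]
        thi = theta.interp_to(nepd.freqs)
        prod = nepd.nepd * thi
        sel = ((nepd.freqs >= 3e6) & (nepd.freqs <= 30e6)
               & np.isfinite(prod))
        assert np.mean(prod[sel]) == pytest.approx(spec.Nq_density, rel=0.10)

    def test_report_scalars_present(self):
        res = run_calibration(SensorSpec(), rng_seed=1)
        assert res["rms_nep_pa"] > 0
        assert res["nepd_inband_mpa"] > 0
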