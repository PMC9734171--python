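"""Image formation: demux, features, unmixing, map assembly, resolution."""

import math

import numpy as np
import pytest

from paesim import (ALineFeatures, OpticalModel, ScanGeometry, TimeTrace,
                    assemble_maps, demux_wavelengths, edge_resolution,
                    extract_features, forward_aline, make_blade_edge,
                    make_vessel_phantom, measure_edge_resolution,
                    rasterize_footprint, simulate_scan, so2_unmix)
from paesim.constants import C_SOUND

FS = 125e6


def _pulse_trace(amp=1.0, t0=1e-6, delay=1.5e-6, amp2=None):
    """Dual-window record with one bipolar pulse per wavelength window."""
    n = 2 * int(round(delay * FS))
    t = np.arange(n) / FS
    tau = 30e-9 / 2.355
    def pulse(tc, a):
        g = -(t - tc) * np.exp(-((t - tc) ** 2) / (2 * tau ** 2))
        return a * g / np.abs(g).max()
    x = pulse(t0, amp) + pulse(t0 + delay, amp2 if amp2 is not None else amp)
    return TimeTrace(x, FS, "Pa")


class TestDemux:
    def test_zero_trace_gives_zero_pair(self):
        tr = TimeTrace(np.zeros(400), FS, "Pa")
        a, b = demux_wavelengths(tr, 200 / FS)
        assert np.all(a.samples == 0) and np.all(b.samples == 0)
        assert len(a) == len(b) == 200

    def test_each_pulse_in_own_subtrace(self):
        tr = _pulse_trace(amp=2.0, amp2=3.0)
        a, b = demux_wavelengths(tr, 1.5e-6)
        assert np.abs(a.samples).max() == pytest.approx(2.0, rel=1e-6)
        assert np.abs(b.samples).max() == pytest.approx(3.0, rel=1e-6)

    def test_demux_concat_identity(self):
        tr = _pulse_trace()
        a, b = demux_wavelengths(tr, 1.5e-6)
        np.testing.assert_array_equal(
            np.concatenate([a.samples, b.samples]), tr.samples)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            demux_wavelengths(TimeTrace(np.zeros(100), FS, "Pa"), 100 / FS)


class TestExtractFeatures:
    def test_symmetric_pulse_pp_is_2a(self):
        pair = demux_wavelengths(_pulse_trace(amp=1.7), 1.5e-6)
        ft = extract_features(pair)
        assert ft.amp_pp[0] == pytest.approx(2 * 1.7, rel=0.02)

    def test_depth_from_arrival_time(self):
        t0 = 0.8e-6
        pair = demux_wavelengths(_pulse_trace(t0=t0), 1.5e-6)
        ft = extract_features(pair)
        assert ft.depth == pytest.approx(t0 * C_SOUND, abs=2 * C_SOUND / FS)

    def test_noise_only_line_masked(self, rng):
        sigma = 5.0
        n = 2 * int(round(1.5e-6 * FS))
        tr = TimeTrace(rng.normal(0, sigma, n), FS, "Pa")
        pair = demux_wavelengths(tr, 1.5e-6)
        ft = extract_features(pair, noise_rms=sigma, k_threshold=3.0)
        assert not ft.detected

    def test_strong_pulse_detected_over_noise(self, rng):
        sigma = 5.0
        tr = _pulse_trace(amp=100.0)
        tr = tr.with_samples(tr.samples + rng.normal(0, sigma, len(tr)))
        pair = demux_wavelengths(tr, 1.5e-6)
        ft = extract_features(pair, noise_rms=sigma, k_threshold=3.0)
        assert ft.detected


class TestSo2Unmix:
    def test_pure_oxyhemoglobin(self, optical):
        s, _ = so2_unmix(optical.eps_hbo2[0], optical.eps_hbo2[1], optical)
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_pure_deoxyhemoglobin(self, optical):
        s, _ = so2_unmix(optical.eps_hb[0], optical.eps_hb[1], optical)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_equal_mixture(self, optical):
        a532 = 0.5 * optical.eps_hbo2[0] + 0.5 * optical.eps_hb[0]
        a558 = 0.5 * optical.eps_hbo2[1] + 0.5 * optical.eps_hb[1]
        s, c = so2_unmix(a532, a558, optical)
        assert s == pytest.approx(0.5, abs=1e-6)
        assert c == pytest.approx(1.0, rel=1e-6)

    def test_zero_amplitudes_masked(self, optical):
        s, c = so2_unmix(0.0, 0.0, optical)
        assert math.isnan(s) and c == 0.0

    def test_singular_extinction_rejected(self, optical):
        bad = OpticalModel(**{**optical.__dict__,
                              "eps_hbo2": (1e4, 1e4), "eps_hb": (1e4, 1e4)})
        with pytest.raises(ValueError):
            so2_unmix(1.0, 1.0, bad)

    def test_energy_ratio_normalization(self, optical):
        double = OpticalModel(**{**optical.__dict__, "energy_ratio": 2.0})
        s_ref, _ = so2_unmix(optical.eps_hbo2[0], optical.eps_hbo2[1],
                             optical)
        s, _ = so2_unmix(optical.eps_hbo2[0], 2 * optical.eps_hbo2[1],
                         double)
        assert s == pytest.approx(s_ref, abs=1e-9)


class TestScanGeometry:
    def test_rotational_lateral_step_5um(self):
        """2.75 mm working distance and 0.1 deg step → ~5 um arc pitch."""
        g = ScanGeometry(mode="rotational", working_distance=2.75e-3,
                         angle_step=0.1)
        assert g.lateral_step * 1e6 == pytest.approx(4.80, abs=0.01)
        assert round(g.lateral_step * 1e6) == 5

    def test_pullback_pitch(self):
        g = ScanGeometry(mode="rotational", pullback_speed=10e-6,
                         bscan_rate=1.0)
        assert g.pullback_pitch == pytest.approx(10e-6)

    def test_raster_pixel_pitch(self):
        g = ScanGeometry(mode="raster", raster_range=(6e-3, 6e-3),
                         raster_pixels=(1500, 1500))
        assert g.lateral_step == pytest.approx(4e-6)

    def test_full_turn_guard(self):
        with pytest.raises(ValueError):
            ScanGeometry(mode="rotational", angle_step=0.2,
                         alines_per_bscan=2000)

    def test_rotational_poses_shape(self):
        g = ScanGeometry(mode="rotational", alines_per_bscan=100)
        poses = g.poses(n_rows=5)
        assert poses.shape == (5, 100, 2)
        dx = np.diff(poses[0, :, 0])
        np.testing.assert_allclose(dx, g.lateral_step, rtol=1e-9)


class TestAssembleMaps:
    def _features(self, n, optical, detected=True):
        a532 = optical.eps_hbo2[0]
        a558 = optical.eps_hbo2[1]
        return [ALineFeatures((a532, a558), (1e-6, 1e-6), depth=1.5e-3,
                              detected=detected,
                              amp_rms=(a532, a558)) for _ in range(n)]

    def test_row_major_grid_and_mask(self, optical):
        g = ScanGeometry(mode="raster", raster_range=(1e-3, 1e-3),
                         raster_pixels=(4, 3))
        fts = self._features(12, optical)
        fts[5] = ALineFeatures((0.0, 0.0), (0.0, 0.0), 0.0, detected=False)
        maps = assemble_maps(fts, g, optical)
        assert maps.chb_map.shape == (3, 4)
        assert not maps.mask[1, 1]  # index 5 → row 1, col 1
        assert np.isnan(maps.so2_map[1, 1])
        on = maps.so2_map[maps.mask]
        np.testing.assert_allclose(on, 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self, optical):
        g = ScanGeometry(mode="raster", raster_pixels=(4, 3))
        with pytest.raises(ValueError):
            assemble_maps(self._features(7, optical), g, optical)


class TestEdgeResolution:
    def test_recovers_beam_fwhm_at_focus(self, optical):
        ph = make_blade_edge(depth=optical.focus_depth)
        fwhm = measure_edge_resolution(ph, optical)
        assert fwhm == pytest.approx(optical.beam_waist_fwhm, rel=0.05)

    def test_recovers_defocused_width(self, optical):
        """At ±300 um defocus the recovered FWHM matches the configured
        beam growth (~20 um)."""
        ph = make_blade_edge(depth=optical.focus_depth)
        for off in (300e-6, -300e-6):
            expect = optical.beam_fwhm(optical.focus_depth + abs(off))
            fwhm = measure_edge_resolution(ph, optical, depth_offset=off,
                                           scan_halfwidth=120e-6)
            assert fwhm == pytest.approx(expect, rel=0.05)

    def test_sampling_floor_for_sharp_step(self):
        """An ideal step with a delta-like LSF reports the scan-step
        sampling floor rather than zero."""
        x = np.arange(-20e-6, 20e-6, 1e-6)
        a = (x >= 0).astype(float)
        fwhm = edge_resolution(x, a)
        assert 0 < fwhm < 3e-6

    def test_flat_profile_rejected(self):
        x = np.linspace(0, 1e-4, 50)
        with pytest.raises(ValueError):
            edge_resolution(x, np.ones(50))


class TestScanConvert:
    def test_rotational_bscan_lands_on_arc(self):
        from paesim.imaging import scan_convert
        g = ScanGeometry(mode="rotational", alines_per_bscan=900,
                         angle_step=0.1)
        img = scan_convert(np.ones(900), g, grid_n=128)
        assert np.isfinite(img).sum() > 100       # an arc, not everything
        assert np.isfinite(img).sum() < 128 * 128 // 4

    def test_raster_rejected(self):
        from paesim.imaging import scan_convert
        with pytest.raises(ValueError):
            scan_convert(np.ones(10), ScanGeometry(mode="raster"))


class TestScanPipeline:
    def test_map_congruence_and_so2_range(self, optical, small_raster):
        ph = make_vessel_phantom(3)
        maps = simulate_scan(ph, small_raster, optical, rng_seed=1)
        assert maps.chb_map.shape == maps.so2_map.shape == maps.mask.shape
        on = maps.so2_map[maps.mask]
        assert np.all((on >= 0) & (on <= 1))
        assert np.isnan(maps.so2_map[~maps.mask]).all()

    def test_depth_map_matches_vessel_depth(self, optical, small_raster):
        ph = make_vessel_phantom(3)
        maps = simulate_scan(ph, small_raster, optical, rng_seed=1)
        x, y = small_raster.grid_axes()
        seg = ph.segments[0]
        cx, cy, cz = seg.centerline[4]
        i, j = np.argmin(abs(y - cy)), np.argmin(abs(x - cx))
        if maps.mask[i, j]:
            assert maps.depth_map[i, j] == pytest.approx(cz, abs=30e-6)

    def test_through_sensor_scan_matches_direct(self, optical):
        """Routing A-lines through the full detection chain preserves the
        functional maps of a small scan."""
        from paesim import DemodConfig, SensorSpec
        ph = make_vessel_phantom(3, branches_per_trunk=0,
                                 capillaries_per_trunk=0)
        g = ScanGeometry(mode="raster", raster_range=(0.4e-3, 0.4e-3),
                         raster_pixels=(8, 8))
        direct = simulate_scan(ph, g, optical, rng_seed=1)
        chain = simulate_scan(ph, g, optical, rng_seed=1,
                              sensor_spec=SensorSpec().quiet(),
                              demod_cfg=DemodConfig.for_carrier(50e6))
        both = direct.mask & chain.mask
        assert both.sum() >= 4
        np.testing.assert_allclose(chain.so2_map[both],
                                   direct.so2_map[both], atol=0.02)
        np.testing.assert_allclose(chain.depth_map[both],
                                   direct.depth_map[both], atol=25e-6)

    def test_noiseless_so2_matches_truth_on_trunk(self, optical,
                                                  small_raster):
        ph = make_vessel_phantom(3, branches_per_trunk=0,
                                 capillaries_per_trunk=0)
        maps = simulate_scan(ph, small_raster, optical, rng_seed=1)
        x, y = small_raster.grid_axes()
        seg = ph.segments[0]
        cx, cy, _ = seg.centerline[4]
        i, j = np.argmin(abs(y - cy)), np.argmin(abs(x - cx))
        assert maps.mask[i, j]
        assert maps.so2_map[i, j] == pytest.approx(seg.sO2, abs=0.02)
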