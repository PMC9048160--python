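"""Acoustic forward model: delays, linearity, transducer band-pass, decimation."""

import numpy as np
import pytest
from scipy.signal import hilbert

from panev.core import ConfigError, RFFrame
from panev.forward import (AcousticConfig, apply_transducer_response,
                           downsample_rf, forward_project, simulate_sensor_rf,
                           transducer_sigma_mhz)
from .conftest import point_source


class TestForwardProject:
    def test_zero_map_gives_zero_rf(self, grid, probe, acfg):
        rf = forward_project(np.zeros((grid.nz, grid.nx)), grid, probe, acfg)
        assert not rf.samples.any()
        assert rf.fs_mhz == 120.0
        assert rf.n_samples == 3072

    def test_on_channel_delay_matches_time_of_flight(self, grid, probe, acfg):
        # unit source at the lateral position of channel 64, depth 10 mm:
        # one-way arrival at round(10 mm / 1540 m/s * 40 MHz) = sample 260
        assert round(10.0e-3 / probe.sound_speed * 40e6) == 260
        p0, (z, x) = point_source(grid, 10.0, probe.element_x_mm[64])
        rf = simulate_sensor_rf(p0, grid, probe, acfg)
        env = np.abs(hilbert(rf.samples[:, 64]))
        # the nearest grid cell sits at z = 10.05 mm, hence sample 261
        expected = round(np.hypot(z, x - probe.element_x_mm[64])
                         * 1e-3 / probe.sound_speed * 40e6)
        assert abs(int(np.argmax(env)) - expected) <= 2

    def test_per_element_delay_profile(self, grid, probe, acfg):
        p0, (z, x) = point_source(grid, 15.0, 0.0)
        rf = forward_project(p0, grid, probe, acfg)
        for ch in (0, 32, 96, 127):
            col = rf.samples[:, ch]
            first = np.flatnonzero(col)[0]
            r = np.hypot(z, x - probe.element_x_mm[ch])
            expected = r * 1e-3 / probe.sound_speed * 120e6
            assert first == int(np.floor(expected))

    def test_causality_no_energy_before_first_arrival(self, grid, probe, acfg):
        p0, (z, x) = point_source(grid, 10.0, 0.0)
        rf = forward_project(p0, grid, probe, acfg)
        earliest = int(z * 1e-3 / probe.sound_speed * 120e6)  # on-axis element
        assert not rf.samples[:earliest].any()

    def test_linearity(self, grid, probe, acfg, rng):
        def sparse_map():
            p0 = np.zeros((grid.nz, grid.nx))
            iz = rng.integers(50, 350, 20)
            ix = rng.integers(50, 350, 20)
            p0[iz, ix] = rng.uniform(0.1, 1.0, 20)
            return p0

        a, b = sparse_map(), sparse_map()
        fa = forward_project(a, grid, probe, acfg).samples
        fb = forward_project(b, grid, probe, acfg).samples
        fab = forward_project(a + b, grid, probe, acfg).samples
        assert np.allclose(fab, fa + fb, rtol=1e-9, atol=1e-12)

    def test_amplitude_decays_as_one_over_r(self, grid, probe, acfg):
        rf5 = forward_project(point_source(grid, 5.0, 0.0)[0], grid, probe, acfg)
        rf20 = forward_project(point_source(grid, 20.0, 0.0)[0], grid, probe, acfg)
        on_axis = np.argmin(np.abs(probe.element_x_mm))
        ratio = (np.abs(rf5.samples[:, on_axis]).sum()
                 / np.abs(rf20.samples[:, on_axis]).sum())
        assert ratio == pytest.approx(4.0, rel=0.01)


class TestTransducerResponse:
    def _gain_curve(self, probe, rng):
        frame = RFFrame(samples=rng.standard_normal((3072, 128)), fs_mhz=120.0,
                        probe=probe)
        out = apply_transducer_response(frame, probe)
        freqs = np.fft.rfftfreq(3072, d=1 / 120.0)
        fin = np.fft.rfft(frame.samples[:, 0])
        fout = np.fft.rfft(out.samples[:, 0])
        return freqs, np.abs(fout) / np.abs(fin)

    def test_centre_frequency_peak_gain(self, probe, rng):
        freqs, gain = self._gain_curve(probe, rng)
        g7 = np.interp(7.0, freqs, gain)
        assert g7 == pytest.approx(1.0, abs=1e-4)
        assert np.max(gain) <= 1.0 + 1e-9
        assert abs(freqs[np.argmax(gain)] - 7.0) <= freqs[1] - freqs[0]

    def test_minus6db_band_edges(self, probe, rng):
        # -6 dB half-width is frac_bw * f0 / 2 = 0.809 * 7 / 2 = 2.832 MHz
        freqs, gain = self._gain_curve(probe, rng)
        for f in (7.0 - 2.8315, 7.0 + 2.8315):
            assert np.interp(f, freqs, gain) == pytest.approx(0.5, abs=0.01)

    def test_dc_suppressed_below_minus30db(self, probe, rng):
        freqs, gain = self._gain_curve(probe, rng)
        assert gain[0] < 10 ** (-30 / 20)
        sigma = transducer_sigma_mhz(probe)
        assert gain[0] == pytest.approx(np.exp(-7.0 ** 2 / (2 * sigma ** 2)),
                                        rel=1e-6)

    def test_undersampled_passband_rejected(self, probe):
        frame = RFFrame(samples=np.zeros((256, 128)), fs_mhz=20.0, probe=probe)
        with pytest.raises(ConfigError):
            apply_transducer_response(frame, probe)


class TestDownsample:
    def test_shapes_and_rates(self, probe):
        frame = RFFrame(samples=np.zeros((3072, 128)), fs_mhz=120.0, probe=probe)
        out = downsample_rf(frame, 3)
        assert out.samples.shape == (1024, 128)
        assert out.fs_mhz == 40.0
        assert not out.samples.any()

    def test_in_band_tone_preserved(self, probe):
        t = np.arange(3072) / 120.0
        tone = np.sin(2 * np.pi * 5.0 * t)  # 5 MHz: bin-aligned, well in band
        frame = RFFrame(samples=np.tile(tone[:, None], (1, 128)), fs_mhz=120.0,
                        probe=probe)
        out = downsample_rf(frame, 3)
        rms_in = np.sqrt(np.mean(tone[200:-200] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[70:-70, 0] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.01)

    def test_non_divisor_factor_rejected(self, probe):
        frame = RFFrame(samples=np.zeros((3072, 128)), fs_mhz=120.0, probe=probe)
        with pytest.raises(ConfigError):
            downsample_rf(frame, 5)


def test_internal_rate_must_be_integer_multiple():
    with pytest.raises(ConfigError):
        AcousticConfig(internal_fs_mhz=100.0, output_fs_mhz=40.0)
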