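"""Array geometry and forward-simulation contracts."""

import numpy as np
import pytest

from needletrack.acoustics import (
    ChannelData,
    add_noise,
    aline_envelope,
    measure_snr,
    simulate_channel_data,
)
from needletrack.geometry import ArrayGeometry, PointSource, Pulse, element_positions


class TestElementPositions:
    def test_printed_geometry(self, geom):
        pos = element_positions(geom)
        assert geom.element_pitch_mm == pytest.approx(0.3)
        assert pos[0] == pytest.approx(-19.05)
        assert pos[-1] == pytest.approx(19.05)
        assert len(pos) == 128

    def test_two_element_symmetry(self):
        pos = element_positions(ArrayGeometry(n_elements=2, aperture_mm=2.0))
        assert pos == pytest.approx([-0.5, 0.5])

    @pytest.mark.parametrize("n,ap", [(3, 1.0), (7, 10.0), (128, 38.4)])
    def test_centred_and_increasing(self, n, ap):
        pos = element_positions(ArrayGeometry(n_elements=n, aperture_mm=ap))
        assert abs(pos.mean()) < 1e-9
        assert np.all(np.diff(pos) > 0)


class TestGeometryInvariants:
    def test_pitch_times_count_is_aperture(self, geom):
        assert geom.element_pitch_mm * geom.n_elements == pytest.approx(geom.aperture_mm)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ArrayGeometry(n_elements=1)
        with pytest.raises(ValueError):
            ArrayGeometry(element_width_mm=0.5)  # wider than the 0.3 mm pitch
        with pytest.raises(ValueError):
            PointSource(0.0, -1.0)
        with pytest.raises(ValueError):
            Pulse(fractional_bandwidth=2.5)


class TestSimulation:
    def test_on_axis_arrival_time(self, geom, pulse):
        cd = simulate_channel_data(PointSource(0.0, 30.0), geom, pulse)
        env = aline_envelope(cd)
        pos = element_positions(geom)
        centre = np.argmin(np.abs(pos))
        t_peak = np.argmax(env[:, centre]) / geom.sampling_freq_hz
        # 30 mm / 1500 m/s = 20 us; centre element is pitch/2 off axis
        expected = np.hypot(30.0, pos[centre]) * 1e-3 / geom.sound_speed_m_s
        assert t_peak == pytest.approx(expected, abs=0.5 / geom.sampling_freq_hz)
        assert expected == pytest.approx(20.0e-6, rel=1e-4)

    def test_arrival_time_law_all_elements(self, geom, pulse):
        src = PointSource(5.0, 28.0)
        cd = simulate_channel_data(src, geom, pulse)
        env = aline_envelope(cd)
        pos = element_positions(geom)
        r = np.hypot(pos - src.x_mm, src.z_mm)
        t_expected = r * 1e-3 / geom.sound_speed_m_s
        t_peak = np.argmax(env, axis=0) / geom.sampling_freq_hz
        assert np.all(np.abs(t_peak - t_expected) <= 0.5 / geom.sampling_freq_hz)

    def test_edge_element_time_of_flight(self, geom, pulse):
        cd = simulate_channel_data(PointSource(0.0, 30.0), geom, pulse)
        env = aline_envelope(cd)
        t_peak = np.argmax(env[:, -1]) / geom.sampling_freq_hz
        expected = np.hypot(30.0, 19.05) * 1e-3 / 1500.0  # 23.69 us
        assert expected == pytest.approx(23.69e-6, abs=5e-9)
        assert t_peak == pytest.approx(expected, abs=0.5 / geom.sampling_freq_hz)

    def test_spherical_spreading_ratio(self, geom, pulse):
        env1 = aline_envelope(simulate_channel_data(PointSource(0.0, 15.0), geom, pulse,
                                                    duration_s=40e-6))
        env2 = aline_envelope(simulate_channel_data(PointSource(0.0, 30.0), geom, pulse,
                                                    duration_s=40e-6))
        pos = element_positions(geom)
        centre = np.argmin(np.abs(pos))
        assert env1[:, centre].max() / env2[:, centre].max() == pytest.approx(2.0, rel=0.01)

    def test_amplitude_nonincreasing_with_distance(self, channel_data, source, geom):
        env = aline_envelope(channel_data)
        peaks = env.max(axis=0)
        r = np.hypot(element_positions(geom) - source.x_mm, source.z_mm)
        order = np.argsort(r)
        assert np.all(np.diff(peaks[order]) <= 1e-12)

    def test_mirror_symmetry(self, geom, pulse):
        cd_l = simulate_channel_data(PointSource(-4.5, 25.0), geom, pulse, duration_s=40e-6)
        cd_r = simulate_channel_data(PointSource(4.5, 25.0), geom, pulse, duration_s=40e-6)
        np.testing.assert_allclose(cd_l.samples, cd_r.samples[:, ::-1], atol=1e-12)

    def test_duration_too_short_raises(self, geom, pulse):
        with pytest.raises(ValueError, match="too short"):
            simulate_channel_data(PointSource(0.0, 30.0), geom, pulse, duration_s=10e-6)


class TestNoise:
    def test_seeded_noise_reproducible(self, channel_data):
        a = add_noise(channel_data, 20.0, seed=42)
        b = add_noise(channel_data, 20.0, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, add_noise(channel_data, 20.0, seed=43).samples)

    def test_no_noise_path_is_identity(self, channel_data):
        # infinite SNR is disallowed; omitting add_noise keeps the data intact
        with pytest.raises(ValueError):
            add_noise(channel_data, np.inf, seed=0)

    def test_all_zero_input_rejected(self, geom):
        cd = ChannelData(np.zeros((64, 128)), geom.sampling_freq_hz, 0.0, geom)
        with pytest.raises(ValueError):
            add_noise(cd, 20.0, seed=0)

    def test_requested_snr_recovered(self, channel_data, geom):
        """Monte-Carlo: measured SNR within 5% of the requested 20.

        The signal window is the known noise-free peak cell (a wide
        window would bias the peak estimate upward: it takes a maximum
        over many noise-perturbed near-peak samples).
        """
        flat = int(np.argmax(np.abs(channel_data.samples)))
        i_peak, e_peak = np.unravel_index(flat, channel_data.samples.shape)
        sig = ((i_peak, i_peak + 1), (e_peak, e_peak + 1))
        noi = (0, channel_data.n_samples // 4)
        vals = [
            measure_snr(add_noise(channel_data, 20.0, seed=s), sig, noi)
            for s in range(100)
        ]
        assert np.mean(vals) == pytest.approx(20.0, rel=0.05)


class TestMeasureSnr:
    def _noise_cd(self, geom):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1.0, size=(1000, geom.n_elements))
        s[800, 0] = 10.0
        return ChannelData(s, geom.sampling_freq_hz, 0.0, geom)

    def test_definition(self, geom):
        cd = self._noise_cd(geom)
        snr = measure_snr(cd, (700, 1000), (0, 600))
        assert snr == pytest.approx(10.0, rel=0.05)

    def test_scale_invariance(self, geom):
        cd = self._noise_cd(geom)
        cd2 = ChannelData(2 * cd.samples, cd.sampling_freq_hz, 0.0, geom)
        assert measure_snr(cd, (700, 1000), (0, 600)) == pytest.approx(
            measure_snr(cd2, (700, 1000), (0, 600))
        )

    def test_overlapping_windows_rejected(self, geom):
        cd = self._noise_cd(geom)
        with pytest.raises(ValueError):
            measure_snr(cd, (0, 500), (400, 900))

    def test_zero_noise_rejected(self, geom):
        cd = ChannelData(np.ones((100, geom.n_elements)), geom.sampling_freq_hz, 0.0, geom)
        with pytest.raises(ValueError):
            measure_snr(cd, (50, 100), (0, 50))
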