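"""Waveform construction, windowing, power accounting and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stochdec as sd
from stochdec.waveforms import coupled_proton_filter


def spectral_power(wf):
    """Frequency-domain mean power via the DFT (Parseval check)."""
    spec = np.fft.fft(wf.complex_samples)
    return np.sum(np.abs(spec) ** 2) / wf.n_samples**2


class TestCW:
    def test_definition(self):
        wf = sd.make_cw(100.0, 0.2048, 1e-4)
        assert wf.n_samples == 2048
        assert np.all(wf.amplitude == 100.0)
        assert np.all(wf.phase_deg == 0.0)
        assert wf.duration == pytest.approx(0.2048)

    def test_power(self):
        assert sd.make_cw(0.0, 0.1, 1e-4).power == 0.0
        assert sd.make_cw(100.0, 0.1, 1e-4).power == pytest.approx(1e4)

    @pytest.mark.parametrize("kwargs,name", [
        (dict(gamma_b2=100, duration=-1, dwell=1e-4), "duration"),
        (dict(gamma_b2=100, duration=0.1, dwell=0), "dwell"),
        (dict(gamma_b2=-5, duration=0.1, dwell=1e-4), "gamma_b2"),
        (dict(gamma_b2=100, duration=1.05e-4, dwell=1e-4), "dwell"),
    ])
    def test_rejects_bad_parameters_naming_them(self, kwargs, name):
        with pytest.raises(ValueError, match=name):
            sd.make_cw(**kwargs)


class TestWaltz:
    def test_s_block_inverts_longitudinal_magnetization(self):
        """90x 180-x 270x composes to a net 180x rotation (2x2 oracle)."""
        # independent oracle: compose the three proton rotation operators
        sx = np.array([[0, 1], [1, 0]], dtype=complex) / 2
        sz = np.array([[1, 0], [0, -1]], dtype=complex) / 2

        def rot(theta, sign):
            from scipy.linalg import expm
            return expm(-1j * theta * sign * sx)

        u = rot(3 * np.pi / 2, +1) @ rot(np.pi, -1) @ rot(np.pi / 2, +1)
        mz_expected = np.trace(u @ sz @ u.conj().T @ sz).real / np.trace(sz @ sz).real
        assert mz_expected == pytest.approx(-1.0, abs=1e-12)

        from stochdec.spinsim import HZ, DensityState, propagate
        wf = sd.make_waltz_s_block(100.0)
        out = propagate(sd.SpinSystem(j_hz=0.0), DensityState.from_operator(HZ),
                        wf, wf.duration)
        assert out.coefficient(HZ).real == pytest.approx(mz_expected, abs=1e-10)

    def test_durations(self):
        # a 540-degree composite block at 100 Hz lasts 540/360/100 = 15 ms
        assert sd.make_waltz_s_block(100.0).duration == pytest.approx(0.015)
        w4 = sd.make_waltz(4, 100.0)
        w16 = sd.make_waltz(16, 100.0)
        assert w4.duration == pytest.approx(0.060)
        assert w16.duration == pytest.approx(4 * w4.duration)

    def test_waltz4_phase_structure(self):
        # Sx Sx S-x S-x: second half is the phase-inverted first half
        w4 = sd.make_waltz(4, 100.0)
        half = w4.n_samples // 2
        assert np.allclose((w4.phase_deg[:half] + 180.0) % 360.0, w4.phase_deg[half:])

    def test_unsupported_variant(self):
        with pytest.raises(ValueError, match="variant"):
            sd.make_waltz(8, 100.0)


class TestStochastic:
    def test_pseudo_constant_amplitude_and_power(self):
        wf = sd.make_pseudo_stochastic(100.0, 512, 1e-3, seed=0)
        assert np.all(wf.amplitude == 100.0)
        assert wf.power == pytest.approx(1e4)
        assert set(np.unique(wf.phase_deg)) <= {0.0, 180.0}

    def test_pseudo_seed_determinism(self):
        a = sd.make_pseudo_stochastic(100.0, 256, 1e-3, seed=42)
        b = sd.make_pseudo_stochastic(100.0, 256, 1e-3, seed=42)
        assert np.array_equal(a.phase_deg, b.phase_deg)

    def test_pseudo_phase_fraction_binomial(self):
        # n = 4096 fair coin: fraction of 180s within 4 sigma of 0.5
        n = 4096
        wf = sd.make_pseudo_stochastic(100.0, n, 1e-3, seed=7)
        frac = np.mean(wf.phase_deg == 180.0)
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_vectorial_support_and_power(self):
        peak = 200.0
        wf = sd.make_vectorial_noise(peak, 20000, 1e-3, seed=3)
        assert wf.peak <= peak
        assert np.all(wf.amplitude >= 0)
        # E[A^2] = peak^2/3 for uniform amplitudes
        assert wf.power == pytest.approx(peak**2 / 3, rel=0.05)

    def test_vectorial_seed_determinism(self):
        a = sd.make_vectorial_noise(100.0, 128, 1e-3, seed=5)
        b = sd.make_vectorial_noise(100.0, 128, 1e-3, seed=5)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.phase_deg, b.phase_deg)

    def test_default_sub_duration_spans_coupled_band(self):
        # repetition rate = 5.89 ppm at the stated field
        assert 1.0 / sd.default_sub_duration(500.0) == pytest.approx(5.89 * 500.0)


class TestWindowing:
    def test_all_pass_identity(self):
        wf = sd.make_pseudo_stochastic(100.0, 256, 1e-3, seed=1)
        fs = 1.0 / wf.dwell
        full = sd.BandFilter(
            [(wf.carrier_ppm - 0.49 * fs / 500.0, wf.carrier_ppm + 0.49 * fs / 500.0)],
            margin_ppm=0.02 * fs / 500.0, f0_mhz=500.0,
        )
        out = sd.window_waveform(wf, full)
        assert np.allclose(out.complex_samples, wf.complex_samples,
                           rtol=0, atol=1e-9 * wf.peak)

    def test_power_equals_in_band_fraction(self):
        wf = sd.make_pseudo_stochastic(100.0, 1024, sd.default_sub_duration(500.0), seed=2)
        filt = coupled_proton_filter(500.0)
        out = sd.window_waveform(wf, filt)
        freqs = np.fft.fftfreq(wf.n_samples, wf.dwell)
        mask = np.zeros(wf.n_samples, bool)
        for lo, hi in filt.bands_hz(wf.carrier_ppm):
            mask |= (freqs >= lo) & (freqs <= hi)
        spec = np.fft.fft(wf.complex_samples)
        in_band = np.sum(np.abs(spec[mask]) ** 2) / wf.n_samples**2
        assert out.power == pytest.approx(in_band, rel=1e-12)

    def test_pure_sinusoid_in_and_out_of_band(self):
        # deterministic oracle: a tone inside the band passes, outside is removed
        n, dwell, f0 = 256, 1e-3, 500.0
        t = np.arange(n) * dwell
        tone_hz = 100.0  # bin-aligned: 100 = 25.6 bins? 100*0.256 = 25.6 -> use bin-aligned
        tone_hz = 25 / (n * dwell)
        z = 50.0 * np.exp(2j * np.pi * tone_hz * t)
        wf = sd.RFWaveform(np.abs(z), np.rad2deg(np.angle(z)), dwell, carrier_ppm=4.755)
        band_in = sd.BandFilter([(4.755 + (tone_hz - 30) / f0, 4.755 + (tone_hz + 30) / f0)],
                                margin_ppm=0.0, f0_mhz=f0)
        band_out = sd.BandFilter([(4.755 + (tone_hz + 60) / f0, 4.755 + (tone_hz + 120) / f0)],
                                 margin_ppm=0.0, f0_mhz=f0)
        assert sd.window_waveform(wf, band_in).power == pytest.approx(wf.power, rel=1e-9)
        assert sd.window_waveform(wf, band_out).power == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        wf = sd.make_vectorial_noise(100.0, 512, 1e-3, seed=9)
        filt = sd.BandFilter([(4.0, 5.5)], 0.1, 500.0)
        once = sd.window_waveform(wf, filt)
        twice = sd.window_waveform(once, filt)
        assert np.allclose(twice.complex_samples, once.complex_samples,
                           rtol=0, atol=1e-9 * max(once.peak, 1e-30))

    def test_band_outside_representable_rejected(self):
        wf = sd.make_pseudo_stochastic(100.0, 64, 1e-3, seed=0)  # +/-500 Hz
        filt = sd.BandFilter([(4.755 + 600 / 500.0, 4.755 + 900 / 500.0)],
                             margin_ppm=0.0, f0_mhz=500.0)
        with pytest.raises(ValueError, match="outside"):
            sd.window_waveform(wf, filt)

    def test_band_filter_validation(self):
        with pytest.raises(ValueError, match="low_ppm < high_ppm"):
            sd.BandFilter([(3.9, 1.91)], 0.1, 500.0)
        with pytest.raises(ValueError, match="overlap"):
            sd.BandFilter([(1.0, 2.0), (2.05, 3.0)], 0.1, 500.0)


class TestPowerAccounting:
    def test_cw_power_and_energy(self):
        wf = sd.make_cw(100.0, 0.2, 1e-4)
        p = sd.waveform_power(wf)
        assert p.mean_power == pytest.approx(1e4)
        assert p.total_energy == pytest.approx(1e4 * 0.2)
        assert p.peak_amplitude == pytest.approx(100.0)

    def test_windowing_never_increases_power(self):
        wf = sd.make_pseudo_stochastic(100.0, 512, 1e-3, seed=4)
        out = sd.window_waveform(wf, sd.BandFilter([(4.0, 5.0)], 0.1, 500.0))
        assert out.power <= wf.power

    def test_parseval_time_vs_frequency(self):
        wf = sd.make_vectorial_noise(150.0, 300, 2e-4, seed=8)
        assert spectral_power(wf) == pytest.approx(wf.power, rel=1e-9)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000), st.integers(8, 300))
def test_generated_waveform_invariants(seed, n_sub):
    """Phases normalized, Parseval equality, windowed power a fraction."""
    wf = sd.make_vectorial_noise(120.0, n_sub, 5e-4, seed=seed)
    assert np.all((wf.phase_deg >= 0) & (wf.phase_deg < 360))
    assert spectral_power(wf) == pytest.approx(wf.power, rel=1e-9)
    out = sd.window_waveform(wf, sd.BandFilter([(4.2, 5.3)], 0.1, 500.0))
    assert -1e-12 <= out.power <= wf.power * (1 + 1e-12)


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["shape", "delimited"])
    def test_round_trip(self, fmt, tmp_path):
        wf = sd.make_vectorial_noise(100.0, 64, 1e-3, seed=6)
        path = tmp_path / f"wf.{fmt}"
        sd.export_waveform(wf, path, fmt)
        back = sd.import_waveform(path)
        assert np.max(np.abs(back.amplitude - wf.amplitude)) < 1e-6 * wf.peak
        assert np.max(np.abs(back.phase_deg - wf.phase_deg)) < 1e-5
        assert back.dwell == pytest.approx(wf.dwell)

    def test_cw_shape_records_100_percent(self, tmp_path):
        path = tmp_path / "cw.shape"
        sd.export_waveform(sd.make_cw(100.0, 0.01, 1e-3), path, "shape")
        rows = [l for l in path.read_text().splitlines()
                if l and not l.startswith("##")]
        assert all(float(r.split(",")[0]) == pytest.approx(100.0) for r in rows)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        from stochdec.fileio import ParseError
        with pytest.raises(ParseError):
            sd.import_waveform(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# dwell_s: 1e-3\n100 0\nnonsense\n")
        from stochdec.fileio import ParseError
        with pytest.raises(ParseError, match=":3:"):
            sd.import_waveform(path, "delimited")
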