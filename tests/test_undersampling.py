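"""Sampling patterns, spectral support and iterative reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stochdec as sd
from stochdec.undersampling import SpectralSupport


class TestPattern:
    def test_zero_skip_is_all_true(self):
        assert np.all(sd.make_pattern(256, 0.0, 0.2, seed=0).mask)

    def test_exact_counts(self):
        pat = sd.make_pattern(1000, 0.30, core_fraction=0.2, seed=3)
        assert pat.n_sampled == 700
        assert np.all(pat.mask[:200])

    def test_different_seeds_differ_with_equal_counts(self):
        a = sd.make_pattern(1024, 0.3, 0.2, seed=1)
        b = sd.make_pattern(1024, 0.3, 0.2, seed=2)
        assert not np.array_equal(a.mask, b.mask)
        assert a.n_sampled == b.n_sampled

    def test_coherent_is_seed_independent(self):
        a = sd.make_pattern(1024, 0.3, 0.2, "coherent", seed=1)
        b = sd.make_pattern(1024, 0.3, 0.2, "coherent", seed=99)
        assert np.array_equal(a.mask, b.mask)

    def test_infeasible_skip_reports_feasible_maximum(self):
        with pytest.raises(ValueError, match="0.8"):
            sd.make_pattern(1000, 0.9, core_fraction=0.2, seed=0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(64, 2048), st.floats(0.0, 0.6), st.integers(0, 1000))
    def test_skip_fraction_within_one_over_n(self, n, rate, seed):
        pat = sd.make_pattern(n, rate, core_fraction=0.2, segment_len=8, seed=seed)
        assert abs(pat.skip_fraction - rate) <= 1.0 / n
        assert np.all(pat.mask[: int(np.ceil(0.2 * n))])


class TestUndersample:
    def test_identity_for_all_true(self, clean_fid_factory):
        fid = clean_fid_factory(0)
        pat = sd.make_pattern(fid.acq.n_points, 0.0, 0.2, seed=0)
        assert np.array_equal(sd.undersample(fid, pat).data, fid.data)

    def test_energy_never_increases(self, clean_fid_factory):
        fid = clean_fid_factory(1)
        pat = sd.make_pattern(fid.acq.n_points, 0.4, 0.2, seed=5)
        assert sd.undersample(fid, pat).energy <= fid.energy

    def test_unsampled_points_zeroed(self, clean_fid_factory):
        fid = clean_fid_factory(2)
        pat = sd.make_pattern(fid.acq.n_points, 0.3, 0.2, seed=6)
        out = sd.undersample(fid, pat)
        assert np.all(out.data[~pat.mask] == 0)
        assert np.array_equal(out.data[pat.mask], fid.data[pat.mask])

    def test_length_mismatch_rejected(self, clean_fid_factory):
        fid = clean_fid_factory(3)
        pat = sd.make_pattern(512, 0.3, 0.2, seed=0)
        with pytest.raises(ValueError, match="length"):
            sd.undersample(fid, pat)


class TestSupport:
    def test_flat_zero_reference_rejected(self, acq):
        zero = sd.SpectrumData(np.zeros(acq.n_points), acq)
        with pytest.raises(ValueError, match="zero"):
            sd.build_support(zero)

    def test_single_lorentzian_contiguous_window(self, acq):
        spec = sd.synth_fid([sd.PeakModel(178.0, 1.0, 3.0)], acq).to_spectrum()
        sup = sd.build_support(spec, threshold_fraction=0.01, guard_hz=6.0)
        idx = sup.p_indices
        assert np.all(np.diff(idx) == 1)  # one contiguous run
        assert acq.ppm_to_bin(178.0) in idx

    def test_peak_list_mode_windows(self, model_spectrum, peaks):
        sup = sd.build_support(model_spectrum, peaks=peaks, guard_linewidths=2)
        ppm = model_spectrum.acq.ppm_axis()
        for p in peaks:
            assert np.any(np.abs(ppm[sup.p_indices] - p.shift_ppm)
                          <= 2 * p.linewidth_hz / model_spectrum.acq.f0_mhz)

    def test_all_bins_support_degenerates_to_zero_filled_ft(self, clean_fid_factory):
        fid = clean_fid_factory(4)
        n = fid.acq.n_points
        sup = SpectralSupport(np.arange(n), n)
        pat = sd.make_pattern(n, 0.3, 0.2, seed=7)
        fid_u = sd.undersample(fid, pat)
        res = sd.reconstruct(fid_u, pat, sup)
        assert res.converged and res.iterations == 1
        assert np.allclose(res.spectrum.data, fid_u.to_spectrum().data)

    def test_empty_p_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SpectralSupport(np.array([], dtype=int), 64)


class TestReconstruct:
    def test_fully_sampled_fixed_point(self, clean_fid_factory, peak_support):
        fid = clean_fid_factory(5, noise_sd=0.0)
        pat = sd.make_pattern(fid.acq.n_points, 0.0, 0.2, seed=0)
        res = sd.reconstruct(sd.undersample(fid, pat), pat, peak_support)
        assert res.converged and res.iterations <= 2
        full = fid.to_spectrum()
        pm = peak_support.p_mask
        scale = np.max(np.abs(full.data))
        assert np.max(np.abs(res.spectrum.data[pm] - full.data[pm])) < 1e-9 * scale

    def test_noiseless_recovery_up_to_half_skip(self, acq):
        """Exact-support single peak recovers to <1e-4 at 50% skipped."""
        peak = sd.PeakModel(178.0, 1.0, 3.0)
        model = sd.synth_fid([peak], acq).to_spectrum()
        sup = sd.build_support(model, peaks=[peak], guard_linewidths=2)
        fid = sd.remove_model_baseline(model.to_fid(), model, sup)
        exact = fid.to_spectrum()
        for skip in (0.3, 0.5):
            pat = sd.make_pattern(acq.n_points, skip, 0.2, seed=11)
            res = sd.reconstruct(sd.undersample(fid, pat), pat, sup,
                                 sd.ReconConfig(tolerance=1e-9))
            assert res.converged
            rel = (np.linalg.norm(res.spectrum.data - exact.data)
                   / np.linalg.norm(exact.data))
            assert rel < 1e-4

    def test_eps_non_increasing_on_noiseless_data(self, clean_fid_factory, peak_support):
        for seed in range(3):
            fid = clean_fid_factory(seed, noise_sd=0.0)
            pat = sd.make_pattern(fid.acq.n_points, 0.3, 0.2, seed=seed)
            res = sd.reconstruct(sd.undersample(fid, pat), pat, peak_support)
            diffs = np.diff(res.eps_history)
            assert np.all(diffs <= 1e-12)

    def test_non_convergence_is_flagged_not_raised(self, clean_fid_factory, peak_support):
        fid = clean_fid_factory(6)  # noisy: data inconsistent with exact support
        pat = sd.make_pattern(fid.acq.n_points, 0.5, 0.2, seed=8)
        res = sd.reconstruct(sd.undersample(fid, pat), pat, peak_support,
                             sd.ReconConfig(max_iter=50))
        assert not res.converged
        assert res.iterations == 50

    def test_measured_points_restored_in_output(self, clean_fid_factory, peak_support):
        fid = clean_fid_factory(7)
        pat = sd.make_pattern(fid.acq.n_points, 0.3, 0.2, seed=9)
        res = sd.reconstruct(sd.undersample(fid, pat), pat, peak_support,
                             sd.ReconConfig(max_iter=100))
        assert np.allclose(res.fid.data[pat.mask], fid.data[pat.mask])


class TestErrorMetrics:
    def test_identical_spectra_zero_error(self, model_spectrum, peaks):
        errs = sd.intensity_error(model_spectrum, model_spectrum, peaks)
        assert all(v == 0.0 for v in errs.values())
        assert sd.rmse(model_spectrum, model_spectrum) == 0.0

    def test_five_percent_scaling(self, model_spectrum, peaks):
        scaled = model_spectrum.copy()
        scaled.data = 1.05 * scaled.data
        errs = sd.intensity_error(scaled, model_spectrum, peaks)
        assert all(v == pytest.approx(5.0) for v in errs.values())
        signed = sd.intensity_error(model_spectrum, scaled, peaks, signed=True)
        assert all(v == pytest.approx(-100 / 21) for v in signed.values())

    def test_zero_reference_rejected(self, acq, model_spectrum):
        zero = sd.SpectrumData(np.zeros(acq.n_points), acq)
        with pytest.raises(ValueError, match="zero reference"):
            sd.intensity_error(model_spectrum, zero, [sd.PeakModel(178.0)])


class TestBaselineRemoval:
    def test_leaves_support_component_only(self, peaks, acq, model_spectrum, peak_support):
        fid = sd.synth_fid(peaks, acq, noise_sd=0.0)
        clean = sd.remove_model_baseline(fid, model_spectrum, peak_support)
        spec = clean.to_spectrum()
        zm = ~peak_support.p_mask
        assert np.max(np.abs(spec.data[zm])) < 1e-9 * np.max(np.abs(spec.data))
        pm = peak_support.p_mask
        assert np.allclose(spec.data[pm], model_spectrum.data[pm])


def test_noise_variance_advantage_at_equal_power(peaks, acq):
    """Same decoupled-point budget: under-sampling averages more transients,
    so the empty-region noise variance drops versus full sampling."""
    r = sd.monte_carlo_noise_ratio(peaks, acq, sd.INVIVO_LIKE_NOISE_SD, 0.30,
                                   probe_ppm=(169.5, 171.5), seed=5)
    assert r["n_under"] > r["n_full"]
    assert r["ratio_full_to_under"] > 1.0
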