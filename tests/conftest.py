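import pytest

import stochdec as sd


@pytest.fixture(scope="session")
def acq():
    """Default carboxylic/amide acquisition: 5 kHz, 1024 points, 75 MHz."""
    return sd.AcquisitionParams()


@pytest.fixture(scope="session")
def peaks():
    return sd.preset_peaks()


@pytest.fixture(scope="session")
def model_spectrum(peaks, acq):
    """Noise-free model spectrum of the carboxylic/amide preset."""
    return sd.synth_fid(peaks, acq, noise_sd=0.0).to_spectrum()


@pytest.fixture(scope="session")
def peak_support(model_spectrum, peaks):
    """Signal group P: metabolite peak windows (shift +/- 2 linewidths)."""
    return sd.build_support(model_spectrum, peaks=peaks, guard_linewidths=2)


@pytest.fixture(scope="session")
def clean_fid_factory(peaks, acq, model_spectrum, peak_support):
    """Baseline-removed noisy datasets (Z genuinely empty), seeded."""

    def make(seed: int, noise_sd: float = sd.INVIVO_LIKE_NOISE_SD):
        fid = sd.synth_fid(peaks, acq, noise_sd=noise_sd, seed=seed)
        return sd.remove_model_baseline(fid, model_spectrum, peak_support)

    return make
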