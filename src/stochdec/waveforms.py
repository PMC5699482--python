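"""Proton decoupling waveform construction, windowing, and analysis.

A decoupling waveform is a piecewise-constant RF irradiation described by
per-sample (amplitude, phase) pairs on a uniform raster.  Amplitudes are
expressed as the nutation frequency gamma*B2 in Hz; phases in degrees.
The complex representation of a sample is ``amplitude * exp(i*phase)``.

Families implemented:

* continuous wave (CW) — constant amplitude, zero phase;
* WALTZ-4 / WALTZ-16 composite-pulse decoupling built from the
  90x 180-x 270x block;
* Ernst-style pseudo-stochastic decoupling — constant amplitude,
  random phases drawn from {0, 180} degrees;
* vectorial noise decoupling — random amplitude and random phase
  on [0, 360) degrees.

The repetition rate of a stochastic sequence (1/sub-pulse duration) sets
its decoupling bandwidth, so the default sub-pulse duration is chosen to
cover the proton resonances scalar-coupled to carboxylic/amide carbons:
the 1.81-7.70 ppm range (the two coupled-proton bands of 1.91-3.90 and
6.83-7.60 ppm plus 0.1 ppm margins), centred at 4.755 ppm.

Frequency-domain windowing multiplies the waveform's discrete spectrum by
an ideal 0/1 double-bandpass mask and transforms back; by Parseval's
(Rayleigh's) theorem the retained power equals the in-band fraction of
the input's spectral power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "RFWaveform",
    "BandFilter",
    "WaveformPower",
    "COUPLED_PROTON_BANDS_PPM",
    "DEFAULT_BAND_MARGIN_PPM",
    "STOCHASTIC_SPAN_PPM",
    "STOCHASTIC_CARRIER_PPM",
    "default_sub_duration",
    "make_cw",
    "make_waltz",
    "make_waltz_s_block",
    "make_pseudo_stochastic",
    "make_vectorial_noise",
    "window_waveform",
    "waveform_power",
    "export_waveform",
    "import_waveform",
]

#: proton bands scalar-coupled to carboxylic/amide carbons (alkyl and amide
#: protons), in ppm: GABA H3 1.91 to Asp H2 3.90, and Gln amide 6.83-7.60.
COUPLED_PROTON_BANDS_PPM: tuple[tuple[float, float], ...] = ((1.91, 3.90), (6.83, 7.60))
DEFAULT_BAND_MARGIN_PPM = 0.1
#: full margin-expanded span 1.81-7.70 ppm covered by the stochastic band
STOCHASTIC_SPAN_PPM = 5.89
#: centre of the 1.81-7.70 ppm span; default irradiation carrier
STOCHASTIC_CARRIER_PPM = 4.755


@dataclass
class RFWaveform:
    """Sampled decoupling pulse on a uniform raster.

    Parameters
    ----------
    amplitude : array of float
        Per-sample gamma*B2 in Hz; non-negative.
    phase_deg : array of float
        Per-sample phase in degrees; normalized into [0, 360).
    dwell : float
        Seconds per sample.
    carrier_ppm : float
        ppm position of the irradiation carrier on the proton axis.
    label : str
    """

    amplitude: np.ndarray
    phase_deg: np.ndarray
    dwell: float
    carrier_ppm: float = STOCHASTIC_CARRIER_PPM
    label: str = ""

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase_deg = np.mod(np.asarray(self.phase_deg, dtype=float), 360.0)
        if self.amplitude.ndim != 1 or self.phase_deg.ndim != 1:
            raise ValueError("amplitude and phase_deg must be one-dimensional")
        if self.amplitude.size != self.phase_deg.size:
            raise ValueError("amplitude and phase_deg must have equal length")
        if self.amplitude.size == 0:
            raise ValueError("waveform must contain at least one sample")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative for every sample")
        if self.dwell <= 0:
            raise ValueError(f"dwell must be positive, got {self.dwell}")

    @property
    def n_samples(self) -> int:
        return int(self.amplitude.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dwell

    @property
    def complex_samples(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.deg2rad(self.phase_deg))

    @property
    def power(self) -> float:
        """Mean squared amplitude, Hz^2."""
        return float(np.mean(self.amplitude**2))

    @property
    def peak(self) -> float:
        return float(np.max(self.amplitude))


@dataclass
class BandFilter:
    """Ideal multi-bandpass filter specified in ppm on the proton axis.

    ``margin_ppm`` is added symmetrically to each band before use.
    ppm -> Hz conversion: ``offset_hz = (ppm - carrier_ppm) * f0_MHz``.
    """

    passbands: Sequence[tuple[float, float]]
    margin_ppm: float = DEFAULT_BAND_MARGIN_PPM
    f0_mhz: float = 500.0

    def __post_init__(self) -> None:
        bands = [(float(lo), float(hi)) for lo, hi in self.passbands]
        if not bands:
            raise ValueError("at least one passband is required")
        for lo, hi in bands:
            if lo >= hi:
                raise ValueError(f"band ({lo}, {hi}) must have low_ppm < high_ppm")
        if self.margin_ppm < 0:
            raise ValueError("margin_ppm must be non-negative")
        if self.f0_mhz <= 0:
            raise ValueError("f0_mhz must be positive")
        self.passbands = bands
        exp = self.expanded_bands
        for (a_lo, a_hi), (b_lo, b_hi) in zip(exp, exp[1:]):
            if a_hi >= b_lo:
                raise ValueError(
                    f"bands ({a_lo:.3f}, {a_hi:.3f}) and ({b_lo:.3f}, {b_hi:.3f}) ppm "
                    "overlap after margin expansion"
                )

    @property
    def expanded_bands(self) -> list[tuple[float, float]]:
        """Margin-expanded bands, sorted ascending in ppm."""
        return sorted(
            (lo - self.margin_ppm, hi + self.margin_ppm) for lo, hi in self.passbands
        )

    def bands_hz(self, carrier_ppm: float) -> list[tuple[float, float]]:
        """Margin-expanded bands as Hz offsets from ``carrier_ppm``."""
        return [
            ((lo - carrier_ppm) * self.f0_mhz, (hi - carrier_ppm) * self.f0_mhz)
            for lo, hi in self.expanded_bands
        ]


def coupled_proton_filter(f0_mhz: float, margin_ppm: float = DEFAULT_BAND_MARGIN_PPM) -> BandFilter:
    """Double bandpass over the carboxylic/amide coupled-proton regions."""
    return BandFilter(COUPLED_PROTON_BANDS_PPM, margin_ppm, f0_mhz)


def default_sub_duration(f0_mhz: float, span_ppm: float = STOCHASTIC_SPAN_PPM) -> float:
    """Stochastic sub-pulse duration whose repetition rate spans ``span_ppm``.

    The decoupling bandwidth of a random sequence equals its repetition
    rate 1/sub_duration; choosing ``1 / (span_ppm * f0_MHz)`` seconds makes
    that band cover the full coupled-proton range at the given field.
    """
    if f0_mhz <= 0:
        raise ValueError("f0_mhz must be positive")
    return 1.0 / (span_ppm * f0_mhz)


class WaveformPower(NamedTuple):
    mean_power: float  # Hz^2
    total_energy: float  # Hz^2 * s
    peak_amplitude: float  # Hz


def make_cw(gamma_b2: float, duration: float, dwell: float,
            carrier_ppm: float = STOCHASTIC_CARRIER_PPM) -> RFWaveform:
    """Constant-amplitude, zero-phase (continuous wave) irradiation."""
    if gamma_b2 < 0:
        raise ValueError(f"gamma_b2 must be non-negative, got {gamma_b2}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dwell <= 0:
        raise ValueError(f"dwell must be positive, got {dwell}")
    n_float = duration / dwell
    n = int(round(n_float))
    if n < 1 or abs(n_float - n) > 1e-6 * max(n, 1):
        raise ValueError(
            f"duration {duration} s is not an integral multiple of dwell {dwell} s"
        )
    return RFWaveform(
        np.full(n, float(gamma_b2)), np.zeros(n), dwell, carrier_ppm, label="cw"
    )


def _s_block(inverted: bool) -> list[tuple[int, float]]:
    """90 180 270 composite block as (n_quarter_turns, phase) entries.

    The base block is 90x 180(-x) 270x; the inverted block swaps x and -x.
    """
    x, mx = (180.0, 0.0) if inverted else (0.0, 180.0)
    return [(1, x), (2, mx), (3, x)]


def _expand_blocks(blocks: list[tuple[int, float]], gamma_b2: float):
    amps: list[float] = []
    phases: list[float] = []
    for quarters, phase in blocks:
        amps.extend([gamma_b2] * quarters)
        phases.extend([phase] * quarters)
    return np.array(amps), np.array(phases)


def make_waltz_s_block(gamma_b2: float, inverted: bool = False,
                       carrier_ppm: float = STOCHASTIC_CARRIER_PPM) -> RFWaveform:
    """Single composite 90x 180(-x) 270x inversion block (or its inverse)."""
    if gamma_b2 <= 0:
        raise ValueError(f"gamma_b2 must be positive, got {gamma_b2}")
    dwell = 0.25 / gamma_b2  # duration of one 90-degree pulse
    amps, phases = _expand_blocks(_s_block(inverted), gamma_b2)
    return RFWaveform(amps, phases, dwell, carrier_ppm, label="waltz-S")


def make_waltz(variant: int, gamma_b2: float, n_repeats: int = 1,
               carrier_ppm: float = STOCHASTIC_CARRIER_PPM) -> RFWaveform:
    """WALTZ-4 or WALTZ-16 composite-pulse decoupling sequence.

    WALTZ-4 is Sx Sx S-x S-x with Sx = 90x 180(-x) 270x.  WALTZ-16 is the
    MLEV-style supercycle of four WALTZ-4 segments, W W' W' W, where W' is
    WALTZ-4 with every phase inverted (x <-> -x).  A theta-degree pulse at
    field gamma_b2 lasts theta/360/gamma_b2 seconds; the raster dwell is
    the 90-degree pulse duration so every constituent pulse is exact.
    """
    if variant not in (4, 16):
        raise ValueError(f"unsupported WALTZ variant {variant}; use 4 or 16")
    if gamma_b2 <= 0:
        raise ValueError(f"gamma_b2 must be positive, got {gamma_b2}")
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    s, sbar = _s_block(False), _s_block(True)
    w4 = s + s + sbar + sbar
    if variant == 4:
        blocks = w4
    else:
        w4bar = sbar + sbar + s + s
        blocks = w4 + w4bar + w4bar + w4
    amps, phases = _expand_blocks(blocks * n_repeats, gamma_b2)
    dwell = 0.25 / gamma_b2
    return RFWaveform(amps, phases, dwell, carrier_ppm, label=f"waltz-{variant}")


def make_pseudo_stochastic(gamma_b2: float, n_sub: int, sub_duration: float,
                           seed: int, carrier_ppm: float = STOCHASTIC_CARRIER_PPM) -> RFWaveform:
    """Ernst pseudo-stochastic sequence: constant amplitude, random 0/180 phases.

    Phases are i.i.d. equiprobable on {0, 180} degrees, reproducible from
    ``seed``.  The decoupling bandwidth equals the sub-pulse repetition
    rate 1/sub_duration.
    """
    if gamma_b2 < 0:
        raise ValueError(f"gamma_b2 must be non-negative, got {gamma_b2}")
    if n_sub < 1:
        raise ValueError(f"n_sub must be >= 1, got {n_sub}")
    if sub_duration <= 0:
        raise ValueError(f"sub_duration must be positive, got {sub_duration}")
    rng = np.random.default_rng(seed)
    phases = rng.choice([0.0, 180.0], size=n_sub)
    return RFWaveform(
        np.full(n_sub, float(gamma_b2)), phases, sub_duration, carrier_ppm,
        label=f"pseudo-stochastic(seed={seed})",
    )


def make_vectorial_noise(peak_gamma_b2: float, n_sub: int, sub_duration: float,
                         seed: int, carrier_ppm: float = STOCHASTIC_CARRIER_PPM) -> RFWaveform:
    """Vectorial noise sequence: random amplitude and random phase.

    Phases i.i.d. uniform on [0, 360) degrees; amplitudes i.i.d. uniform on
    [0, peak_gamma_b2] (the amplitude law is a documented modelling choice;
    expected power is peak^2/3).
    """
    if peak_gamma_b2 < 0:
        raise ValueError(f"peak_gamma_b2 must be non-negative, got {peak_gamma_b2}")
    if n_sub < 1:
        raise ValueError(f"n_sub must be >= 1, got {n_sub}")
    if sub_duration <= 0:
        raise ValueError(f"sub_duration must be positive, got {sub_duration}")
    rng = np.random.default_rng(seed)
    amps = rng.uniform(0.0, peak_gamma_b2, size=n_sub)
    phases = rng.uniform(0.0, 360.0, size=n_sub)
    return RFWaveform(
        amps, phases, sub_duration, carrier_ppm,
        label=f"vectorial-noise(seed={seed})",
    )


def window_waveform(wf: RFWaveform, filt: BandFilter) -> RFWaveform:
    """Apply an ideal 0/1 multi-bandpass mask to the waveform's spectrum.

    The discrete Fourier transform of the complex waveform is multiplied by
    the mask (real and imaginary components identically, i.e. the complex
    bins), band edges mapped to the nearest DFT bins, then inverse
    transformed.  Output length and dwell equal the input's; output power
    equals the in-band fraction of the input's spectral power (Parseval).
    """
    n = wf.n_samples
    fs = 1.0 / wf.dwell
    freqs = np.fft.fftfreq(n, wf.dwell)
    mask = np.zeros(n, dtype=bool)
    for lo_hz, hi_hz in filt.bands_hz(wf.carrier_ppm):
        if hi_hz < -fs / 2 or lo_hz >= fs / 2:
            raise ValueError(
                f"band ({lo_hz:.1f}, {hi_hz:.1f}) Hz lies entirely outside the "
                f"representable bandwidth +/-{fs / 2:.1f} Hz around the carrier"
            )
        mask |= (freqs >= lo_hz) & (freqs <= hi_hz)
    spectrum = np.fft.fft(wf.complex_samples)
    out = np.fft.ifft(spectrum * mask)
    return RFWaveform(
        np.abs(out),
        np.rad2deg(np.angle(out)),
        wf.dwell,
        wf.carrier_ppm,
        label=(wf.label + "|windowed") if wf.label else "windowed",
    )


def waveform_power(wf: RFWaveform) -> WaveformPower:
    """Mean power (Hz^2), total energy (Hz^2 s) and peak amplitude (Hz)."""
    mean_power = wf.power
    return WaveformPower(mean_power, mean_power * wf.duration, wf.peak)


def export_waveform(wf: RFWaveform, path, format: str = "shape") -> None:
    """Serialize a waveform to disk.

    ``shape`` writes a JCAMP-DX-style pulse-shape file (amplitude as percent
    of the peak, phase in degrees); ``delimited`` writes two-column
    amplitude/phase text with dwell and carrier in the header.
    """
    from . import fileio

    if format == "shape":
        fileio.write_shape(wf, path)
    elif format == "delimited":
        fileio.write_delimited_waveform(wf, path)
    else:
        raise ValueError(f"unknown waveform format {format!r}; use 'shape' or 'delimited'")


def import_waveform(path, format: str | None = None) -> RFWaveform:
    """Inverse of :func:`export_waveform`; format auto-detected when omitted."""
    from . import fileio

    if format is None:
        format = fileio.sniff_waveform_format(path)
    if format == "shape":
        return fileio.read_shape(path)
    if format == "delimited":
        return fileio.read_delimited_waveform(path)
    raise ValueError(f"unknown waveform format {format!r}; use 'shape' or 'delimited'")
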