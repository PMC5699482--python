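"""Shared in-memory containers: acquisition metadata, FIDs and spectra.

Conventions
-----------
* The forward Fourier transform maps time to frequency with no
  normalization; the inverse carries the ``1/n`` factor (numpy default).
* :class:`SpectrumData` stores bins in ascending-frequency (fftshifted)
  order.  The conventional NMR display runs ppm *decreasing* left to
  right; exporters and plots reverse the axis, the container does not.
* Chemical-shift axis: ``ppm = carrier_ppm + offset_hz / f0_mhz``
  (1 ppm corresponds to ``f0_mhz`` Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["AcquisitionParams", "FIDData", "SpectrumData"]

#: metadata entry recorded on every transformed container
FFT_CONVENTION = "forward fft time->frequency (no scaling); inverse carries 1/n; ppm decreasing left-to-right on export"


@dataclass
class AcquisitionParams:
    """Receiver-side acquisition parameters for a 1D acquisition.

    Defaults correspond to a carboxylic/amide carbon acquisition:
    5 kHz spectral width, 1024 complex points, carrier at 177 ppm on a
    75 MHz carbon channel (~7 T).
    """

    sw_hz: float = 5000.0
    n_points: int = 1024
    f0_mhz: float = 75.0
    carrier_ppm: float = 177.0
    tr_s: float = 5.0
    ns: int = 1

    def __post_init__(self) -> None:
        if self.sw_hz <= 0:
            raise ValueError(f"sw_hz must be positive, got {self.sw_hz}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.f0_mhz <= 0:
            raise ValueError(f"f0_mhz must be positive, got {self.f0_mhz}")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.ns < 1:
            raise ValueError(f"ns must be >= 1, got {self.ns}")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sw_hz

    @property
    def acq_time_s(self) -> float:
        return self.n_points * self.dwell_s

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_s

    def freq_axis_hz(self) -> np.ndarray:
        """Offsets from the receiver carrier, ascending (fftshifted)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, self.dwell_s))

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis matching :meth:`freq_axis_hz` (ascending)."""
        return self.carrier_ppm + self.freq_axis_hz() / self.f0_mhz

    def ppm_to_bin(self, ppm: float) -> int:
        """Nearest spectrum bin (ascending-frequency order) for a shift."""
        axis = self.ppm_axis()
        return int(np.argmin(np.abs(axis - ppm)))


@dataclass
class FIDData:
    """Complex time-domain signal plus its acquisition metadata."""

    data: np.ndarray
    acq: AcquisitionParams
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 1:
            raise ValueError("FID data must be one-dimensional")
        if self.data.size != self.acq.n_points:
            raise ValueError(
                f"FID length {self.data.size} does not match acq.n_points {self.acq.n_points}"
            )

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))

    def to_spectrum(self) -> "SpectrumData":
        spec = np.fft.fftshift(np.fft.fft(self.data))
        meta = dict(self.meta)
        meta["fft_convention"] = FFT_CONVENTION
        return SpectrumData(spec, self.acq, meta)

    def copy(self) -> "FIDData":
        return FIDData(self.data.copy(), self.acq, dict(self.meta))


@dataclass
class SpectrumData:
    """Complex frequency-domain signal, bins in ascending-frequency order."""

    data: np.ndarray
    acq: AcquisitionParams
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 1:
            raise ValueError("spectrum data must be one-dimensional")
        if self.data.size != self.acq.n_points:
            raise ValueError(
                f"spectrum length {self.data.size} does not match acq.n_points {self.acq.n_points}"
            )

    @property
    def ppm(self) -> np.ndarray:
        return self.acq.ppm_axis()

    @property
    def freq_hz(self) -> np.ndarray:
        return self.acq.freq_axis_hz()

    def to_fid(self) -> FIDData:
        fid = np.fft.ifft(np.fft.ifftshift(self.data))
        meta = dict(self.meta)
        meta["fft_convention"] = FFT_CONVENTION
        return FIDData(fid, self.acq, meta)

    def copy(self) -> "SpectrumData":
        return SpectrumData(self.data.copy(), self.acq, dict(self.meta))
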