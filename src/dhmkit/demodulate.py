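"""Fourier sideband demodulation of off-axis interferograms.

The carrier tilt shifts the object spectrum away from DC, producing two
conjugate sidelobes.  Cropping one sidelobe, re-centering it at zero
frequency and inverse-transforming recovers (a scaled estimate of) the
complex object field, whose argument is the wrapped object phase.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import Interferogram, PhaseMap

__all__ = [
    "ComplexSpectrum",
    "SidelobeWindow",
    "NoSidelobeError",
    "fourier_spectrum",
    "locate_sidelobe",
    "demodulate",
]


class NoSidelobeError(ValueError):
    """Raised when no carrier sidelobe stands out of the spectrum."""


@dataclass
class ComplexSpectrum:
    """Centred 2D DFT of an interferogram (zero frequency at ``dc_bin``)."""

    values: np.ndarray
    frequency_pitch: tuple[float, float]  # (rows, cols) cycles/μm per bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("spectrum must be 2D")

    @property
    def dc_bin(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


@dataclass(frozen=True)
class SidelobeWindow:
    """Rectangular crop window in spectrum bins, centred on a sidelobe."""

    center_bin: tuple[int, int]
    half_size: tuple[int, int]

    def slices(self) -> tuple[slice, slice]:
        (r, c), (hr, hc) = self.center_bin, self.half_size
        return slice(r - hr, r + hr + 1), slice(c - hc, c + hc + 1)

    def validate(self, shape: tuple[int, int], dc_bin: tuple[int, int]) -> None:
        (r, c), (hr, hc) = self.center_bin, self.half_size
        if hr < 0 or hc < 0:
            raise ValueError("half_size must be nonnegative")
        if r - hr < 0 or c - hc < 0 or r + hr >= shape[0] or c + hc >= shape[1]:
            raise ValueError("sidelobe window extends outside the spectrum")
        if abs(r - dc_bin[0]) <= hr and abs(c - dc_bin[1]) <= hc:
            raise ValueError("sidelobe window must exclude the DC bin")


def fourier_spectrum(holo: Interferogram) -> ComplexSpectrum:
    """Centred discrete Fourier transform of the interferogram."""
    pixels = np.asarray(holo.pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("interferogram must be 2D")
    spec = np.fft.fftshift(np.fft.fft2(pixels))
    ny, nx = pixels.shape
    pitch = holo.config.pixel_pitch
    return ComplexSpectrum(spec, (1.0 / (ny * pitch), 1.0 / (nx * pitch)))


def locate_sidelobe(spec: ComplexSpectrum, dc_exclusion_radius: int = 8,
                    half_size: tuple[int, int] | None = None,
                    snr_threshold: float = 3.0) -> SidelobeWindow:
    """Find the carrier sidelobe in the upper half-plane of the spectrum.

    The sidelobe is the magnitude argmax outside a disk of
    ``dc_exclusion_radius`` bins around DC, restricted to rows strictly above
    the DC row (ties broken towards larger column index).  Unless
    ``half_size`` is given, the window half-width is half the Chebyshev
    distance from the peak to DC — the largest square window that cannot
    touch the DC bin.

    Raises
    ------
    NoSidelobeError
        If the winning peak is weaker than ``snr_threshold`` times the median
        spectral magnitude (an unmodulated or blank image).
    """
    if dc_exclusion_radius < 1:
        raise ValueError("dc_exclusion_radius must be >= 1")
    mag = np.abs(spec.values)
    dc_r, dc_c = spec.dc_bin
    rows = np.arange(mag.shape[0])[:, None]
    cols = np.arange(mag.shape[1])[None, :]
    allowed = ((rows - dc_r) ** 2 + (cols - dc_c) ** 2
               > dc_exclusion_radius ** 2) & (rows < dc_r)
    if not allowed.any():
        raise NoSidelobeError("no spectrum bins available outside DC exclusion")

    masked = np.where(allowed, mag, -np.inf)
    best = masked.max()
    # numerically blank spectra can still show >3x median FFT round-off
    # noise, so also require the peak to be non-negligible relative to DC
    dc_floor = 1e-6 * mag[dc_r, dc_c]
    if (not np.isfinite(best) or best < snr_threshold * np.median(mag)
            or best < dc_floor):
        raise NoSidelobeError(
            "no sidelobe: peak magnitude below threshold — image appears "
            "unmodulated or blank")
    peak_rows, peak_cols = np.nonzero(masked == best)
    order = np.lexsort((-peak_cols, peak_rows))  # ties: larger column wins
    r, c = int(peak_rows[order[0]]), int(peak_cols[order[0]])

    if half_size is None:
        cheb = max(abs(r - dc_r), abs(c - dc_c))
        h = cheb // 2
        half_size = (h, h)
    window = SidelobeWindow((r, c), tuple(int(v) for v in half_size))
    window.validate(mag.shape, spec.dc_bin)
    return window


def demodulate(holo: Interferogram, window: SidelobeWindow | None = None,
               dc_exclusion_radius: int = 8,
               taper: bool = False) -> tuple[PhaseMap, np.ndarray]:
    """Recover the wrapped object phase and amplitude from a hologram.

    Crops the sidelobe window, embeds it centred at DC in a zero spectrum of
    the original shape, and inverse-transforms.  Returns the wrapped phase
    (argument of the field, in (−π, π]) and the field modulus, which
    estimates ``P_R * P_O``.

    With ``taper=True`` a raised-cosine (Hann) window is applied to the crop
    to suppress ringing from the hard spectral edges.
    """
    spec = fourier_spectrum(holo)
    if window is None:
        window = locate_sidelobe(spec, dc_exclusion_radius=dc_exclusion_radius)
    window.validate(spec.values.shape, spec.dc_bin)

    crop = spec.values[window.slices()].copy()
    if taper:
        wr = np.hanning(crop.shape[0] + 2)[1:-1]
        wc = np.hanning(crop.shape[1] + 2)[1:-1]
        crop *= wr[:, None] * wc[None, :]

    out = np.zeros_like(spec.values)
    dc_r, dc_c = spec.dc_bin
    hr, hc = window.half_size
    out[dc_r - hr: dc_r + hr + 1, dc_c - hc: dc_c + hc + 1] = crop
    field = np.fft.ifft2(np.fft.ifftshift(out))
    phase = np.angle(field)
    # np.angle returns [-pi, pi]; fold the closed lower endpoint
    phase[phase <= -np.pi] = np.pi
    return PhaseMap(phase, wrapped=True), np.abs(field)
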