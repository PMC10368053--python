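"""Optical configuration and core image/phase containers.

All lengths are micrometres (μm); angles and phases are radians. Carrier
tilts are spatial angular frequencies in rad/μm at the object plane.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["OpticalConfig", "Interferogram", "PhaseMap"]


@dataclass(frozen=True)
class OpticalConfig:
    """Physical constants of the imaging experiment.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in μm.
    pixel_pitch : float
        Object-plane sampling in μm per pixel.
    n_medium : float
        Refractive index of the surrounding fluid medium.
    tilt_alpha, tilt_beta : float
        Carrier spatial angular frequencies along x (columns) and
        y (rows), rad/μm.  The default carrier lies along the image
        diagonal at one eighth of the per-axis Nyquist frequency, with
        ``tilt_beta < 0`` so that the selected sidelobe sits in the
        upper half-plane of the centred spectrum.
    image_shape : (int, int)
        Rows, columns of the simulated/recorded frame.
    bit_depth : int
        Camera quantization depth (intensity levels ``2**bit_depth``).
    """

    wavelength: float = 0.532
    pixel_pitch: float = 0.3
    n_medium: float = 1.336
    tilt_alpha: float = field(default=math.nan)
    tilt_beta: float = field(default=math.nan)
    image_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if math.isnan(self.tilt_alpha) or math.isnan(self.tilt_beta):
            # 1/8 of the per-axis Nyquist angular frequency, diagonal.
            f = math.pi / self.pixel_pitch / 8.0
            if math.isnan(self.tilt_alpha):
                object.__setattr__(self, "tilt_alpha", f)
            if math.isnan(self.tilt_beta):
                object.__setattr__(self, "tilt_beta", -f)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def wavenumber(self) -> float:
        """k = 2π/λ in rad/μm."""
        return 2.0 * math.pi / self.wavelength

    @property
    def carrier_magnitude(self) -> float:
        """sqrt(α² + β²), rad/μm."""
        return math.hypot(self.tilt_alpha, self.tilt_beta)

    @property
    def field_of_view(self) -> tuple[float, float]:
        """Physical extent (height, width) in μm."""
        return (self.image_shape[0] * self.pixel_pitch,
                self.image_shape[1] * self.pixel_pitch)

    @property
    def max_level(self) -> int:
        return 2 ** self.bit_depth - 1

    def validate(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ValueError("image_shape must be two positive integers")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        if self.carrier_magnitude * self.pixel_pitch >= math.pi:
            raise ValueError(
                "carrier tilt violates Nyquist: "
                "sqrt(alpha^2+beta^2) * pixel_pitch must be < pi"
            )

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate grids of pixel centres, μm.

        Pixel (0, 0) is the top-left corner; the centre of pixel
        ``(i, j)`` is at ``x = (j + 0.5) * pixel_pitch``,
        ``y = (i + 0.5) * pixel_pitch``.
        """
        ny, nx = self.image_shape
        x = (np.arange(nx) + 0.5) * self.pixel_pitch
        y = (np.arange(ny) + 0.5) * self.pixel_pitch
        return np.meshgrid(x, y)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(int(v) for v in d["image_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OpticalConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Interferogram:
    """A recorded or simulated intensity frame (nonnegative)."""

    pixels: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("interferogram must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("interferogram intensities must be nonnegative")


@dataclass
class PhaseMap:
    """A 2D phase field in radians, wrapped into (−π, π] or unwrapped."""

    values: np.ndarray
    wrapped: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phase map must be a 2D array")
        if self.wrapped:
            v = self.values
            if v.size and (v.min() <= -np.pi - 1e-12 or v.max() > np.pi + 1e-12):
                raise ValueError("wrapped phase must lie in (-pi, pi]")
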