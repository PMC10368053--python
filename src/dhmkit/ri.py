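"""Per-pixel effective refractive index from unwrapped phase.

The specimen is modelled as a hemisphere (doubled to a full sphere of radius
R) sitting on the circular region of interest, so the geometric path length
through the specimen at in-plane radius r is the chord ``h = 2*sqrt(R²-r²)``.
With the annulus just outside the ROI fixing the phase zero level, the
effective index at each pixel is ``n_s = dphi / (k*h) + n_medium``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import find_peaks

from .optics import OpticalConfig, PhaseMap

__all__ = [
    "CircularROI",
    "RIMap",
    "chord_height",
    "background_subtract",
    "compute_ri",
    "ri_histogram",
]

#: pixels whose reconstructed index falls outside
#: [n_medium + LOWER_MARGIN, n_medium + UPPER_MARGIN] are flagged invalid
LOWER_MARGIN = -0.05
UPPER_MARGIN = 0.10

MIN_RING_PIXELS = 50


@dataclass(frozen=True)
class CircularROI:
    """Analysis circle (μm): centre, radius, and background-ring width."""

    center_x: float
    center_y: float
    radius: float
    ring_width: float = 5.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if self.ring_width <= 0:
            raise ValueError("ring width must be positive")

    def scaled(self, factor: float) -> "CircularROI":
        return CircularROI(self.center_x, self.center_y,
                           self.radius * factor, self.ring_width)

    def radial_distance(self, config: OpticalConfig) -> np.ndarray:
        x, y = config.pixel_coords()
        return np.hypot(x - self.center_x, y - self.center_y)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "center_x": self.center_x, "center_y": self.center_y,
            "radius": self.radius, "ring_width": self.ring_width,
        }, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CircularROI":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RIMap:
    """Per-pixel effective RI with validity mask and summary statistics."""

    values: np.ndarray
    mask: np.ndarray
    n_medium: float
    summary: dict = field(default_factory=dict)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def chord_height(roi: CircularROI, x, y) -> np.ndarray | float:
    """Chord length through the sphere at physical position(s) (x, y), μm.

    ``h = 2*sqrt(R² - r²)`` inside the circle, 0 at and beyond the rim.
    """
    r2 = (np.asarray(x, dtype=float) - roi.center_x) ** 2 + \
         (np.asarray(y, dtype=float) - roi.center_y) ** 2
    h = 2.0 * np.sqrt(np.maximum(roi.radius ** 2 - r2, 0.0))
    return h if h.ndim else float(h)


def background_subtract(phase: PhaseMap, roi: CircularROI,
                        config: OpticalConfig) -> PhaseMap:
    """Remove the mean phase measured in the annulus [R, R + ring_width].

    After subtraction the annulus mean is zero, anchoring the phase zero
    level to the specimen-free background.
    """
    if phase.wrapped:
        raise ValueError("background subtraction expects an unwrapped phase")
    r = roi.radial_distance(config)
    ring = (r >= roi.radius) & (r <= roi.radius + roi.ring_width)
    height, width = config.field_of_view
    x, y = config.pixel_coords()
    inside = (x >= 0) & (x <= width) & (y >= 0) & (y <= height)
    ring &= inside
    n_ring = int(ring.sum())
    if n_ring < MIN_RING_PIXELS:
        raise ValueError(
            f"background annulus has only {n_ring} pixels inside the image "
            f"(need >= {MIN_RING_PIXELS}); enlarge ring_width or move the ROI")
    return PhaseMap(phase.values - phase.values[ring].mean(), wrapped=False)


def compute_ri(phase: PhaseMap, roi: CircularROI, config: OpticalConfig,
               h_min_frac: float = 0.1) -> RIMap:
    """Invert phase to effective RI over the ROI.

    Pixels are valid when inside the circle, their chord is at least
    ``h_min_frac`` of the centre chord 2R (guarding the rim where the
    vanishing denominator amplifies noise), and the resulting index lies
    within the plausibility band around ``n_medium``.  Implausible values are
    flagged, never clipped.
    """
    if phase.wrapped:
        raise ValueError("compute_ri expects an unwrapped phase")
    if not 0 <= h_min_frac < 1:
        raise ValueError("h_min_frac must be in [0, 1)")
    x, y = config.pixel_coords()
    h = chord_height(roi, x, y)
    geometric = h >= max(h_min_frac, 1e-12) * 2.0 * roi.radius

    values = np.full(config.image_shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[geometric] = (phase.values[geometric]
                             / (config.wavenumber * h[geometric])
                             + config.n_medium)

    plausible = np.zeros_like(geometric)
    plausible[geometric] = (
        np.isfinite(values[geometric])
        & (values[geometric] >= config.n_medium + LOWER_MARGIN)
        & (values[geometric] <= config.n_medium + UPPER_MARGIN)
    )
    mask = geometric & plausible
    if not mask.any():
        raise ValueError("no valid pixels in the RI map")

    valid = values[mask]
    hist, edges = np.histogram(valid, bins=64)
    summary = {
        "mean": float(valid.mean()),
        "median": float(np.median(valid)),
        "n_valid": int(mask.sum()),
        "n_geometric": int(geometric.sum()),
        "histogram": {"counts": hist.tolist(), "bin_edges": edges.tolist()},
    }
    return RIMap(values=values, mask=mask, n_medium=config.n_medium,
                 summary=summary)


def ri_histogram(rimap: RIMap, bins: int = 64,
                 min_separation_bins: int = 2,
                 min_prominence_frac: float = 0.05) -> dict:
    """Normalised RI frequency distribution and its detected modes.

    Modes are local maxima of the normalised histogram separated by at least
    ``min_separation_bins`` bins, with prominence at least
    ``min_prominence_frac`` of the tallest bin (suppresses sampling jitter).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    valid = rimap.valid_values
    if valid.size == 0:
        raise ValueError("RI map has no valid pixels")
    counts, edges = np.histogram(valid, bins=bins)
    freq = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    # zero-pad so modes sitting on the first/last bin are still detected
    padded = np.concatenate([[0.0], freq, [0.0]])
    peaks, _ = find_peaks(padded, distance=max(min_separation_bins, 1),
                          prominence=min_prominence_frac * freq.max())
    peaks = peaks - 1
    return {
        "frequency": freq,
        "bin_centers": centers,
        "bin_edges": edges,
        "modes": [float(centers[i]) for i in peaks],
    }
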