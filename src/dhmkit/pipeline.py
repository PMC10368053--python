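"""High-level composition of the reconstruction stages.

``reconstruct_phase`` chains demodulation and unwrapping;
``reconstruct_ri`` additionally anchors the background and inverts to an
effective refractive-index map.
"""
from __future__ import annotations

from .demodulate import SidelobeWindow, demodulate
from .optics import Interferogram, OpticalConfig, PhaseMap
from .ri import CircularROI, RIMap, background_subtract, compute_ri
from .unwrap import unwrap_phase

__all__ = ["reconstruct_phase", "reconstruct_ri"]


def reconstruct_phase(holo: Interferogram,
                      window: SidelobeWindow | None = None,
                      dc_exclusion_radius: int = 8,
                      taper: bool = False) -> PhaseMap:
    """Demodulate and unwrap a hologram into a continuous phase map.

    The returned phase carries an arbitrary global offset (integer-bin
    sidelobe centering leaves a residual constant/linear term); use ring
    background subtraction to fix the zero level.
    """
    wrapped, _ = demodulate(holo, window=window,
                            dc_exclusion_radius=dc_exclusion_radius,
                            taper=taper)
    return unwrap_phase(wrapped)


def reconstruct_ri(holo: Interferogram, roi: CircularROI,
                   config: OpticalConfig | None = None,
                   window: SidelobeWindow | None = None,
                   h_min_frac: float = 0.1,
                   taper: bool = False) -> RIMap:
    """Full hologram → RI-map pipeline for one specimen."""
    config = config or holo.config
    phase = reconstruct_phase(holo, window=window, taper=taper)
    corrected = background_subtract(phase, roi, config)
    return compute_ri(corrected, roi, config, h_min_frac=h_min_frac)
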