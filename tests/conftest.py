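import math

import numpy as np
import pytest

import dhmkit as dk


def make_config(n: int = 256, carrier_frac: float = 4.0,
                pitch: float = 0.3) -> dk.OpticalConfig:
    """Square config with a diagonal carrier at 1/carrier_frac of the
    per-axis Nyquist frequency.  For n divisible by 2*carrier_frac the
    carrier lands on an integer spectrum bin, so integer-bin sidelobe
    centering leaves no residual linear phase."""
    f = math.pi / pitch / carrier_frac
    return dk.OpticalConfig(tilt_alpha=f, tilt_beta=-f,
                            image_shape=(n, n), pixel_pitch=pitch)


def sidelobe_window(cfg: dk.OpticalConfig, frac: float = 7 / 64):
    """Generous crop window (half-size = frac * image size) used when the
    carrier separation allows it."""
    n = cfg.image_shape[0]
    h = int(frac * n)
    return (h, h)


def roundtrip(spec: dk.PhantomSpec, cfg: dk.OpticalConfig,
              taper: bool = False):
    """synthesize → demodulate → unwrap; returns (truth, recovered)."""
    truth = dk.phantom_phase(spec, cfg)
    holo = dk.synthesize_hologram(truth, spec, cfg)
    window = dk.locate_sidelobe(dk.fourier_spectrum(holo),
                                half_size=sidelobe_window(cfg))
    wrapped, _ = dk.demodulate(holo, window, taper=taper)
    return truth, dk.unwrap_phase(wrapped)


def offset_rms(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    d = d - d.mean()
    return float(np.sqrt(np.mean(d ** 2)))


@pytest.fixture(scope="session")
def fast_config() -> dk.OpticalConfig:
    """256 px field at 0.3 μm/px with quarter-Nyquist diagonal carrier."""
    return make_config(256)


@pytest.fixture(scope="session")
def paper_config() -> dk.OpticalConfig:
    """The shipped representative configuration: 512 px, 0.3 μm/px,
    eighth-Nyquist diagonal carrier."""
    return dk.OpticalConfig()


@pytest.fixture(scope="session")
def sphere_phantom(fast_config):
    h, w = fast_config.field_of_view
    spec = dk.PhantomSpec(
        spheres=[dk.Sphere(w / 2, h / 2, 25.0, 0.004)])
    roi = dk.CircularROI(w / 2, h / 2, 25.0)
    return spec, roi


@pytest.fixture(scope="session")
def shell_phantom(fast_config):
    """Cytoplasm sphere nearly filling a thin zona-like shell."""
    h, w = fast_config.field_of_view
    spec = dk.PhantomSpec(
        spheres=[dk.Sphere(w / 2, h / 2, 28.0, 0.004)],
        shell=dk.Shell(w / 2, h / 2, 28.0, 30.0, 0.002))
    roi = dk.CircularROI(w / 2, h / 2, 30.0)
    return spec, roi
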