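"""Synthetic off-axis hologram generator for embryo-like phase phantoms.

A phantom is a collection of transparent spherical compartments (cytoplasm
spheres, an optional zona-like shell, an optional low-index cavity) immersed
in a medium.  Under the projection approximation the accumulated phase at a
pixel is the wavenumber times the sum over compartments of
``delta_n * chord_length`` along the optical axis; compartment contributions
are additive, so overlapping geometry simply accumulates optical path.

The forward interferogram model is

    I = P_R**2 + P_O**2 + 2 * P_R * P_O * cos(dphi + alpha*x + beta*y)

followed by optional Poisson shot noise and camera quantization.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .optics import Interferogram, OpticalConfig, PhaseMap

__all__ = [
    "Sphere",
    "Shell",
    "NoiseSpec",
    "PhantomSpec",
    "phantom_phase",
    "synthesize_hologram",
    "make_embryo_series",
    "EMBRYO_STAGES",
    "LIPID_LEVELS",
]

EMBRYO_STAGES = ("2cell", "4cell", "8cell", "morula", "blastocyst")
LIPID_LEVELS = ("low", "high")

#: delta_n of cytoplasm under low-lipid conditions; high-lipid multiplies it.
CYTOPLASM_DELTA_N = 0.004
HIGH_LIPID_FACTOR = 1.5
ZONA_DELTA_N = 0.002


@dataclass(frozen=True)
class Sphere:
    """A homogeneous sphere: in-plane centre (μm), radius (μm), RI excess."""

    center_x: float
    center_y: float
    radius: float
    delta_n: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def chord(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r2 = (x - self.center_x) ** 2 + (y - self.center_y) ** 2
        return 2.0 * np.sqrt(np.maximum(self.radius ** 2 - r2, 0.0))


@dataclass(frozen=True)
class Shell:
    """A spherical shell: chord is outer-sphere chord minus inner-sphere chord."""

    center_x: float
    center_y: float
    inner_radius: float
    outer_radius: float
    delta_n: float

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius <= self.outer_radius:
            raise ValueError("require 0 < inner_radius <= outer_radius")

    def chord(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r2 = (x - self.center_x) ** 2 + (y - self.center_y) ** 2
        outer = 2.0 * np.sqrt(np.maximum(self.outer_radius ** 2 - r2, 0.0))
        inner = 2.0 * np.sqrt(np.maximum(self.inner_radius ** 2 - r2, 0.0))
        return outer - inner


@dataclass(frozen=True)
class NoiseSpec:
    """Shot-noise model: expected photons per intensity unit, and RNG seed."""

    photon_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")


@dataclass
class PhantomSpec:
    """Full description of a synthetic specimen.

    ``background_poly`` holds 2D polynomial coefficients ``c[i, j]`` for the
    term ``(x / width)**j * (y / height)**i`` evaluated over normalised frame
    coordinates, so coefficients are read directly in radians of peak
    background phase across the field.
    """

    spheres: list[Sphere] = field(default_factory=list)
    shell: Shell | None = None
    cavity: Sphere | None = None
    background_poly: np.ndarray | None = None
    amplitude_object: float = 120.0
    amplitude_reference: float = 120.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def components(self) -> list[Sphere | Shell]:
        out: list[Sphere | Shell] = list(self.spheres)
        if self.shell is not None:
            out.append(self.shell)
        if self.cavity is not None:
            out.append(self.cavity)
        return out

    def validate(self, config: OpticalConfig) -> None:
        height, width = config.field_of_view
        for c in self.components():
            r = c.outer_radius if isinstance(c, Shell) else c.radius
            if (c.center_x - r < 0 or c.center_x + r > width
                    or c.center_y - r < 0 or c.center_y + r > height):
                raise ValueError(
                    f"phantom component at ({c.center_x:.1f}, {c.center_y:.1f}) "
                    f"with radius {r:.1f} μm does not fit the "
                    f"{height:.1f}x{width:.1f} μm field of view"
                )
        if self.amplitude_reference <= 0:
            raise ValueError("amplitude_reference must be > 0")
        if self.amplitude_object < 0:
            raise ValueError("amplitude_object must be >= 0")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):  # numpy scalars -> YAML-safe python floats
            return {k: float(v) for k, v in asdict(obj).items()}

        d = {
            "spheres": [plain(s) for s in self.spheres],
            "shell": plain(self.shell) if self.shell else None,
            "cavity": plain(self.cavity) if self.cavity else None,
            "background_poly": (None if self.background_poly is None
                                else np.asarray(self.background_poly).tolist()),
            "amplitude_object": self.amplitude_object,
            "amplitude_reference": self.amplitude_reference,
            "noise": asdict(self.noise),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            spheres=[Sphere(**s) for s in d.get("spheres", [])],
            shell=Shell(**d["shell"]) if d.get("shell") else None,
            cavity=Sphere(**d["cavity"]) if d.get("cavity") else None,
            background_poly=(None if d.get("background_poly") is None
                             else np.asarray(d["background_poly"], dtype=float)),
            amplitude_object=d.get("amplitude_object", 120.0),
            amplitude_reference=d.get("amplitude_reference", 120.0),
            noise=NoiseSpec(**d.get("noise", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def phantom_phase(spec: PhantomSpec, config: OpticalConfig) -> PhaseMap:
    """Ground-truth (unwrapped) phase accumulated through the phantom.

    At each pixel ``dphi = k * sum(delta_n * chord)`` over all compartments,
    plus the smooth background polynomial.
    """
    spec.validate(config)
    x, y = config.pixel_coords()
    k = config.wavenumber
    dphi = np.zeros(config.image_shape, dtype=float)
    for comp in spec.components():
        dphi += k * comp.delta_n * comp.chord(x, y)
    if spec.background_poly is not None:
        height, width = config.field_of_view
        c = np.asarray(spec.background_poly, dtype=float)
        dphi += np.polynomial.polynomial.polyval2d(y / height, x / width, c)
    return PhaseMap(dphi, wrapped=False)


def synthesize_hologram(truth: PhaseMap, spec: PhantomSpec,
                        config: OpticalConfig) -> Interferogram:
    """Render the off-axis interferogram of a ground-truth phase field.

    Applies the carrier tilt, optional Poisson shot noise (``photon_scale``
    expected photons per intensity unit) and quantization to the camera's
    integer levels, clipped to ``[0, 2**bit_depth - 1]``.
    """
    if truth.wrapped:
        raise ValueError("truth phase must be unwrapped")
    if truth.values.shape != tuple(config.image_shape):
        raise ValueError("truth phase shape does not match config.image_shape")
    spec.validate(config)
    config.validate()

    x, y = config.pixel_coords()
    p_r = spec.amplitude_reference
    p_o = spec.amplitude_object
    carrier = config.tilt_alpha * x + config.tilt_beta * y
    intensity = p_r ** 2 + p_o ** 2 + 2 * p_r * p_o * np.cos(truth.values + carrier)

    if spec.noise.photon_scale > 0:
        rng = np.random.default_rng(spec.noise.seed)
        scale = spec.noise.photon_scale
        intensity = rng.poisson(intensity * scale).astype(float) / scale

    levels = np.clip(np.rint(intensity), 0, config.max_level)
    dtype = np.uint16 if config.bit_depth <= 16 else np.uint32
    return Interferogram(levels.astype(dtype), config)


def _ring_positions(n: int, ring_radius: float, rng: np.random.Generator,
                    cx: float, cy: float) -> list[tuple[float, float]]:
    phase0 = rng.uniform(0, 2 * np.pi)
    angles = phase0 + 2 * np.pi * np.arange(n) / n
    return [(cx + ring_radius * np.cos(a), cy + ring_radius * np.sin(a))
            for a in angles]


def make_embryo_series(stage: str, lipid_level: str, seed: int,
                       config: OpticalConfig | None = None,
                       embryo_radius: float | None = None,
                       zona_thickness: float | None = None,
                       high_lipid_factor: float = HIGH_LIPID_FACTOR,
                       photon_scale: float = 0.0) -> PhantomSpec:
    """Deterministic embryo-like phantom for a developmental stage.

    Same (stage, lipid_level, seed) always yields the same spec; the lipid
    level only rescales cytoplasm ``delta_n``, never the geometry.  When
    ``embryo_radius`` is omitted it defaults to 32.5% of the smaller field
    dimension (≈50 μm on the default 154 μm field) and the zona thickness
    to a tenth of that radius.
    """
    if stage not in EMBRYO_STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {EMBRYO_STAGES}")
    if lipid_level not in LIPID_LEVELS:
        raise ValueError(
            f"unknown lipid level {lipid_level!r}; choose from {LIPID_LEVELS}")
    config = config or OpticalConfig()

    rng = np.random.default_rng(seed)
    height, width = config.field_of_view
    if embryo_radius is None:
        embryo_radius = 0.325 * min(height, width)
    if zona_thickness is None:
        zona_thickness = 0.1 * embryo_radius
    cx, cy = width / 2.0, height / 2.0
    dn = CYTOPLASM_DELTA_N
    if lipid_level == "high":
        if high_lipid_factor <= 1:
            raise ValueError("high_lipid_factor must be > 1")
        dn *= high_lipid_factor

    outer = embryo_radius * rng.uniform(0.95, 1.05)
    inner = outer - zona_thickness
    shell = Shell(cx, cy, inner, outer, ZONA_DELTA_N)
    spheres: list[Sphere] = []
    cavity: Sphere | None = None

    if stage == "2cell":
        r = inner * 0.48
        for px, py in _ring_positions(2, inner - r, rng, cx, cy):
            spheres.append(Sphere(px, py, r, dn))
    elif stage in ("4cell", "8cell", "morula"):
        n = {"4cell": 4, "8cell": 8, "morula": 16}[stage]
        # pack n blastomeres: one or two rings plus, for dense stages, a centre
        if n == 4:
            r = inner * 0.40
            positions = _ring_positions(4, inner - r, rng, cx, cy)
        elif n == 8:
            r = inner * 0.33
            positions = _ring_positions(7, inner - r, rng, cx, cy)
            positions.append((cx, cy))
        else:
            r = inner * 0.28
            positions = _ring_positions(10, inner - r, rng, cx, cy)
            positions += _ring_positions(5, (inner - r) * 0.45, rng, cx, cy)
            positions.append((cx, cy))
        for px, py in positions:
            spheres.append(Sphere(px, py, r, dn))
    else:  # blastocyst: thin trophoblast-like layer around a fluid cavity
        cell_layer_outer = inner * 0.96
        cavity_radius = cell_layer_outer * 0.88
        spheres.append(Sphere(cx, cy, cell_layer_outer, dn))
        cavity = Sphere(cx, cy, cavity_radius, -dn)  # net excess 0 inside

    # gentle seeded background so every phantom exercises ring subtraction
    bg = np.zeros((2, 2))
    bg[0, 1] = rng.uniform(-0.05, 0.05)
    bg[1, 0] = rng.uniform(-0.05, 0.05)

    spec = PhantomSpec(spheres=spheres, shell=shell, cavity=cavity,
                       background_poly=bg,
                       noise=NoiseSpec(photon_scale=photon_scale, seed=seed))
    spec.validate(config)
    return spec
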