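"""File formats, run configuration and the batch pipeline driver.

Interferograms travel as 16-bit grayscale TIFF/PNG, intermediate phase and
RI fields as 32-bit float TIFF, configuration as YAML, tables as CSV and
summaries as JSON.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .demodulate import fourier_spectrum
from .optics import Interferogram, OpticalConfig, PhaseMap
from .pipeline import reconstruct_phase
from .ri import CircularROI, background_subtract, compute_ri

__all__ = [
    "RunConfig",
    "SpecimenRecord",
    "read_interferogram",
    "write_interferogram",
    "read_phase_tiff",
    "write_phase_tiff",
    "run_pipeline",
]

log = logging.getLogger("dhmkit")

_RUNCONFIG_KEYS = {
    "optics", "roi", "demodulation", "unwrap", "ri", "stats",
    "out_dir", "log_level",
}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration, YAML round-trippable.

    Unknown top-level keys are rejected so that typos never silently fall
    back to defaults.
    """

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    roi: CircularROI | None = None
    demodulation: dict = field(default_factory=lambda: {
        "dc_exclusion_radius": 8, "half_size": None, "taper": False})
    unwrap: dict = field(default_factory=dict)
    ri: dict = field(default_factory=lambda: {
        "h_min_frac": 0.1, "ring_width": 5.0})
    stats: dict = field(default_factory=lambda: {
        "alpha": 0.05, "seed": 0, "reps": 500})
    out_dir: str = "out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "optics": self.optics.to_dict(),
            "roi": None if self.roi is None else {
                "center_x": self.roi.center_x, "center_y": self.roi.center_y,
                "radius": self.roi.radius, "ring_width": self.roi.ring_width,
            },
            "demodulation": dict(self.demodulation),
            "unwrap": dict(self.unwrap),
            "ri": dict(self.ri),
            "stats": dict(self.stats),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"allowed keys are {sorted(_RUNCONFIG_KEYS)}")
        kwargs: dict = {}
        if "optics" in d:
            kwargs["optics"] = OpticalConfig.from_dict(d["optics"])
        if d.get("roi") is not None:
            kwargs["roi"] = CircularROI(**d["roi"])
        for key in ("demodulation", "unwrap", "ri", "stats",
                    "out_dir", "log_level"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class SpecimenRecord:
    """One specimen: identity, input hologram, ROI and derived summary."""

    id: str
    stage: str
    lipid: str
    hologram_path: str
    roi: CircularROI | None = None
    summary: dict | None = None
    provenance: dict = field(default_factory=dict)


def read_interferogram(path: str | Path, config: OpticalConfig,
                       allow_float: bool = False) -> Interferogram:
    """Load a grayscale interferogram losslessly.

    8-bit inputs are up-scaled to the configured bit depth with a warning;
    multi-channel and (unless ``allow_float``) floating-point images are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-plane grayscale image, got "
            f"shape {data.shape} (multi-channel input is not supported)")
    if np.issubdtype(data.dtype, np.floating):
        if not allow_float:
            raise ValueError(
                f"{path.name}: floating-point image; pass allow_float=True "
                "to accept")
    elif data.dtype == np.uint8 and config.bit_depth > 8:
        log.warning("%s: 8-bit input up-scaled to %d-bit range",
                    path.name, config.bit_depth)
        data = data.astype(np.uint16) * (config.max_level // 255)
    return Interferogram(data, config)


def write_interferogram(holo: Interferogram, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(holo.pixels))


def write_phase_tiff(phase: PhaseMap, path: str | Path) -> None:
    tifffile.imwrite(Path(path), phase.values.astype(np.float32))


def read_phase_tiff(path: str | Path, wrapped: bool) -> PhaseMap:
    return PhaseMap(tifffile.imread(Path(path)).astype(float), wrapped=wrapped)


def _save_spectrum_png(holo: Interferogram, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    spec = fourier_spectrum(holo)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.log1p(np.abs(spec.values)), cmap="magma")
    ax.set_title("log |spectrum|")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, specimens: list[SpecimenRecord],
                 out_dir: str | Path | None = None,
                 save_spectra: bool = False) -> dict:
    """Reconstruct every specimen and assemble cohort tables.

    Per specimen: wrapped + unwrapped phase TIFFs, RI map TIFF, summary row.
    Failures abort only the affected specimen and are collected in a
    failures table; cohort statistics run on the survivors.  All outputs are
    stamped with the resolved configuration hash.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(out / "resolved_config.yaml")

    rows, failures = [], []
    for rec in specimens:
        try:
            holo = read_interferogram(rec.hologram_path, config.optics)
            roi = rec.roi or config.roi
            if roi is None:
                raise ValueError(f"specimen {rec.id}: no ROI supplied")
            if save_spectra:
                _save_spectrum_png(holo, out / f"{rec.id}_spectrum.png")
            phase = reconstruct_phase(
                holo,
                dc_exclusion_radius=config.demodulation.get(
                    "dc_exclusion_radius", 8),
                taper=config.demodulation.get("taper", False))
            corrected = background_subtract(phase, roi, config.optics)
            rimap = compute_ri(corrected, roi, config.optics,
                               h_min_frac=config.ri.get("h_min_frac", 0.1))
            write_phase_tiff(phase, out / f"{rec.id}_phase.tif")
            tifffile.imwrite(out / f"{rec.id}_ri.tif",
                             rimap.values.astype(np.float32))
            rec.summary = {"mean_ri": rimap.summary["mean"],
                           "median_ri": rimap.summary["median"],
                           "n_valid": rimap.summary["n_valid"]}
            rec.provenance = {"config_hash": cfg_hash}
            rows.append({"id": rec.id, "stage": rec.stage, "lipid": rec.lipid,
                         **rec.summary, "config_hash": cfg_hash})
        except Exception as exc:  # noqa: BLE001 - per-specimen isolation
            log.error("specimen %s failed: %s", rec.id, exc)
            failures.append({"id": rec.id, "error": str(exc)})

    summary_df = pd.DataFrame(
        rows, columns=["id", "stage", "lipid", "mean_ri", "median_ri",
                       "n_valid", "config_hash"])
    failures_df = pd.DataFrame(failures, columns=["id", "error"])
    summary_df.to_csv(out / "specimens.csv", index=False)
    failures_df.to_csv(out / "failures.csv", index=False)

    group_df = (summary_df.groupby(["stage", "lipid"])["mean_ri"]
                .agg(["count", "mean", "std"]).reset_index()
                if len(summary_df) else
                pd.DataFrame(columns=["stage", "lipid", "count", "mean", "std"]))
    group_df.to_csv(out / "groups.csv", index=False)
    return {"specimens": summary_df, "failures": failures_df,
            "groups": group_df, "config_hash": cfg_hash}
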