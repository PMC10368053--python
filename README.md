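# dhmkit

Off-axis digital holographic microscopy at the desk: simulate interferograms
of near-spherical multi-compartment phase phantoms (embryo-like specimens),
recover the object phase by Fourier sideband demodulation and
reliability-sorted 2D unwrapping, and invert it to per-pixel effective
refractive-index (RI) maps with the hemispherical chord model — plus the
group statistics and sensitivity analyses that go with such an experiment.

No laboratory data is required: the simulator provides seeded ground truth
for every downstream stage.

## Pipeline

1. **simulate** (`dhmkit.simulate`) — renders ground-truth phase fields for
   phantoms built from cytoplasm spheres, an optional zona-like shell and an
   optional fluid cavity, then forms the off-axis interferogram
   `I = P_R² + P_O² + 2·P_R·P_O·cos(Δϕ + αx + βy)` with optional Poisson
   shot noise and camera quantization.
2. **demodulate** (`dhmkit.demodulate`) — centred DFT, carrier sidelobe
   location in the upper half-plane, rectangular crop, re-centering, inverse
   DFT; yields the wrapped phase and amplitude.
3. **unwrap** (`dhmkit.unwrap`) — noncontinuous-path unwrapping: pixels
   scored by wrapped second differences, 4-connected edges merged in order
   of decreasing reliability (numba-accelerated union loop).
4. **ri** (`dhmkit.ri`) — annular ring background subtraction, then
   `n_s = Δϕ/(k·h) + n_m` with chord `h = 2√(R² − r²)` over a circular ROI,
   with a rim guard and plausibility mask; histogram/mode summaries.
5. **stats** (`dhmkit.stats`) — normality-gated two-group comparison
   (Shapiro-Wilk → t-test or Mann-Whitney U), one-way ANOVA + Tukey HSD with
   compact letters, radius/background sensitivity tables, and the
   energy-density dosimetry helper.

## CLI

```bash
# synthesize a phantom hologram (16-bit TIFF) + ground truth (float TIFF)
dhmkit simulate --stage morula --lipid high --seed 3 --out-dir out/

# demodulate + unwrap + RI map inside a circular ROI (xc,yc,R in μm)
dhmkit reconstruct out/morula_high_seed3_holo.tif \
    --roi 76.8,76.8,50.0 --save-spectrum --out-dir out/

# group statistics on a per-specimen summary table (id,stage,lipid,mean_ri)
dhmkit analyze out/specimens.csv --out-dir out/stats/

# radius ±15% and 0.2-rad background sensitivity on the standard phantom
dhmkit sensitivity --out-dir out/
```

All lengths in configs and ROIs are micrometres; phases are radians.
Configuration is YAML (`RunConfig`); unknown keys are rejected and every run
writes back the fully resolved config plus its hash.

## Layout

```
src/dhmkit/
  optics.py      OpticalConfig, Interferogram, PhaseMap
  simulate.py    phantoms, forward interferogram model, embryo series
  demodulate.py  spectrum, sidelobe window, demodulation
  unwrap.py      reliability map, reliability-sorted unwrapping
  ri.py          ROI, ring subtraction, RI inversion, histograms
  stats.py       group tests, sensitivity ops, dosimetry
  pipeline.py    reconstruct_phase / reconstruct_ri composition
  io.py          TIFF/YAML/CSV formats, RunConfig, batch driver
  cli.py         simulate / reconstruct / analyze / sensitivity
tests/           unit + property + acceptance suites (pytest, hypothesis)
scripts/
  acceptance.py  headline-number report (JSON)
```
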