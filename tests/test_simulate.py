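import math

import numpy as np
import pytest

import dhmkit as dk
from dhmkit.simulate import EMBRYO_STAGES

from conftest import make_config


def chord_by_line_integral(radius, delta_n, r, n_steps=200_001):
    """Independent oracle: integrate the RI excess along the optical axis
    through a sphere on a fine z-grid (trapezoid rule)."""
    z = np.linspace(-radius, radius, n_steps)
    inside = (z ** 2 + r ** 2) < radius ** 2
    return np.trapezoid(np.where(inside, delta_n, 0.0), z)


class TestPhantomPhase:
    def test_empty_phantom_is_zero(self, fast_config):
        truth = dk.phantom_phase(dk.PhantomSpec(), fast_config)
        assert not truth.wrapped
        assert np.all(truth.values == 0.0)

    def test_centre_pixel_matches_line_integral_oracle(self):
        # sphere centred exactly on a pixel centre so r = 0 there
        cfg = make_config(256)
        cx = cy = (128 + 0.5) * cfg.pixel_pitch
        R, dn = 25.0, 0.005
        spec = dk.PhantomSpec(spheres=[dk.Sphere(cx, cy, R, dn)])
        truth = dk.phantom_phase(spec, cfg)
        got = truth.values[128, 128]
        # closed form 2*k*R*delta_n
        assert got == pytest.approx(2 * cfg.wavenumber * R * dn, rel=1e-12)
        # independent numerical line integral
        oracle = cfg.wavenumber * chord_by_line_integral(R, dn, 0.0)
        assert got == pytest.approx(oracle, rel=2e-5)

    def test_off_centre_pixel_matches_line_integral_oracle(self):
        cfg = make_config(256)
        cx = cy = (128 + 0.5) * cfg.pixel_pitch
        R, dn = 25.0, 0.005
        spec = dk.PhantomSpec(spheres=[dk.Sphere(cx, cy, R, dn)])
        truth = dk.phantom_phase(spec, cfg)
        # pixel 40 columns to the right: r = 40 * pitch
        r = 40 * cfg.pixel_pitch
        oracle = cfg.wavenumber * chord_by_line_integral(R, dn, r)
        assert truth.values[128, 168] == pytest.approx(oracle, rel=2e-5)

    def test_degenerate_shell_contributes_nothing(self, fast_config):
        h, w = fast_config.field_of_view
        spec = dk.PhantomSpec(
            shell=dk.Shell(w / 2, h / 2, 20.0, 20.0, 0.003))
        truth = dk.phantom_phase(spec, fast_config)
        assert np.all(truth.values == 0.0)

    def test_shell_is_outer_minus_inner(self, fast_config):
        h, w = fast_config.field_of_view
        shell = dk.PhantomSpec(
            shell=dk.Shell(w / 2, h / 2, 15.0, 25.0, 0.003))
        outer = dk.PhantomSpec(spheres=[dk.Sphere(w / 2, h / 2, 25.0, 0.003)])
        inner = dk.PhantomSpec(spheres=[dk.Sphere(w / 2, h / 2, 15.0, 0.003)])
        got = dk.phantom_phase(shell, fast_config).values
        expected = (dk.phantom_phase(outer, fast_config).values
                    - dk.phantom_phase(inner, fast_config).values)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_additivity_of_components(self, fast_config):
        h, w = fast_config.field_of_view
        a = dk.Sphere(w / 2 - 8, h / 2, 12.0, 0.004)
        b = dk.Sphere(w / 2 + 8, h / 2, 10.0, 0.002)
        both = dk.phantom_phase(dk.PhantomSpec(spheres=[a, b]), fast_config)
        only_a = dk.phantom_phase(dk.PhantomSpec(spheres=[a]), fast_config)
        only_b = dk.phantom_phase(dk.PhantomSpec(spheres=[b]), fast_config)
        np.testing.assert_allclose(both.values,
                                   only_a.values + only_b.values, atol=1e-12)

    def test_background_poly_added_once(self, fast_config):
        h, w = fast_config.field_of_view
        bg = np.array([[0.3, 0.1], [0.2, 0.0]])
        spec = dk.PhantomSpec(spheres=[dk.Sphere(w / 2, h / 2, 10.0, 0.004)],
                              background_poly=bg)
        no_bg = dk.PhantomSpec(spheres=[dk.Sphere(w / 2, h / 2, 10.0, 0.004)])
        bg_only = dk.PhantomSpec(background_poly=bg)
        np.testing.assert_allclose(
            dk.phantom_phase(spec, fast_config).values,
            dk.phantom_phase(no_bg, fast_config).values
            + dk.phantom_phase(bg_only, fast_config).values,
            atol=1e-12)

    def test_geometry_must_fit_field_of_view(self, fast_config):
        spec = dk.PhantomSpec(spheres=[dk.Sphere(5.0, 5.0, 30.0, 0.004)])
        with pytest.raises(ValueError, match="field of view"):
            dk.phantom_phase(spec, fast_config)


class TestSynthesizeHologram:
    def test_flat_object_gives_pure_carrier(self, fast_config):
        spec = dk.PhantomSpec()
        truth = dk.phantom_phase(spec, fast_config)
        holo = dk.synthesize_hologram(truth, spec, fast_config)
        p_r, p_o = spec.amplitude_reference, spec.amplitude_object
        # mean of the cosine over many fringe periods is ~0
        assert float(holo.pixels.mean()) == pytest.approx(
            p_r ** 2 + p_o ** 2, rel=1e-3)

    def test_fringe_contrast(self, fast_config):
        spec = dk.PhantomSpec(amplitude_reference=100.0, amplitude_object=50.0)
        truth = dk.phantom_phase(spec, fast_config)
        holo = dk.synthesize_hologram(truth, spec, fast_config)
        i_max, i_min = float(holo.pixels.max()), float(holo.pixels.min())
        contrast = (i_max - i_min) / (i_max + i_min)
        p_r, p_o = 100.0, 50.0
        expected = 2 * p_r * p_o / (p_r ** 2 + p_o ** 2)
        assert contrast == pytest.approx(expected, rel=1e-3)

    def test_intensity_bounds_after_quantization(self, fast_config):
        spec = dk.PhantomSpec(noise=dk.NoiseSpec(photon_scale=0.05, seed=3))
        truth = dk.phantom_phase(spec, fast_config)
        holo = dk.synthesize_hologram(truth, spec, fast_config)
        assert holo.pixels.min() >= 0
        assert holo.pixels.max() <= fast_config.max_level
        assert np.issubdtype(holo.pixels.dtype, np.integer)

    def test_noiseless_spectrum_has_dc_and_two_conjugate_sidelobes(
            self, fast_config, sphere_phantom):
        spec, _ = sphere_phantom
        truth = dk.phantom_phase(spec, fast_config)
        holo = dk.synthesize_hologram(truth, spec, fast_config)
        mag = np.abs(dk.fourier_spectrum(holo).values)
        n = fast_config.image_shape[0]
        dc = (n // 2, n // 2)
        # expected sidelobe offset in bins: f [rad/μm] * n * pitch / 2π
        db = round(fast_config.tilt_beta * n * fast_config.pixel_pitch
                   / (2 * math.pi))
        da = round(fast_config.tilt_alpha * n * fast_config.pixel_pitch
                   / (2 * math.pi))
        peaks = {dc, (dc[0] + db, dc[1] + da), (dc[0] - db, dc[1] - da)}
        # the three tallest spectral bins are exactly DC and ±carrier
        flat = np.argsort(mag.ravel())[::-1][:3]
        found = {tuple(np.unravel_index(i, mag.shape)) for i in flat}
        assert found == peaks

    def test_rejects_bad_amplitudes(self, fast_config):
        spec = dk.PhantomSpec(amplitude_reference=0.0)
        truth = dk.phantom_phase(dk.PhantomSpec(), fast_config)
        with pytest.raises(ValueError):
            dk.synthesize_hologram(truth, spec, fast_config)

    def test_rejects_wrapped_truth(self, fast_config):
        wrapped = dk.PhaseMap(np.zeros(fast_config.image_shape), wrapped=True)
        with pytest.raises(ValueError, match="unwrapped"):
            dk.synthesize_hologram(wrapped, dk.PhantomSpec(), fast_config)

    def test_seeded_noise_is_bit_reproducible(self, fast_config):
        spec = dk.PhantomSpec(noise=dk.NoiseSpec(photon_scale=0.1, seed=11))
        truth = dk.phantom_phase(spec, fast_config)
        h1 = dk.synthesize_hologram(truth, spec, fast_config)
        h2 = dk.synthesize_hologram(truth, spec, fast_config)
        np.testing.assert_array_equal(h1.pixels, h2.pixels)


class TestMakeEmbryoSeries:
    @pytest.mark.parametrize("stage", EMBRYO_STAGES)
    def test_deterministic(self, stage, fast_config):
        a = dk.make_embryo_series(stage, "low", 7, fast_config,
                                  embryo_radius=30.0)
        b = dk.make_embryo_series(stage, "low", 7, fast_config,
                                  embryo_radius=30.0)
        assert a.to_dict() == b.to_dict()

    def test_unknown_stage_rejected(self, fast_config):
        with pytest.raises(ValueError, match="unknown stage"):
            dk.make_embryo_series("16cell", "low", 0, fast_config)
        with pytest.raises(ValueError, match="lipid"):
            dk.make_embryo_series("morula", "medium", 0, fast_config)

    def test_high_lipid_same_geometry_larger_delta_n(self, fast_config):
        lo = dk.make_embryo_series("8cell", "low", 5, fast_config,
                                   embryo_radius=30.0)
        hi = dk.make_embryo_series("8cell", "high", 5, fast_config,
                                   embryo_radius=30.0)
        assert len(lo.spheres) == len(hi.spheres)
        for s_lo, s_hi in zip(lo.spheres, hi.spheres):
            assert (s_lo.center_x, s_lo.center_y, s_lo.radius) == \
                   (s_hi.center_x, s_hi.center_y, s_hi.radius)
            assert s_hi.delta_n > s_lo.delta_n
        assert lo.shell == hi.shell
        np.testing.assert_array_equal(lo.background_poly, hi.background_poly)

    def test_stage_cell_counts(self, fast_config):
        assert len(dk.make_embryo_series("2cell", "low", 0, fast_config,
                                         embryo_radius=30.0).spheres) == 2
        assert len(dk.make_embryo_series("4cell", "low", 0, fast_config,
                                         embryo_radius=30.0).spheres) == 4
        assert len(dk.make_embryo_series("8cell", "low", 0, fast_config,
                                         embryo_radius=30.0).spheres) == 8
        assert len(dk.make_embryo_series("morula", "low", 0, fast_config,
                                         embryo_radius=30.0).spheres) == 16
        blast = dk.make_embryo_series("blastocyst", "low", 0, fast_config,
                                      embryo_radius=30.0)
        assert blast.cavity is not None
        assert blast.cavity.delta_n < 0  # fluid cavity cancels cytoplasm

    def test_blastocyst_mean_ri_below_morula(self, fast_config):
        # cavity-dominated phantom depresses the effective index
        means = {}
        for stage in ("morula", "blastocyst"):
            spec = dk.make_embryo_series(stage, "low", 2, fast_config,
                                         embryo_radius=30.0)
            truth = dk.phantom_phase(spec, fast_config)
            roi = dk.CircularROI(spec.shell.center_x, spec.shell.center_y,
                                 spec.shell.outer_radius)
            corrected = dk.background_subtract(truth, roi, fast_config)
            means[stage] = dk.compute_ri(
                corrected, roi, fast_config).summary["mean"]
        assert means["blastocyst"] < means["morula"]

    def test_phantom_yaml_round_trip(self, tmp_path, fast_config):
        spec = dk.make_embryo_series("blastocyst", "high", 3, fast_config,
                                     embryo_radius=30.0)
        path = tmp_path / "phantom.yaml"
        spec.to_yaml(path)
        again = dk.PhantomSpec.from_yaml(path)
        assert again.to_dict() == spec.to_dict()
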