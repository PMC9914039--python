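import dataclasses

import numpy as np
import pytest

from cbctiq import (
    InsertDef,
    InsertSpec,
    NoiseModel,
    PhantomConfig,
    compute_nps,
    default_inserts,
    default_roi_layout,
    generate_insert_module,
    generate_uniform_module,
    measure_contrast,
    refine_center,
    synthesize_noise_field,
)


class TestNoiseSynthesis:
    def test_flat_spectrum_reaches_target_sigma(self):
        model = NoiseModel(target_sigma_hu=10.0, family="flat")
        field = synthesize_noise_field((512, 512), 0.55, model, seed=3)
        assert abs(field.std() / 10.0 - 1.0) < 0.02

    def test_zero_sigma_gives_zero_field(self):
        model = NoiseModel(target_sigma_hu=0.0, family="fbp")
        field = synthesize_noise_field((64, 64), 0.55, model, seed=0)
        assert np.all(field == 0)

    def test_degenerate_all_zero_shape_raises(self):
        # a 1x1 grid only carries the DC frequency, where band-pass shapes vanish
        model = NoiseModel(target_sigma_hu=5.0, family="fbp")
        with pytest.raises(ValueError, match="degenerate"):
            synthesize_noise_field((1, 1), 0.55, model, seed=0)

    def test_same_seed_reproduces_field(self):
        model = NoiseModel(target_sigma_hu=20.0, family="ir", peak_frequency_mm=0.2)
        a = synthesize_noise_field((128, 128), 0.55, model, seed=9)
        b = synthesize_noise_field((128, 128), 0.55, model, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("family,peak", [("fbp", 0.29), ("ir", 0.20)])
    def test_nps_round_trip_recovers_prescription(self, family, peak):
        """Empirical NPS of >=40 synthetic slices matches the prescribed
        magnitude within 5% and peak within one radial bin."""
        cfg = PhantomConfig(
            matrix_size=320,
            n_slices=40,
            noise_model=NoiseModel(30.0, family, peak),
            seed=5,
        )
        stack = generate_uniform_module(cfg)
        res = compute_nps(stack, default_roi_layout(stack, 82))
        assert abs(res.noise_magnitude_hu / 30.0 - 1.0) < 0.05
        one_bin = res.radial_freq[1] - res.radial_freq[0]
        assert len(res.peak_freqs_mm) == 1
        assert abs(res.peak_freqs_mm[0] - peak) <= one_bin


class TestUniformModule:
    def test_noiseless_flat_module_equals_background(self):
        cfg = PhantomConfig(matrix_size=128, n_slices=3, background_hu=12.0)
        stack = generate_uniform_module(cfg)
        assert np.all(stack.voxels == 12.0)

    def test_cupping_center_minus_edge_equals_amplitude(self):
        cfg = PhantomConfig(matrix_size=320, pixel_spacing_mm=0.7, n_slices=1,
                            cupping_amplitude_hu=30.0)
        stack = generate_uniform_module(cfg)
        img = stack.voxels[0]
        c = 159  # (matrix-1)/2 rounded
        center = img[c - 2 : c + 3, c - 2 : c + 3].mean()
        edge_px = int(100.0 / cfg.pixel_spacing_mm)  # phantom disk edge
        edge = img[c, c + edge_px - 1]
        assert center - edge == pytest.approx(30.0, abs=0.5)

    def test_same_seed_identical_stacks(self, head_fbp_config):
        a = generate_uniform_module(head_fbp_config)
        b = generate_uniform_module(head_fbp_config)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_cupping_produces_low_frequency_nps_peak(self):
        """A strong bowl leaves a residual below 0.05 mm^-1 after per-ROI
        detrending, reported ahead of the band-pass texture peak."""
        cfg = PhantomConfig(
            matrix_size=320,
            pixel_spacing_mm=0.96,
            n_slices=40,
            cupping_amplitude_hu=120.0,
            noise_model=NoiseModel(10.6, "fbp", 0.22),
            seed=2,
        )
        stack = generate_uniform_module(cfg)
        res = compute_nps(stack, default_roi_layout(stack, 46))
        assert len(res.peak_freqs_mm) == 2
        assert res.peak_freqs_mm[0] < 0.05
        assert abs(res.peak_freqs_mm[1] - 0.22) < 0.025


class TestInsertModule:
    def test_interior_value_is_background_plus_contrast(self):
        ins = InsertDef("air", (0.0, 30.0), 12.2, -1000.0)
        cfg = PhantomConfig(matrix_size=256, n_slices=1, background_hu=0.0,
                            insert_specs=(ins,))
        stack = generate_insert_module(cfg)
        row, col = stack.meta["inserts"][0]["center_px"]
        assert stack.voxels[0, int(row), int(col)] == pytest.approx(-1000.0)

    def test_contrast_linearity_under_scaling(self):
        """Scaling all prescribed contrasts by k scales measured contrasts
        by k (noise off)."""
        base = default_inserts()
        scaled = [dataclasses.replace(i, contrast_hu=2.5 * i.contrast_hu) for i in base]
        meas = {}
        for tag, inserts in [("base", base), ("scaled", scaled)]:
            cfg = PhantomConfig(matrix_size=320, n_slices=1, insert_specs=tuple(inserts),
                                psf_sigma_mm=0.4)
            stack = generate_insert_module(cfg)
            for d in stack.meta["inserts"]:
                spec = InsertSpec(d["name"], tuple(d["center_px"]), d["diameter_mm"])
                center = refine_center(stack, spec)
                meas[(tag, d["name"])] = measure_contrast(stack, spec, center)
        for name in ("air", "ldpe", "delrin", "teflon"):
            assert meas[("scaled", name)] == pytest.approx(2.5 * meas[("base", name)], rel=1e-3)

    def test_nominal_contrasts_recovered_within_2pct(self):
        """Parameter recovery: the four nominal insert contrasts measured to
        within +/-2% under modest noise, slices averaged."""
        cfg = PhantomConfig(matrix_size=320, n_slices=40,
                            insert_specs=tuple(default_inserts()),
                            psf_sigma_mm=0.45,
                            noise_model=NoiseModel(5.0, "fbp", 0.29), seed=3)
        stack = generate_insert_module(cfg)
        for d in stack.meta["inserts"]:
            spec = InsertSpec(d["name"], tuple(d["center_px"]), d["diameter_mm"])
            center = refine_center(stack, spec)
            c = measure_contrast(stack, spec, center)
            assert c == pytest.approx(d["contrast_hu"], rel=0.02)

    def test_overlapping_inserts_raise(self):
        a = InsertDef("a", (0.0, 0.0), 12.2, 100.0)
        b = InsertDef("b", (0.0, 10.0), 12.2, 100.0)
        cfg_kwargs = dict(matrix_size=256, n_slices=1)
        with pytest.raises(ValueError, match="overlap"):
            generate_insert_module(PhantomConfig(insert_specs=(a, b), **cfg_kwargs))

    def test_insert_outside_field_raises(self):
        far = InsertDef("far", (0.0, 200.0), 12.2, 100.0)
        with pytest.raises(ValueError, match="fit"):
            PhantomConfig(matrix_size=256, insert_specs=(far,))

    def test_empty_insert_list_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_insert_module(PhantomConfig(matrix_size=128, n_slices=1))
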