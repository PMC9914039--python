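import dataclasses

import numpy as np
import pytest
from scipy.signal import fftconvolve

from cbctiq import (
    ImageStack,
    InsertDef,
    NoiseModel,
    PhantomConfig,
    compute_esf,
    compute_ttf,
    esf_to_lsf,
    generate_insert_module,
    lsf_to_ttf,
    measure_contrast,
    refine_center,
)
from cbctiq.ttf import Curve, InsertNotFoundError, InsertSpec


def _single_insert_stack(center_offset_mm=(0.0, 20.0), contrast=-1000.0,
                         psf_sigma_mm=0.0, noise_sigma=0.0, n_slices=1,
                         matrix=192, spacing=0.55, seed=0):
    ins = InsertDef("probe", center_offset_mm, 12.2, contrast)
    model = NoiseModel(noise_sigma, "flat") if noise_sigma > 0 else None
    cfg = PhantomConfig(matrix_size=matrix, pixel_spacing_mm=spacing,
                        n_slices=n_slices, insert_specs=(ins,),
                        psf_sigma_mm=psf_sigma_mm, noise_model=model, seed=seed)
    stack = generate_insert_module(cfg)
    d = stack.meta["inserts"][0]
    return stack, InsertSpec("probe", tuple(d["center_px"]), 12.2), tuple(d["center_px"])


def _binary_disk_stack(radius_mm=6.1, spacing=0.55, matrix=192, contrast=400.0):
    """Sharp (non-anti-aliased) disk: pixel centers strictly inside get the
    full contrast."""
    c = (matrix - 1) / 2.0
    rows = (np.arange(matrix)[:, None] - c) * spacing
    cols = (np.arange(matrix)[None, :] - c) * spacing
    r = np.hypot(rows, cols)
    img = np.where(r < radius_mm, contrast, 0.0)
    stack = ImageStack(img[None], (spacing, spacing), 1.991)
    return stack, InsertSpec("disk", (c, c), 2 * radius_mm), (c, c)


def _gaussian_f50(sigma_mm):
    return np.sqrt(np.log(2.0) / 2.0) / (np.pi * sigma_mm)


class TestRefineCenter:
    @pytest.mark.parametrize("offset_mm", [(0.0, 20.0), (0.275, 20.275)])
    def test_center_recovered_within_tenth_pixel(self, offset_mm):
        # the second offset puts the true center on a half-pixel position
        stack, spec, truth = _single_insert_stack(
            center_offset_mm=offset_mm, psf_sigma_mm=0.4, noise_sigma=3.0, n_slices=10
        )
        approx = (truth[0] + 0.8, truth[1] - 0.8)  # start from a wrong guess
        found = refine_center(stack, dataclasses.replace(spec, approx_center_px=approx))
        assert np.hypot(found[0] - truth[0], found[1] - truth[1]) < 0.1

    def test_uniform_image_raises_insert_not_found(self):
        stack = ImageStack(np.zeros((2, 192, 192)), (0.55, 0.55), 1.991)
        spec = InsertSpec("ghost", (95.5, 95.5), 12.2)
        with pytest.raises(InsertNotFoundError):
            refine_center(stack, spec)


class TestContrast:
    def test_noiseless_contrast_exact(self):
        stack, spec, center = _single_insert_stack(contrast=-1000.0)
        assert measure_contrast(stack, spec, center) == pytest.approx(-1000.0, abs=1e-9)

    def test_noisy_contrast_recovered_within_2hu(self):
        stack, spec, center = _single_insert_stack(
            contrast=793.0, psf_sigma_mm=0.4, noise_sigma=5.0, n_slices=40, seed=4
        )
        c = measure_contrast(stack, spec, center)
        assert c == pytest.approx(793.0, abs=2.0)

    def test_annulus_outside_image_raises(self):
        stack, spec, center = _single_insert_stack()
        wide = dataclasses.replace(spec, background_annulus_mm=(20.0, 70.0))
        with pytest.raises(ValueError, match="outside"):
            measure_contrast(stack, wide, center)


class TestEsf:
    def test_sharp_disk_esf_is_a_step(self):
        stack, spec, center = _binary_disk_stack()
        esf = compute_esf(stack, spec, center)
        bw = esf.x[1] - esf.x[0]
        # transition confined to <= 2 bins around the disk radius
        lo = esf.x < 6.1 - 2 * bw
        hi = esf.x > 6.1 + 2 * bw
        assert np.all(np.abs(esf.y[lo] - 400.0) < 1e-9)
        assert np.all(np.abs(esf.y[hi]) < 1e-9)

    def test_blurred_esf_matches_numerical_convolution_oracle(self):
        sigma = 0.5
        stack, spec, center = _single_insert_stack(contrast=1000.0, psf_sigma_mm=sigma)
        esf = compute_esf(stack, spec, center)
        # independent oracle: continuous disk rasterized on a 0.05 mm grid,
        # convolved with the Gaussian PSF, radially averaged
        fine = 0.05
        n = 512
        c = (n - 1) / 2.0
        rows = (np.arange(n)[:, None] - c) * fine
        cols = (np.arange(n)[None, :] - c) * fine
        r = np.hypot(rows, cols)
        disk = np.where(r < 6.1, 1000.0, 0.0)
        ax = (np.arange(n) - c) * fine
        g1 = np.exp(-0.5 * (ax / sigma) ** 2)
        g2 = np.outer(g1, g1)
        g2 /= g2.sum()
        blurred = fftconvolve(disk, g2, mode="same")
        oracle = np.interp(esf.x, *_radial_mean(r, blurred))
        mask = esf.x < 11.0  # clear of the fine-grid boundary
        assert np.max(np.abs(esf.y[mask] - oracle[mask])) < 0.01 * 1000.0

    def test_doubling_slices_halves_esf_noise_variance(self):
        truth_stack, spec, center = _single_insert_stack(contrast=500.0, psf_sigma_mm=0.5)
        truth = compute_esf(truth_stack, spec, center)
        errs = {}
        for n_slices in (10, 20):
            stack, spec_n, center_n = _single_insert_stack(
                contrast=500.0, psf_sigma_mm=0.5, noise_sigma=20.0,
                n_slices=n_slices, seed=11,
            )
            esf = compute_esf(stack, spec_n, center_n)
            errs[n_slices] = np.var(esf.y - truth.y)
        ratio = errs[10] / errs[20]
        assert 1.4 < ratio < 2.9

    def test_too_few_bins_raises(self):
        stack, spec, center = _binary_disk_stack()
        with pytest.raises(ValueError, match="10 populated"):
            compute_esf(stack, spec, center, bin_width_mm=3.0)


def _radial_mean(r, img, bw=0.05):
    idx = (r / bw).astype(int)
    n = idx.max() + 1
    s = np.bincount(idx.ravel(), weights=img.ravel(), minlength=n)
    c = np.bincount(idx.ravel(), minlength=n)
    return (np.arange(n) + 0.5) * bw, s / np.maximum(c, 1)


class TestLsf:
    def test_erf_esf_gives_gaussian_lsf(self):
        from scipy.special import erf

        sigma = 0.5
        x = np.arange(0.025, 12.0, 0.05)
        esf = Curve(x=x, y=0.5 * (1.0 - erf((x - 6.1) / (sigma * np.sqrt(2)))))
        lsf = esf_to_lsf(esf)
        expected = np.exp(-0.5 * ((x - 6.1) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        mask = np.abs(x - 6.1) < 2 * sigma  # inside the window plateau
        assert np.max(np.abs(lsf.y[mask] - expected[mask])) < 0.02 * expected.max()

    def test_step_esf_gives_single_bin_impulse(self):
        x = np.arange(0.05, 10.0, 0.1)
        esf = Curve(x=x, y=np.where(x < 5.0, 1.0, 0.0))
        lsf = esf_to_lsf(esf)
        assert (np.abs(lsf.y) > 1e-12).sum() <= 2  # central difference support

    def test_negative_contrast_yields_positive_lobe(self):
        stack, spec, center = _single_insert_stack(contrast=-1000.0, psf_sigma_mm=0.5)
        lsf = esf_to_lsf(compute_esf(stack, spec, center))
        assert lsf.y.max() > 0
        assert lsf.y[np.argmax(np.abs(lsf.y))] > 0

    def test_flat_esf_raises(self):
        with pytest.raises(ValueError, match="no edge"):
            esf_to_lsf(Curve(x=np.arange(0.5, 10.0, 0.5), y=np.ones(19)))


class TestTtf:
    @pytest.mark.parametrize("sigma", [0.3, 0.5, 1.0])
    def test_gaussian_blur_recovers_closed_form_ttf(self, sigma):
        """Circular-edge TTF of a Gaussian-blurred insert matches
        exp(-2 pi^2 sigma^2 f^2) within 3% up to f50, and f50 within 3%."""
        stack, spec, center = _single_insert_stack(contrast=1000.0, psf_sigma_mm=sigma)
        res = compute_ttf(stack, spec)
        truth50 = _gaussian_f50(sigma)
        assert res.f50_mm == pytest.approx(truth50, rel=0.03)
        mask = res.ttf.x <= truth50
        expected = np.exp(-2 * np.pi**2 * sigma**2 * res.ttf.x[mask] ** 2)
        assert np.max(np.abs(res.ttf.y[mask] - expected)) < 0.03

    def test_f50_scales_inversely_with_blur(self):
        f50 = {}
        for sigma in (0.3, 0.5, 1.0):
            stack, spec, center = _single_insert_stack(contrast=500.0, psf_sigma_mm=sigma)
            f50[sigma] = compute_ttf(stack, spec).f50_mm
        assert f50[0.5] * 0.5 == pytest.approx(f50[1.0] * 1.0, rel=0.05)
        assert f50[0.3] * 0.3 == pytest.approx(f50[1.0] * 1.0, rel=0.05)

    def test_impulse_lsf_gives_unity_ttf_without_f50(self):
        x = np.arange(0.05, 10.0, 0.1)
        y = np.zeros_like(x)
        y[50] = 1.0
        with pytest.warns(UserWarning, match="f50"):
            curve, f50 = lsf_to_ttf(Curve(x=x, y=y))
        assert f50 is None
        assert np.all(curve.y > 0.9)

    def test_ttf_invariant_to_contrast_sign_and_magnitude(self):
        f50 = {}
        for contrast in (-1000.0, 235.0):
            stack, spec, center = _single_insert_stack(contrast=contrast, psf_sigma_mm=0.5)
            f50[contrast] = compute_ttf(stack, spec).f50_mm
        assert f50[-1000.0] == pytest.approx(f50[235.0], rel=0.01)

    def test_pooling_40_vs_8_slices_stays_within_noise_spread(self):
        """More slices must not shift f50 beyond the repeat-to-repeat spread."""
        truth = _gaussian_f50(0.5)
        f50_8 = []
        for seed in range(4):
            stack, spec, center = _single_insert_stack(
                contrast=235.0, psf_sigma_mm=0.5, noise_sigma=10.0, n_slices=8, seed=seed
            )
            f50_8.append(compute_ttf(stack, spec).f50_mm)
        stack, spec, center = _single_insert_stack(
            contrast=235.0, psf_sigma_mm=0.5, noise_sigma=10.0, n_slices=40, seed=99
        )
        f50_40 = compute_ttf(stack, spec).f50_mm
        spread = max(np.std(f50_8, ddof=1), 0.002)
        assert abs(f50_40 - np.mean(f50_8)) < 3 * spread
        assert f50_40 == pytest.approx(truth, rel=0.05)
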