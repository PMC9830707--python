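import math
import numpy as np
import pytest
from scipy import ndimage as ndi

from collafiber.image_io import IntensityImage
from collafiber import segmentation as seg


def _img(pixels, px_um=0.5):
    return IntensityImage(pixels=np.asarray(pixels, float), pixel_size_um=px_um)


def _bar_image(shape=(64, 128), row=32, half=2, amp=1.0):
    px = np.zeros(shape)
    px[row - half : row + half, :] = amp
    return px


class TestFrangiEnhance:
    def test_constant_image_zero_response(self):
        enh = seg.frangi_enhance(_img(np.full((32, 32), 0.5)))
        assert np.all(enh.pixels == 0)

    def test_bar_centerline_dominates_background(self):
        enh = seg.frangi_enhance(_img(_bar_image()))
        on_bar = enh.pixels[31:33, 20:108].mean()
        far = enh.pixels[:18, 20:108].mean()
        assert on_bar > 5 * max(far, 1e-12)

    def test_blob_suppressed_relative_to_bar(self):
        shape = (64, 128)
        rr, cc = np.mgrid[:64, :128]
        spot = np.exp(-((rr - 32) ** 2 + (cc - 64) ** 2) / (2 * 4.0**2))
        bar = _bar_image(shape, amp=1.0)
        peak_spot = seg.frangi_enhance(_img(spot)).pixels.max()
        peak_bar = seg.frangi_enhance(_img(bar)).pixels.max()
        assert peak_spot < peak_bar

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        base = 0.3 * rng.uniform(size=(48, 48))
        a = seg.frangi_enhance(_img(base))
        b = seg.frangi_enhance(_img(base + 0.2))
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-10)

    def test_rotation_equivariance_90deg(self):
        img = _bar_image()
        a = seg.frangi_enhance(_img(img)).pixels
        b = seg.frangi_enhance(_img(np.rot90(img).copy())).pixels
        np.testing.assert_allclose(np.rot90(a), b, atol=1e-7)

    def test_empty_scales_rejected(self):
        with pytest.raises(ValueError):
            seg.frangi_enhance(_img(np.zeros((8, 8))), scales=[])

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            seg.frangi_enhance(_img(np.full((8, 8), 9.0)))

    def test_matches_numeric_hessian_oracle(self):
        """Independent oracle: evaluate the vesselness formula at sampled
        interior pixels from a hand-built Gaussian-smoothed numeric Hessian
        (np.gradient + np.linalg.eigvalsh), with sigma^2 normalization."""
        rng = np.random.default_rng(9)
        img = np.clip(_bar_image() * 0.9 + 0.05 * rng.uniform(size=(64, 128)),
                      0, 1)
        sigmas = (1.0, 2.0, 3.0)
        beta, c = 0.5, 0.08
        ours = seg.frangi_enhance(_img(img), scales=sigmas, beta=beta, c=c)

        points = [(r, cc) for r in range(8, 57, 7) for cc in range(8, 121, 13)]
        expected = np.zeros(len(points))
        for s in sigmas:
            sm = ndi.gaussian_filter(img, s, mode="reflect")
            d0 = np.gradient(sm, axis=0)
            d1 = np.gradient(sm, axis=1)
            Hrr = np.gradient(d0, axis=0) * s**2
            Hrc = np.gradient(d0, axis=1) * s**2
            Hcc = np.gradient(d1, axis=1) * s**2
            for i, (r, cc) in enumerate(points):
                H = np.array([[Hrr[r, cc], Hrc[r, cc]],
                              [Hrc[r, cc], Hcc[r, cc]]])
                ev = np.linalg.eigvalsh(H)
                l1, l2 = sorted(ev, key=abs)
                if l2 >= 0:
                    continue
                v = math.exp(-((l1 / l2) ** 2) / (2 * beta**2)) * (
                    1 - math.exp(-(l1**2 + l2**2) / (2 * c**2))
                )
                expected[i] = max(expected[i], v)
        got = np.array([ours.pixels[p] for p in points])
        np.testing.assert_allclose(got, expected, atol=1e-3)


class TestGmmSegment:
    def _mix_image(self, frac_fiber, n=100_000, seed=0):
        rng = np.random.default_rng(seed)
        nf = int(n * frac_fiber)
        vals = np.concatenate([
            rng.normal(0.10, 0.02, n - nf),
            rng.normal(0.80, 0.05, nf),
        ])
        rng.shuffle(vals)
        side = int(np.sqrt(n))
        vals = np.clip(vals[: side * side], 0, 1).reshape(side, side)
        return seg.EnhancedImage(pixels=vals, scales_used=(1.0,), beta=0.5,
                                 c=1.0, pixel_size_um=0.5)

    @pytest.mark.parametrize("frac", [0.5, 0.1])
    def test_balanced_mixture_fraction_and_boundary(self, frac):
        """Foreground fraction matches the Bayes rate for the known mixture,
        and the implied decision boundary separates the classes within the
        analytic intersection band."""
        enh = self._mix_image(frac)
        mask = seg.gmm_segment(enh, seed=0)
        fg_frac = mask.pixels.mean()
        assert fg_frac == pytest.approx(frac, abs=0.02)
        # every background-classified value sits below 0.6 and every
        # foreground-classified value above 0.2: the boundary is in [0.2, 0.6]
        assert enh.pixels[~mask.pixels].max() <= 0.6
        assert enh.pixels[mask.pixels].min() >= 0.2

    def test_constant_image_degenerate(self):
        enh = seg.EnhancedImage(pixels=np.zeros((32, 32)), scales_used=(1.0,),
                                beta=0.5, c=1.0, pixel_size_um=0.5)
        mask = seg.gmm_segment(enh)
        assert not mask.pixels.any()
        assert mask.warning is not None

    def test_reproducible_under_seed(self):
        enh = self._mix_image(0.3, seed=5)
        a = seg.gmm_segment(enh, seed=11)
        b = seg.gmm_segment(enh, seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_posterior_decision_variant(self):
        enh = self._mix_image(0.5)
        mask = seg.gmm_segment(enh, fit_on="all", decision="posterior")
        assert mask.pixels.mean() == pytest.approx(0.5, abs=0.02)


class TestRefineMask:
    def test_minimum_segment_rule_exact(self):
        px = np.zeros((40, 60), dtype=bool)
        px[2, 2:5] = True          # 3 px -> removed
        px[10, 10:14] = True       # 4 px -> removed
        px[20, 20:25] = True       # 5 px -> kept
        px[30, 30:50] = True       # 20 px -> kept
        mask = seg.BinaryMask(px, refined=False, min_segment_px=5,
                              pixel_size_um=1.0)
        out = seg.refine_mask(mask, closing_radius_px=0, min_segment_px=5)
        lbl, n = ndi.label(out.pixels, structure=np.ones((3, 3), int))
        sizes = sorted(np.bincount(lbl.ravel())[1:])
        assert sizes == [5, 20]

    def test_hole_filled(self):
        px = np.zeros((30, 30), dtype=bool)
        px[5:25, 5:25] = True
        px[12:15, 12:15] = False
        mask = seg.BinaryMask(px, refined=False, min_segment_px=5,
                              pixel_size_um=1.0)
        out = seg.refine_mask(mask, closing_radius_px=0)
        assert out.pixels.sum() == 400

    def test_closing_bridges_one_px_gap(self):
        px = np.zeros((9, 30), dtype=bool)
        px[4, 2:12] = True
        px[4, 13:23] = True  # 1-px gap at col 12
        mask = seg.BinaryMask(px, refined=False, min_segment_px=5,
                              pixel_size_um=1.0)
        out = seg.refine_mask(mask, closing_radius_px=1)
        _, n = ndi.label(out.pixels, structure=np.ones((3, 3), int))
        assert n == 1

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        px = rng.uniform(size=(60, 60)) > 0.6
        mask = seg.BinaryMask(px, refined=False, min_segment_px=5,
                              pixel_size_um=1.0)
        once = seg.refine_mask(mask)
        with pytest.warns(UserWarning):
            twice = seg.refine_mask(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_refined_invariants(self):
        rng = np.random.default_rng(8)
        px = rng.uniform(size=(80, 80)) > 0.55
        mask = seg.BinaryMask(px, refined=False, min_segment_px=5,
                              pixel_size_um=1.0)
        out = seg.refine_mask(mask)
        assert out.refined
        lbl, n = ndi.label(out.pixels, structure=np.ones((3, 3), int))
        if n:
            assert np.bincount(lbl.ravel())[1:].min() >= 5
        filled = ndi.binary_fill_holes(out.pixels)
        np.testing.assert_array_equal(filled, out.pixels)
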