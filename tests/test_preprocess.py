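"""Quality filter, hue-peak unmixing, NNLS, border crop and resize."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from har_locator.preprocess import (
    BBox,
    ChannelPair,
    FormatError,
    UnmixingError,
    crop_border_canny,
    fit_unmix,
    hue_histogram,
    resize_to_input,
    staining_quality_filter,
    stained_fraction,
    unmix_lin,
)
from har_locator.synthetic import SynthConfig, generate_dataset, render


def _two_stain_image(size=96, seed=0, noise=0.0):
    cfg = SynthConfig(n_per_class=1, image_size=size, seed=seed, noise_sigma=noise,
                      classes=("cytosol",))
    return generate_dataset(cfg)[0], cfg


class TestQualityFilter:
    def test_pure_white_rejected(self):
        white = np.full((32, 32, 3), 255, np.uint8)
        assert staining_quality_filter(white) is False

    def test_forty_percent_stained_kept(self):
        """40% stained area passes a 5% minimum-stain threshold."""
        img = np.full((100, 100, 3), 255, np.uint8)
        img[:40] = [180, 120, 80]  # strongly stained band, saturation ~0.55
        assert staining_quality_filter(img, min_stain_fraction=0.05) is True

    def test_stained_synthetic_kept(self, small_dataset):
        # sparse classes (centrosome, vesicles) legitimately stain few pixels;
        # all synthetic images must still clear a blank-image threshold
        for s in small_dataset:
            assert staining_quality_filter(s.image, min_stain_fraction=0.01)

    def test_non_rgb_rejected(self):
        with pytest.raises(FormatError):
            staining_quality_filter(np.zeros((10, 10)))

    def test_kept_count_non_increasing_in_threshold(self, small_dataset):
        """Sweeping the minimum stained fraction can only shrink the kept set,
        and agrees with a direct count of per-image stained fractions."""
        fracs = np.array([stained_fraction(s.image) for s in small_dataset])
        kept = [
            sum(staining_quality_filter(s.image, min_stain_fraction=t) for s in small_dataset)
            for t in np.linspace(0, 1, 21)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))
        for t, k in zip(np.linspace(0, 1, 21), kept):
            assert k == int((fracs >= t).sum())


class TestFitUnmix:
    def test_recovers_rendered_basis(self):
        s, cfg = _two_stain_image(noise=0.0)
        m = fit_unmix(s.image)
        for j in range(2):
            cos = abs(m.basis[:, j] @ cfg.stain_basis[:, j])
            assert cos >= 0.99, (j, cos)

    def test_grayscale_raises(self):
        gray = np.tile(np.arange(64, dtype=np.uint8)[:, None, None], (1, 64, 3))
        with pytest.raises(UnmixingError):
            fit_unmix(gray)

    def test_hue_peaks_match_histogram_argmax(self):
        """Each reported peak is within one bin of the local argmax of the
        explicitly computed histogram near the rendered stain hue."""
        s, _ = _two_stain_image(noise=0.0)
        m = fit_unmix(s.image, hue_bins=256)
        hist, _, _ = hue_histogram(s.image, 256)
        # brown stain lives in bins [0, 64), purple in [128, 224)
        brown = np.argmax(hist[:64])
        purple = 128 + np.argmax(hist[128:224])
        assert abs(m.hue_peaks[0] * 256 - brown) <= 2
        assert abs(m.hue_peaks[1] * 256 - purple) <= 2

    def test_permutation_safe_assignment(self):
        """Swapping basis column order at render time must not swap the
        protein/DNA assignment (it is by hue proximity, not peak order)."""
        cfg = SynthConfig(n_per_class=1, image_size=96, seed=4, noise_sigma=0.0,
                          classes=("cytosol",))
        s = generate_dataset(cfg)[0]
        rng = np.random.default_rng(0)
        swapped = render(s.truth_dna, s.truth_protein,
                         cfg.stain_basis[:, ::-1], 0.0, rng)
        m1 = fit_unmix(s.image)
        m2 = fit_unmix(swapped)
        assert abs(m1.basis[:, 0] @ m2.basis[:, 0]) > 0.99
        assert abs(m1.basis[:, 1] @ m2.basis[:, 1]) > 0.99


class TestUnmixLin:
    def test_single_stain_image_gives_empty_dna(self):
        s, cfg = _two_stain_image(noise=0.0)
        from har_locator.preprocess import UnmixModel

        model = UnmixModel(hue_peaks=(0.08, 0.7), basis=cfg.stain_basis)
        a = 120.0 * np.random.default_rng(0).uniform(0.2, 1.0, (32, 32))
        img = 255.0 - a[..., None] * cfg.stain_basis[:, 0]  # exactly a*b1
        pair = unmix_lin(img, model)
        assert pair.dna.max() < 1e-6 * pair.protein.max()

    def test_reconstruction_error_small(self):
        s, cfg = _two_stain_image(noise=0.0)
        m = fit_unmix(s.image)
        pair = unmix_lin(s.image, m)
        inv = 255.0 - s.image.astype(float)
        rec = pair.protein[..., None] * m.basis[:, 0] + pair.dna[..., None] * m.basis[:, 1]
        rel = np.linalg.norm(rec - inv) / np.linalg.norm(inv)
        assert rel < 0.05

    def test_nonnegative_abundances(self, small_dataset):
        for s in small_dataset[:4]:
            pair = unmix_lin(s.image, fit_unmix(s.image))
            assert pair.protein.min() >= 0 and pair.dna.min() >= 0

    def test_matches_scipy_nnls_per_pixel(self):
        """Closed-form 2-column active set equals scipy NNLS on random pixels."""
        s, _ = _two_stain_image(noise=3.0, seed=5)
        m = fit_unmix(s.image)
        pair = unmix_lin(s.image, m)
        rng = np.random.default_rng(0)
        h, w = s.image.shape[:2]
        for _ in range(10):
            r, c = rng.integers(0, h), rng.integers(0, w)
            y = 255.0 - s.image[r, c].astype(float)
            ref, _ = scipy_nnls(m.basis, y)
            assert abs(pair.protein[r, c] - ref[0]) < 1e-6
            assert abs(pair.dna[r, c] - ref[1]) < 1e-6


class TestCropBorder:
    def _centered_content(self, size=128):
        img = np.full((size, size, 3), 255, np.uint8)
        prot = np.zeros((size, size))
        q = size // 4
        rng = np.random.default_rng(0)
        prot[q : 3 * q, q : 3 * q] = rng.uniform(50, 150, (2 * q, 2 * q))
        return ChannelPair(protein=prot, dna=np.zeros_like(prot)), img

    def test_blank_border_excluded(self):
        pair, img = self._centered_content()
        _, _, bbox = crop_border_canny(pair, img, margin=0)
        size = img.shape[0]
        content = (size // 2) ** 2
        blank_area = size * size - content
        kept_blank = (bbox.r1 - bbox.r0) * (bbox.c1 - bbox.c0) - content
        assert bbox.found_edges
        assert kept_blank < 0.1 * blank_area

    def test_constant_channel_passthrough(self):
        size = 64
        pair = ChannelPair(protein=np.ones((size, size)), dna=np.zeros((size, size)))
        img = np.zeros((size, size, 3), np.uint8)
        out_img, out_pair, bbox = crop_border_canny(pair, img)
        assert not bbox.found_edges
        assert out_img.shape == img.shape and np.array_equal(out_pair.protein, pair.protein)

    def test_bbox_matches_bruteforce_edge_scan(self):
        """bbox equals the exhaustive min/max over the union edge mask."""
        from skimage import feature, filters

        pair, img = self._centered_content()
        _, _, bbox = crop_border_canny(pair, img, margin=0)
        p = pair.protein
        pn = (p - p.min()) / (p.max() - p.min())
        union = np.zeros(p.shape, bool)
        for s in (1.0, 3.0):
            gmag = filters.sobel(filters.gaussian(pn, sigma=s))
            th = filters.threshold_otsu(gmag)
            union |= feature.canny(pn, sigma=s, low_threshold=0.5 * th, high_threshold=th)
        rows = np.flatnonzero(union.any(axis=1))
        cols = np.flatnonzero(union.any(axis=0))
        assert (bbox.r0, bbox.r1, bbox.c0, bbox.c1) == (
            rows[0],
            rows[-1] + 1,
            cols[0],
            cols[-1] + 1,
        )

    def test_crop_never_enlarges(self, small_dataset):
        for s in small_dataset[:3]:
            pair = unmix_lin(s.image, fit_unmix(s.image))
            out_img, _, bbox = crop_border_canny(pair, s.image)
            h, w = s.image.shape[:2]
            assert 0 <= bbox.r0 <= bbox.r1 <= h and 0 <= bbox.c0 <= bbox.c1 <= w
            assert out_img.shape[0] <= h and out_img.shape[1] <= w


class TestResize:
    def test_large_to_512(self):
        big = np.random.default_rng(0).integers(0, 255, (600, 600, 3), dtype=np.uint8)
        assert resize_to_input(big, 512).shape == (512, 512, 3)

    def test_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        assert np.array_equal(resize_to_input(img, 64), img)

    def test_constant_stays_constant(self):
        img = np.full((100, 80, 3), 137, np.uint8)
        out = resize_to_input(img, 64)
        assert np.all(out == 137)
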