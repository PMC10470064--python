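"""IHC preprocessing: quality filter, linear spectral unmixing, border crop, resize.

Brightfield IHC images carry two absorbing stains: brown DAB on the target
protein and purple hematoxylin on DNA.  Because stains *remove* light,
unmixing operates on inverted intensities ``255 - RGB`` ("stain amount"),
which makes two-stain separation a per-pixel nonnegative least-squares
problem against a 3x2 stain-color basis.  The basis is estimated per image
from the two dominant peaks of the saturation-weighted hue histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage import color, feature, filters, transform

#: reference hues used to assign histogram peaks to stains
BROWN_HUE = 0.08  # DAB / protein
PURPLE_HUE = 0.70  # hematoxylin / DNA

#: fallback stain basis (inverted-intensity colors) when peak finding fails
from .synthetic import DAB_OD, HEMATOXYLIN_OD  # noqa: E402

DEFAULT_BASIS = np.stack(
    [DAB_OD / np.linalg.norm(DAB_OD), HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)], axis=1
)


class FormatError(ValueError):
    """Raised when an input image has the wrong shape or dtype."""


class UnmixingError(RuntimeError):
    """Raised when a two-stain basis cannot be estimated from the image."""


@dataclass
class UnmixModel:
    """Estimated stain model: two hue peaks and a 3x2 inverted-RGB basis.

    ``basis[:, 0]`` is the protein (DAB-like) column, ``basis[:, 1]`` the
    DNA (hematoxylin-like) column; both unit-normalized and nonnegative.
    """

    hue_peaks: tuple  # (protein_hue, dna_hue), each in [0, 1)
    basis: np.ndarray


@dataclass
class ChannelPair:
    """Aligned nonnegative abundance maps for protein (DAB) and DNA."""

    protein: np.ndarray
    dna: np.ndarray

    def __post_init__(self):
        if self.protein.shape != self.dna.shape:
            raise FormatError("protein/dna shapes differ")


@dataclass
class BBox:
    """Half-open crop box [r0, r1) x [c0, c1); ``found_edges`` False means
    the crop was a passthrough because no edges were detected."""

    r0: int
    r1: int
    c0: int
    c1: int
    found_edges: bool = True


def _check_rgb(image):
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected HxWx3 RGB image, got shape {image.shape}")
    return image


# ---------------------------------------------------------------------------
# quality filter


def staining_quality_filter(image, min_stain_fraction=0.02, saturation_threshold=0.1):
    """Keep an image only if enough pixels are visibly stained.

    A pixel counts as stained when its HSV saturation exceeds
    ``saturation_threshold``; the image is kept when the stained fraction
    reaches ``min_stain_fraction``.
    """
    image = _check_rgb(image)
    hsv = color.rgb2hsv(image)
    frac = float(np.mean(hsv[..., 1] > saturation_threshold))
    return frac >= min_stain_fraction


def stained_fraction(image, saturation_threshold=0.1):
    """Fraction of pixels with saturation above the threshold."""
    image = _check_rgb(image)
    hsv = color.rgb2hsv(image)
    return float(np.mean(hsv[..., 1] > saturation_threshold))


# ---------------------------------------------------------------------------
# unmixing


def hue_histogram(image, hue_bins=256, value_ceiling=0.95, saturation_floor=0.1):
    """Saturation-weighted circular hue histogram with background excluded.

    Near-white pixels (value > ceiling) and essentially unsaturated pixels
    (saturation < floor, whose hue is noise) are background and contribute
    nothing.  Returns ``(hist, hsv, mask)``.
    """
    image = _check_rgb(image)
    hsv = color.rgb2hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    mask = (s >= saturation_floor) & ~(v > value_ceiling)
    bins = np.clip((h[mask] * hue_bins).astype(int), 0, hue_bins - 1)
    hist = np.bincount(bins, weights=s[mask], minlength=hue_bins)
    return hist, hsv, mask


def _circular_smooth(hist, sigma=2.0):
    n = len(hist)
    k = np.arange(-int(4 * sigma), int(4 * sigma) + 1)
    kern = np.exp(-0.5 * (k / sigma) ** 2)
    kern /= kern.sum()
    ext = np.concatenate([hist[-len(k) :], hist, hist[: len(k)]])
    sm = np.convolve(ext, kern, mode="same")
    return sm[len(k) : len(k) + n]


def _circular_peaks(hist, prominence_frac=0.01, min_separation=16):
    """Two dominant well-separated local maxima of a circular histogram.

    The histogram is circularly smoothed first; the second peak must lie at
    a circular distance of at least ``min_separation`` bins from the first.
    Returns the peak indices found (possibly fewer than two).
    """
    n = len(hist)
    sm = _circular_smooth(hist)
    pad = n // 4
    ext = np.concatenate([sm[-pad:], sm, sm[:pad]])
    floor = prominence_frac * (sm.max() if sm.max() > 0 else 1.0)
    idx, _ = find_peaks(ext, prominence=floor)
    idx = np.unique((idx - pad) % n)
    idx = idx[sm[idx] > 0]
    idx = idx[np.argsort(sm[idx])[::-1]]
    chosen = []
    for i in idx:
        if all(min(abs(i - j), n - abs(i - j)) >= min_separation for j in chosen):
            chosen.append(int(i))
        if len(chosen) == 2:
            break
    return np.array(chosen, dtype=int)


def _circ_dist(a, b):
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def fit_unmix(image, hue_bins=256, peak_window=8, prominence_frac=0.01):
    """Estimate a two-stain :class:`UnmixModel` from the hue histogram.

    The two most massive peaks are assigned to protein/DNA by circular hue
    proximity to brown (0.08) and purple (0.70); each basis column is the
    mean inverted RGB of pixels within ``peak_window`` bins of its peak.
    """
    image = _check_rgb(image)
    hist, hsv, mask = hue_histogram(image, hue_bins)
    if hist.sum() <= 0:
        raise UnmixingError("no hue mass (grayscale or blank image)")
    peaks = _circular_peaks(hist, prominence_frac)
    if len(peaks) < 2:
        raise UnmixingError(f"found {len(peaks)} hue peak(s); need 2")
    p1, p2 = peaks[:2]
    h1, h2 = p1 / hue_bins, p2 / hue_bins
    # assignment minimizing total circular distance to the stain references
    direct = _circ_dist(h1, BROWN_HUE) + _circ_dist(h2, PURPLE_HUE)
    swapped = _circ_dist(h2, BROWN_HUE) + _circ_dist(h1, PURPLE_HUE)
    prot_peak, dna_peak = (p1, p2) if direct <= swapped else (p2, p1)

    inv = 255.0 - np.asarray(image, dtype=float)
    hbin = np.clip((hsv[..., 0] * hue_bins).astype(int), 0, hue_bins - 1)
    cols = []
    for pk in (prot_peak, dna_peak):
        d = np.abs(hbin - pk)
        d = np.minimum(d, hue_bins - d)
        sel = (d <= peak_window) & mask
        if not np.any(sel):
            raise UnmixingError("empty hue window around a peak")
        col = inv[sel].mean(axis=0)
        nrm = np.linalg.norm(col)
        if nrm <= 0:
            raise UnmixingError("degenerate (zero) basis column")
        cols.append(col / nrm)
    basis = np.stack(cols, axis=1)
    ang = np.degrees(
        np.arccos(np.clip(basis[:, 0] @ basis[:, 1], -1, 1))
    )
    if ang < 1.0:
        raise UnmixingError("stain basis columns nearly collinear")
    return UnmixModel(hue_peaks=(prot_peak / hue_bins, dna_peak / hue_bins), basis=basis)


def unmix_lin(image, model: UnmixModel) -> ChannelPair:
    """Per-pixel nonnegative least squares of ``255 - RGB`` on the basis.

    With two columns the NNLS optimum has one of three supports
    ({1,2}, {1}, {2}); all three are solved in closed form, vectorized, and
    the feasible one with the smallest residual is kept.
    """
    image = _check_rgb(image)
    b = np.asarray(model.basis, dtype=float)
    if b.shape != (3, 2):
        raise FormatError("basis must be 3x2")
    y = (255.0 - image.reshape(-1, 3).astype(float)).T  # 3 x n
    g = b.T @ b
    c = b.T @ y  # 2 x n
    det = g[0, 0] * g[1, 1] - g[0, 1] ** 2
    # unconstrained solution
    a1 = (g[1, 1] * c[0] - g[0, 1] * c[1]) / det
    a2 = (g[0, 0] * c[1] - g[0, 1] * c[0]) / det
    ok = (a1 >= 0) & (a2 >= 0)
    # single-column fallbacks
    s1 = np.maximum(c[0] / g[0, 0], 0.0)
    s2 = np.maximum(c[1] / g[1, 1], 0.0)
    # objective difference (residual, up to constant ||y||^2):
    # J(a) = a'Ga - 2a'c
    j1 = s1 * s1 * g[0, 0] - 2 * s1 * c[0]
    j2 = s2 * s2 * g[1, 1] - 2 * s2 * c[1]
    use1 = j1 <= j2
    a1f = np.where(ok, a1, np.where(use1, s1, 0.0))
    a2f = np.where(ok, a2, np.where(use1, 0.0, s2))
    h, w = image.shape[:2]
    return ChannelPair(
        protein=a1f.reshape(h, w), dna=a2f.reshape(h, w)
    )


# ---------------------------------------------------------------------------
# border crop


def crop_border_canny(pair: ChannelPair, image, scales=(1.0, 3.0), margin=8):
    """Crop to the protein-bearing region found by two-scale Canny edges.

    Canny runs on the normalized protein channel at both Gaussian scales
    (hysteresis thresholds from Otsu on the gradient magnitude); the union
    edge mask's tight bounding box (plus ``margin``) is mapped back onto the
    RGB image and both channels.  With no edges the inputs pass through
    unchanged and ``bbox.found_edges`` is False.
    """
    if scales[0] >= scales[1]:
        raise ValueError("scales must be increasing")
    image = _check_rgb(image)
    p = pair.protein.astype(float)
    rng_ = p.max() - p.min()
    pn = (p - p.min()) / rng_ if rng_ > 0 else np.zeros_like(p)
    union = np.zeros(p.shape, bool)
    for s in scales:
        gmag = filters.sobel(filters.gaussian(pn, sigma=s))
        if gmag.max() <= 0:
            continue
        t_high = filters.threshold_otsu(gmag)
        union |= feature.canny(
            pn, sigma=s, low_threshold=0.5 * t_high, high_threshold=t_high
        )
    h, w = p.shape
    if not union.any():
        return image, pair, BBox(0, h, 0, w, found_edges=False)
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(h, rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(w, cols[-1] + 1 + margin)
    bbox = BBox(int(r0), int(r1), int(c0), int(c1), found_edges=True)
    return (
        image[r0:r1, c0:c1],
        ChannelPair(protein=pair.protein[r0:r1, c0:c1], dna=pair.dna[r0:r1, c0:c1]),
        bbox,
    )


def resize_to_input(image, size=512):
    """Bilinear resize to ``size`` x ``size``; output clipped uint8 RGB."""
    if size < 32:
        raise ValueError("size must be >= 32")
    image = _check_rgb(image)
    if image.shape[0] == size and image.shape[1] == size:
        return image.astype(np.uint8)
    out = transform.resize(
        image.astype(float),
        (size, size, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def preprocess_image(image, input_size=512, crop=True, model=None):
    """Full preprocessing of one image.

    Fits the unmix model (falling back to :data:`DEFAULT_BASIS` when peak
    finding fails), unmixes, optionally crops invalid borders, resizes the
    RGB image to the network input size and re-unmixes the resized image so
    the channels align with it.

    Returns ``(rgb_resized, ChannelPair, UnmixModel, BBox)``.
    """
    image = _check_rgb(image)
    if model is None:
        try:
            model = fit_unmix(image)
        except UnmixingError:
            model = UnmixModel(hue_peaks=(BROWN_HUE, PURPLE_HUE), basis=DEFAULT_BASIS.copy())
    pair = unmix_lin(image, model)
    if crop:
        image, pair, bbox = crop_border_canny(pair, image)
    else:
        h, w = image.shape[:2]
        bbox = BBox(0, h, 0, w, found_edges=False)
    rgb = resize_to_input(image, input_size)
    pair = unmix_lin(rgb, model)
    return rgb, pair, model, bbox
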