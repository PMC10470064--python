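"""1096-D shallow feature stack: wavelet Haralick | DNA spatial | LBP.

Block layout (fixed, documented):

* ``haralick`` (836): 2-D discrete wavelet transform of the protein channel
  (Daubechies ``db4``, 5 levels) gives 16 coefficient images (LL5 + 15
  detail bands).  On each band, a symmetric normalized GLCM is computed at
  the four unit offsets (0,1), (1,0), (1,1), (1,-1) after 32-level min-max
  quantization, and the 13 classical Haralick statistics are taken:
  16 bands x 4 offsets x 13 stats = 832.  The remaining 4 entries are the
  GLCM contrast of the raw (untransformed) channel at the same 4 offsets.
* ``dna`` (4): protein/DNA mask overlap fractions, mask area ratio and the
  normalized distance between intensity-weighted centroids.
* ``lbp`` (256): normalized histogram of classic 3x3 8-neighbor local
  binary pattern codes (bit 0 = top-left neighbor, clockwise, ties >=).

Entropy-type statistics use the natural logarithm with 0*log(0) := 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage import filters

from .preprocess import ChannelPair

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)


class SizeError(ValueError):
    """Raised when an image is too small for the requested operation."""


@dataclass
class Glcm:
    """Symmetric, unit-sum gray-level co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    offset: tuple


@dataclass
class HaralickLayout:
    """Configuration of the 836-D wavelet Haralick block."""

    wavelet: str = "db4"
    levels: int = 5
    glcm_levels: int = 32
    offsets: tuple = OFFSETS

    @property
    def n_bands(self):
        return 3 * self.levels + 1

    @property
    def dim(self):
        return self.n_bands * len(self.offsets) * 13 + len(self.offsets)


@dataclass
class ShallowVector:
    """1096-D shallow feature vector with a named block layout."""

    vector: np.ndarray
    layout: dict = field(
        default_factory=lambda: {"haralick": (0, 836), "dna": (836, 840), "lbp": (840, 1096)}
    )

    def block(self, name):
        a, b = self.layout[name]
        return self.vector[a:b]


def quantize(channel, levels):
    """Min-max linear quantization to integer levels 0..levels-1.

    A constant channel maps to all zeros.
    """
    channel = np.asarray(channel, dtype=float)
    lo, hi = channel.min(), channel.max()
    # a range at floating-point noise level is treated as constant
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.zeros(channel.shape, dtype=np.intp)
    q = ((channel - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(channel, offset, levels=32) -> Glcm:
    """Symmetric normalized co-occurrence matrix at one (dr, dc) offset.

    The channel is min-max quantized to ``levels`` gray levels; every pixel
    pair (p, p+offset) inside the image contributes to (i, j) and (j, i).
    """
    q = quantize(channel, levels)
    dr, dc = offset
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    m = (counts + counts.T).astype(float)
    total = m.sum()
    if total > 0:
        m /= total
    return Glcm(matrix=m, levels=levels, offset=(dr, dc))


def _xlogx(p):
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_stats(g: Glcm) -> np.ndarray:
    """The 13 classical Haralick statistics, in :data:`HARALICK_NAMES` order.

    Degenerate GLCMs (zero marginal variance) define correlation-type
    statistics as 0.  ``sum_variance`` is the variance of the i+j
    distribution about its own mean (the common erratum-corrected form).
    """
    p = g.matrix
    L = g.levels
    i = np.arange(L, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = i @ px
    mu_y = i @ py
    var_x = ((i - mu_x) ** 2) @ px
    var_y = ((i - mu_y) ** 2) @ py

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}(k), k = 0..2L-2 ; p_{x-y}(k), k = 0..L-1
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(), minlength=2 * L - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(), minlength=L)
    ks = np.arange(2 * L - 1, dtype=float)
    kd = np.arange(L, dtype=float)

    energy = float((p * p).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    mu = mu_x  # symmetric GLCM: mu_x == mu_y
    variance = float((((ii - mu) ** 2) * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float(ks @ psum)
    sum_var = float(((ks - sum_avg) ** 2) @ psum)
    sum_ent = float(-_xlogx(psum).sum())
    entropy = float(-_xlogx(p).sum())
    diff_avg = float(kd @ pdiff)
    diff_var = float(((kd - diff_avg) ** 2) @ pdiff)
    diff_ent = float(-_xlogx(pdiff).sum())

    hxy = entropy
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log(pxy[nz])).sum())
    hxy2 = float(-_xlogx(pxy).sum())
    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return np.array(
        [
            energy,
            contrast,
            correlation,
            variance,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            entropy,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ]
    )


def wavelet_bands(channel, layout: HaralickLayout):
    """DWT coefficient images: [LL_n, (LH_n, HL_n, HH_n), ..., (LH_1, ...)]."""
    channel = np.asarray(channel, dtype=float)
    if min(channel.shape) < 64:
        raise SizeError("channel too small for 5-level wavelet decomposition (< 64 px)")
    with warnings.catch_warnings():
        # boundary-effect warning when levels exceed the nominal maximum
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(channel, layout.wavelet, level=layout.levels)
    bands = [coeffs[0]]
    for detail in coeffs[1:]:
        bands.extend(detail)
    return bands


def haralick_dwt_features(protein, layout: HaralickLayout = None) -> np.ndarray:
    """836-D wavelet-domain Haralick block of the protein channel."""
    layout = layout or HaralickLayout()
    feats = []
    for band in wavelet_bands(protein, layout):
        for off in layout.offsets:
            feats.append(haralick_stats(glcm(band, off, layout.glcm_levels)))
    raw_contrast = [
        haralick_stats(glcm(protein, off, layout.glcm_levels))[1] for off in layout.offsets
    ]
    vec = np.concatenate(feats + [np.asarray(raw_contrast)])
    assert vec.shape[0] == layout.dim
    return vec


def lbp_codes(channel) -> np.ndarray:
    """3x3 LBP code of every interior pixel.

    Bit k is set when the k-th neighbor >= center; neighbors are ordered
    clockwise from the top-left: TL, T, TR, R, BR, B, BL, L.
    """
    x = np.asarray(channel, dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise SizeError("LBP needs at least a 3x3 image")
    c = x[1:-1, 1:-1]
    nbrs = (
        x[:-2, :-2],  # TL
        x[:-2, 1:-1],  # T
        x[:-2, 2:],  # TR
        x[1:-1, 2:],  # R
        x[2:, 2:],  # BR
        x[2:, 1:-1],  # B
        x[2:, :-2],  # BL
        x[1:-1, :-2],  # L
    )
    code = np.zeros(c.shape, dtype=np.intp)
    for bit, nb in enumerate(nbrs):
        code |= (nb >= c).astype(np.intp) << bit
    return code


def lbp_features(protein) -> np.ndarray:
    """Normalized 256-bin histogram of 3x3 LBP codes."""
    codes = lbp_codes(protein)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def dna_spatial_features(pair: ChannelPair) -> np.ndarray:
    """4-D DNA spatial-distribution block.

    (1) fraction of protein-positive pixels inside the DNA mask,
    (2) fraction of DNA-positive pixels inside the protein mask,
    (3) DNA mask area / protein mask area,
    (4) distance between intensity-weighted centroids / image diagonal.
    Otsu binarization; empty-mask fallback is (0, 0, 0, 1).
    """

    def _mask(ch):
        ch = np.asarray(ch, dtype=float)
        if ch.max() <= ch.min():
            return np.zeros(ch.shape, bool)
        return ch > filters.threshold_otsu(ch)

    pm = _mask(pair.protein)
    dm = _mask(pair.dna)
    if not pm.any() or not dm.any():
        return np.array([0.0, 0.0, 0.0, 1.0])
    f1 = float((pm & dm).sum() / pm.sum())
    f2 = float((pm & dm).sum() / dm.sum())
    ratio = float(dm.sum() / pm.sum())

    def _centroid(ch):
        w = np.asarray(ch, dtype=float)
        tot = w.sum()
        if tot <= 0:
            return None
        yy, xx = np.mgrid[0 : ch.shape[0], 0 : ch.shape[1]]
        return np.array([(yy * w).sum() / tot, (xx * w).sum() / tot])

    cp, cd = _centroid(pair.protein), _centroid(pair.dna)
    if cp is None or cd is None:
        dist = 1.0
    else:
        diag = float(np.hypot(*pair.protein.shape))
        dist = float(np.linalg.norm(cp - cd) / diag)
    return np.array([f1, f2, ratio, dist])


def shallow_vector(pair: ChannelPair, layout: HaralickLayout = None) -> ShallowVector:
    """Concatenate haralick | dna | lbp into the 1096-D shallow vector."""
    har = haralick_dwt_features(pair.protein, layout)
    dna = dna_spatial_features(pair)
    lbp = lbp_features(pair.protein)
    vec = np.concatenate([har, dna, lbp])
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite shallow feature encountered")
    return ShallowVector(vector=vec)
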