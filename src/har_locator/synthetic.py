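"""Seeded synthetic IHC image generator.

Renders two-stain brightfield-like RGB images under a linear-clip
optical-density convention::

    image = clip(255 - protein * b_dab - dna * b_hema + noise, 0, 255)

where ``b_dab`` / ``b_hema`` are nonnegative stain "color" vectors (the
amount of intensity each abundance unit removes from R, G and B) and the
``protein`` / ``dna`` maps carry class-specific spatial patterns: diffuse
cytosol, reticular ER, perinuclear Golgi crescents, intranuclear nucleoli,
granular mitochondria, centrosomal puncta and scattered vesicles.  The DNA
channel always contains elliptical nuclei.  Generation is fully determined
by the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import CLASS_NAMES

# Ruifrok-Johnston H-DAB optical-density directions (unit vectors).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.268, 0.570, 0.776])

_HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
_DAB_OD = DAB_OD / np.linalg.norm(DAB_OD)

#: peak abundance (inverted-intensity units) for each stain; chosen so that
#: fully co-stained pixels stay inside [0, 255] without clipping.
PROTEIN_AMPLITUDE = 160.0
DNA_AMPLITUDE = 170.0


class ConfigurationError(ValueError):
    """Raised for invalid synthetic-generator configuration."""


@dataclass
class SynthConfig:
    """Configuration of the synthetic IHC dataset generator.

    Parameters
    ----------
    n_per_class : int
        Images generated per class (balanced by construction).
    image_size : int
        Side length in pixels of the square images (>= 64).
    classes : tuple of str
        Pattern names; must be a subset/reordering of the seven canonical
        class names.
    stain_basis : (3, 2) ndarray
        Columns are the DAB-like (protein) and hematoxylin-like (DNA)
        inverted-intensity color vectors; nonnegative, linearly independent.
    noise_sigma : float
        Gaussian pixel noise std, intensity units on the 0-255 scale.
    seed : int
        Seed for all randomness.
    """

    n_per_class: int = 10
    image_size: int = 512
    classes: tuple = CLASS_NAMES
    stain_basis: np.ndarray = field(
        default_factory=lambda: np.stack([_DAB_OD, _HEMATOXYLIN_OD], axis=1)
    )
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self):
        self.stain_basis = np.asarray(self.stain_basis, dtype=float)
        if self.stain_basis.shape != (3, 2):
            raise ConfigurationError("stain_basis must be 3x2")
        if np.any(self.stain_basis < 0):
            raise ConfigurationError("stain_basis must be nonnegative")
        b1, b2 = self.stain_basis.T
        cos = abs(b1 @ b2) / (np.linalg.norm(b1) * np.linalg.norm(b2))
        if cos > 1 - 1e-6:
            raise ConfigurationError("stain_basis columns must be linearly independent")
        unknown = set(self.classes) - set(CLASS_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown class name(s): {sorted(unknown)}")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")


@dataclass
class SynthSample:
    """One generated image with its label and ground-truth abundance maps."""

    image: np.ndarray  # H x W x 3 uint8
    label: int
    truth_protein: np.ndarray  # H x W float, inverted-intensity abundance
    truth_dna: np.ndarray


# ---------------------------------------------------------------------------
# pattern primitives


def _soft_disks(size, centers, radii, rng=None, jitter=0.0):
    """Sum of smooth radial bumps; values roughly in [0, 1]."""
    out = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for (cy, cx), r in zip(centers, radii):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        out += np.exp(-d2 / (2 * (0.55 * r) ** 2))
    return np.clip(out, 0, 1)


def _nuclei(size, rng):
    """Elliptical nuclei mask/intensity map plus center+radius bookkeeping."""
    n = max(4, int(round((size / 64.0) ** 2 * 2)))
    dna = np.zeros((size, size))
    info = []
    yy, xx = np.mgrid[0:size, 0:size]
    margin = int(size * 0.08)
    for _ in range(n):
        cy, cx = rng.integers(margin, size - margin, size=2)
        a = rng.uniform(0.035, 0.065) * size  # semi-axes
        b = a * rng.uniform(0.6, 1.0)
        th = rng.uniform(0, np.pi)
        yr = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        xr = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        d = (yr / a) ** 2 + (xr / b) ** 2
        dna = np.maximum(dna, np.clip(1.15 - d, 0, 1) ** 0.7)
        info.append((cy, cx, max(a, b)))
    dna = np.clip(dna, 0, 1)
    return dna, info


def _texture_noise(size, rng, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


def _pattern_cytosol(size, rng, dna, nuclei):
    base = _texture_noise(size, rng, size / 16.0)
    p = np.clip(0.55 + 0.45 * base, 0, 1)
    return p * (1 - 0.75 * dna)


def _pattern_er(size, rng, dna, nuclei):
    f = _texture_noise(size, rng, size / 40.0)
    web = np.exp(-((f / 0.25) ** 2))  # thin filaments at zero crossings
    prox = ndimage.gaussian_filter(dna, size / 24.0)
    prox = prox / (prox.max() + 1e-12)
    return np.clip(web * (0.35 + 0.65 * prox), 0, 1)


def _pattern_golgi(size, rng, dna, nuclei):
    p = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx, r in nuclei:
        phi0 = rng.uniform(0, 2 * np.pi)
        rad = r * 1.45
        ang = np.arctan2(yy - cy, xx - cx)
        dphi = np.angle(np.exp(1j * (ang - phi0)))
        d = np.hypot(yy - cy, xx - cx)
        band = np.exp(-((d - rad) ** 2) / (2 * (0.16 * r) ** 2))
        arc = np.exp(-((dphi / 1.05) ** 2))
        p = np.maximum(p, band * arc)
    return np.clip(p, 0, 1)


def _pattern_nucleoli(size, rng, dna, nuclei):
    centers, radii = [], []
    for cy, cx, r in nuclei:
        for _ in range(rng.integers(1, 4)):
            rr = rng.uniform(0, 0.45 * r)
            th = rng.uniform(0, 2 * np.pi)
            centers.append((cy + rr * np.sin(th), cx + rr * np.cos(th)))
            radii.append(max(2.0, 0.018 * size))
    p = _soft_disks(size, centers, radii)
    return p * (dna > 0.15)


def _pattern_mitochondria(size, rng, dna, nuclei):
    n = max(60, size * size // 260)
    pts = np.zeros((size, size))
    idx = rng.integers(0, size, size=(n, 2))
    pts[idx[:, 0], idx[:, 1]] = rng.uniform(0.6, 1.0, size=n)
    # elongated grains: anisotropic smoothing in two orientations
    g1 = ndimage.gaussian_filter(pts, (0.8, 2.4))
    g2 = ndimage.gaussian_filter(pts, (2.4, 0.8))
    p = np.maximum(g1, g2)
    p = p / (p.max() + 1e-12)
    return np.clip(p * (1 - 0.6 * dna), 0, 1)


def _pattern_centrosome(size, rng, dna, nuclei):
    centers, radii = [], []
    for cy, cx, r in nuclei:
        for _ in range(rng.integers(1, 3)):
            th = rng.uniform(0, 2 * np.pi)
            d = r * rng.uniform(1.15, 1.5)
            centers.append((cy + d * np.sin(th), cx + d * np.cos(th)))
            radii.append(max(2.0, 0.008 * size))
    return _soft_disks(size, centers, radii)


def _pattern_vesicles(size, rng, dna, nuclei):
    n = max(30, size * size // 800)
    centers = rng.uniform(0, size, size=(n, 2))
    radii = rng.uniform(0.006, 0.012, size=n) * size
    return _soft_disks(size, centers, radii)


_PATTERNS = {
    "cytosol": _pattern_cytosol,
    "er": _pattern_er,
    "golgi": _pattern_golgi,
    "nucleoli": _pattern_nucleoli,
    "mitochondria": _pattern_mitochondria,
    "centrosome": _pattern_centrosome,
    "vesicles": _pattern_vesicles,
}


# ---------------------------------------------------------------------------


def render(protein, dna, stain_basis, noise_sigma, rng):
    """Render an RGB image from abundance maps under the linear-clip model."""
    od = protein[..., None] * stain_basis[:, 0] + dna[..., None] * stain_basis[:, 1]
    img = 255.0 - od
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_sample(class_name: str, cfg: SynthConfig, rng) -> SynthSample:
    """Generate one labeled sample for ``class_name``."""
    if class_name not in _PATTERNS:
        raise ConfigurationError(f"unknown class name: {class_name!r}")
    size = cfg.image_size
    dna01, nuclei = _nuclei(size, rng)
    prot01 = _PATTERNS[class_name](size, rng, dna01, nuclei)
    amp_p = PROTEIN_AMPLITUDE * rng.uniform(0.9, 1.1)
    amp_d = DNA_AMPLITUDE * rng.uniform(0.9, 1.1)
    protein = prot01 * amp_p
    dna = dna01 * amp_d
    image = render(protein, dna, cfg.stain_basis, cfg.noise_sigma, rng)
    return SynthSample(
        image=image,
        label=CLASS_NAMES.index(class_name),
        truth_protein=protein,
        truth_dna=dna,
    )


def generate_dataset(cfg: SynthConfig) -> list:
    """Generate ``len(cfg.classes) * cfg.n_per_class`` labeled samples.

    Classes are exactly balanced and ordering is deterministic: all samples
    of the first class, then the second, etc.  Same seed, same output bytes.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for cname in cfg.classes:
        for _ in range(cfg.n_per_class):
            samples.append(generate_sample(cname, cfg, rng))
    return samples


def write_dataset(samples, out_dir):
    """Write samples as PNGs plus a ``labels.csv`` (filename,label)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"img_{i:04d}_{CLASS_NAMES[s.label]}.png"
        iio.imwrite(out / name, s.image)
        rows.append((name, s.label))
    with open(out / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return [r[0] for r in rows]
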