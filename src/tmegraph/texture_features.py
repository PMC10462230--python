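"""Tile-level texture features on the hematoxylin channel.

Eighty features from six families — gray-level co-occurrence (GLCM), Gabor
filter bank, local binary patterns (LBP), Tamura perceptual descriptors,
lower-order intensity histogram and higher-order (gradient-magnitude)
histogram — followed by a degenerate-feature filter that keeps the columns
that are informative on training data (all-zero, NA and duplicate columns
are removed). Exact supplementary parameterizations of the published
families are not available, so the registry below is a documented
reconstruction; it is data-driven only through the filtering step.

All extractors take a single-channel image with values in [0, 1] and are
deterministic. Feature order is fixed by the registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_ANGLE_NAMES = ("0", "45", "90", "135")
GABOR_FREQUENCIES = (0.1, 0.2, 0.4)
GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GABOR_THETA_NAMES = ("0", "45", "90", "135")
LBP_P, LBP_R = 8, 1
HIST_BINS = 32
PERCENTILES = (1, 5, 10, 25, 40, 50, 60, 75, 90, 99)


def _registry_entries() -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    for f in ("contrast", "correlation", "energy", "homogeneity", "entropy"):
        entries.append((f"glcm_{f}", "GLCM"))
    for ang in GLCM_ANGLE_NAMES:
        for f in ("contrast", "correlation", "energy", "homogeneity"):
            entries.append((f"glcm_{f}_a{ang}", "GLCM"))
    for freq in GABOR_FREQUENCIES:
        for theta in GABOR_THETA_NAMES:
            for stat in ("mean", "var"):
                entries.append((f"gabor_f{freq:g}_o{theta}_{stat}", "Gabor"))
    for b in range(LBP_P + 1):
        entries.append((f"lbp_u{b}", "LBP"))
    entries.append(("lbp_nonuniform", "LBP"))
    for f in ("coarseness", "contrast", "directionality"):
        entries.append((f"tamura_{f}", "Tamura"))
    for f in ("mean", "variance", "skewness", "kurtosis", "energy", "entropy"):
        entries.append((f"hist_{f}", "lower_histogram"))
    for f in ("mean", "variance", "skewness", "kurtosis", "energy", "entropy"):
        entries.append((f"grad_{f}", "higher_histogram"))
    for p in PERCENTILES:
        entries.append((f"pct_{p}", "lower_histogram"))
    return entries


@dataclass
class FeatureRegistry:
    """Stable ordered feature definitions plus the retained mask."""

    names: tuple[str, ...]
    families: tuple[str, ...]
    retained: np.ndarray | None = field(default=None)

    @classmethod
    def default(cls) -> "FeatureRegistry":
        entries = _registry_entries()
        names = tuple(n for n, _ in entries)
        families = tuple(f for _, f in entries)
        assert len(names) == 80 and len(set(names)) == 80
        return cls(names, families)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def retained_names(self) -> tuple[str, ...]:
        if self.retained is None:
            raise ValueError("retained mask not set; call filter_features first")
        return tuple(n for n, keep in zip(self.names, self.retained) if keep)

    def index(self, name: str) -> int:
        return self.names.index(name)


def quantize(img: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """[0,1] image -> integer gray levels 0..levels-1."""
    return np.minimum((np.clip(img, 0.0, 1.0) * levels).astype(np.uint8), levels - 1)


def glcm_matrix(img: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric normalized GLCMs at distance 1 for the four standard
    offsets; shape (levels, levels, 4)."""
    q = quantize(img, levels)
    glcm = graycomatrix(q, distances=[1], angles=list(GLCM_ANGLES), levels=levels,
                        symmetric=True, normed=True)
    return glcm[:, :, 0, :]


def _glcm_props(p: np.ndarray) -> dict[str, float]:
    """Haralick-style properties of one normalized symmetric GLCM.

    Energy is the angular second moment (sum of squared entries);
    correlation of a constant image (zero marginal variance) is defined 0.
    """
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float((p * (i - j) ** 2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def glcm_features(img: np.ndarray) -> dict[str, float]:
    """Offset-averaged (5) plus per-offset (16) GLCM features."""
    mats = glcm_matrix(img)
    per_offset = [_glcm_props(mats[:, :, k]) for k in range(mats.shape[2])]
    out: dict[str, float] = {}
    for f in ("contrast", "correlation", "energy", "homogeneity", "entropy"):
        out[f"glcm_{f}"] = float(np.mean([po[f] for po in per_offset]))
    for ang, po in zip(GLCM_ANGLE_NAMES, per_offset):
        for f in ("contrast", "correlation", "energy", "homogeneity"):
            out[f"glcm_{f}_a{ang}"] = po[f]
    return out


_GABOR_KERNELS = {
    (freq, name): gabor_kernel(frequency=freq, theta=theta)
    for freq in GABOR_FREQUENCIES
    for theta, name in zip(GABOR_THETAS, GABOR_THETA_NAMES)
}


def gabor_features(img: np.ndarray) -> dict[str, float]:
    """Mean and variance of the response magnitude of a 3-frequency x
    4-orientation Gabor bank (24 features). The DC component is removed so a
    constant image yields zero response."""
    x = img - img.mean()
    out: dict[str, float] = {}
    for (freq, name), kernel in _GABOR_KERNELS.items():
        resp = signal.fftconvolve(x, kernel, mode="same")
        mag = np.abs(resp)
        out[f"gabor_f{freq:g}_o{name}_mean"] = float(mag.mean())
        out[f"gabor_f{freq:g}_o{name}_var"] = float(mag.var())
    return out


def _lbp_offsets(p: int = LBP_P, radius: float = LBP_R) -> list[tuple[float, float]]:
    """Circle sample offsets (drow, dcol), rounded to 8 decimals so the four
    axis-aligned samples land exactly on grid points."""
    return [
        (round(-radius * np.sin(2 * np.pi * k / p), 8),
         round(radius * np.cos(2 * np.pi * k / p), 8))
        for k in range(p)
    ]


def lbp_codes(img: np.ndarray, p: int = LBP_P, radius: float = LBP_R) -> np.ndarray:
    """Uniform rotation-invariant LBP codes of all interior pixels.

    Each pixel is compared (>=) against p bilinearly interpolated samples on
    the radius-R circle; patterns with at most two circular 0/1 transitions
    ("uniform") are coded by their number of set bits, all others collapse
    to code p+1. Only pixels with a complete neighborhood are coded, so the
    output shrinks by ceil(R) on every side.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    b = int(np.ceil(radius))
    center = img[b : h - b, b : w - b]
    bits = np.empty((p,) + center.shape, dtype=bool)
    rows = np.arange(b, h - b)
    cols = np.arange(b, w - b)
    for k, (dr, dc) in enumerate(_lbp_offsets(p, radius)):
        r0 = np.floor(rows + dr).astype(int)
        r1 = np.ceil(rows + dr).astype(int)
        c0 = np.floor(cols + dc).astype(int)
        c1 = np.ceil(cols + dc).astype(int)
        fr = (rows + dr) - r0
        fc = (cols + dc) - c0
        top = (1 - fc) * img[np.ix_(r0, c0)] + fc * img[np.ix_(r0, c1)]
        bottom = (1 - fc) * img[np.ix_(r1, c0)] + fc * img[np.ix_(r1, c1)]
        sample = (1 - fr)[:, None] * top + fr[:, None] * bottom
        bits[k] = sample >= center
    transitions = np.zeros(center.shape, dtype=int)
    for k in range(p):
        transitions += bits[k] != bits[(k + 1) % p]
    n_set = bits.sum(axis=0)
    return np.where(transitions <= 2, n_set, p + 1)


def lbp_features(img: np.ndarray) -> dict[str, float]:
    """Normalized histogram of uniform rotation-invariant LBP codes
    (P=8, R=1): bins 0..8 count uniform patterns by number of set bits,
    bin 9 collects non-uniform patterns. The image is quantized to 8 bits
    first so neighbor comparisons are exact; border pixels (incomplete
    neighborhood) do not contribute."""
    codes = lbp_codes(np.asarray(quantize(img, 256), dtype=float))
    hist, _ = np.histogram(codes, bins=np.arange(LBP_P + 3) - 0.5)
    hist = hist / hist.sum()
    out = {f"lbp_u{b}": float(hist[b]) for b in range(LBP_P + 1)}
    out["lbp_nonuniform"] = float(hist[LBP_P + 1])
    return out


def _tamura_coarseness(img: np.ndarray, kmax: int = 5) -> float:
    """Tamura coarseness: mean over pixels of the best (largest-contrast)
    averaging window size 2^k."""
    h, w = img.shape
    e_best = np.zeros((kmax, h, w))
    for k in range(1, kmax + 1):
        size = 2**k
        if size >= min(h, w):
            break
        avg = ndimage.uniform_filter(img, size=size, mode="nearest")
        half = size // 2
        eh = np.zeros_like(img)
        ev = np.zeros_like(img)
        eh[:, half:w - half] = np.abs(
            np.roll(avg, -half, axis=1)[:, half:w - half] - np.roll(avg, half, axis=1)[:, half:w - half]
        )
        ev[half:h - half, :] = np.abs(
            np.roll(avg, -half, axis=0)[half:h - half, :] - np.roll(avg, half, axis=0)[half:h - half, :]
        )
        e_best[k - 1] = np.maximum(eh, ev)
    k_star = np.argmax(e_best, axis=0) + 1
    # Pixels with no response anywhere default to the finest scale.
    flat = e_best.max(axis=0) <= 0
    sbest = (2.0**k_star).astype(float)
    sbest[flat] = 2.0
    return float(sbest.mean())


def _tamura_contrast(img: np.ndarray) -> float:
    sigma = img.std()
    if sigma <= 0:
        return 0.0
    alpha4 = ((img - img.mean()) ** 4).mean() / sigma**4
    return float(sigma / alpha4**0.25)


def _tamura_directionality(img: np.ndarray, bins: int = 16, threshold: float = 1e-4) -> float:
    """Peak concentration (sum of squares) of the gradient-orientation
    histogram over [0, pi); 1/bins for isotropic texture, ->1 for stripes,
    0 when no gradient exceeds the threshold."""
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    mask = mag > threshold
    if not mask.any():
        return 0.0
    theta = np.mod(np.arctan2(gy[mask], gx[mask]), np.pi)
    hist, _ = np.histogram(theta, bins=bins, range=(0, np.pi), weights=mag[mask])
    hist = hist / hist.sum()
    return float((hist**2).sum())


def tamura_features(img: np.ndarray) -> dict[str, float]:
    return {
        "tamura_coarseness": _tamura_coarseness(img),
        "tamura_contrast": _tamura_contrast(img),
        "tamura_directionality": _tamura_directionality(img),
    }


def _moment_stats(values: np.ndarray, prefix: str) -> dict[str, float]:
    """mean/variance/skewness/kurtosis of values plus energy/entropy of
    their 32-bin histogram over [0, 1]; higher moments of a constant sample
    are defined as 0."""
    v = values.ravel()
    mean = float(v.mean())
    var = float(v.var())
    if var <= 0:
        skew = kurt = 0.0
    else:
        skew = float(_skew(v))
        kurt = float(_kurtosis(v, fisher=False))
    hist, _ = np.histogram(np.clip(v, 0.0, 1.0), bins=HIST_BINS, range=(0.0, 1.0))
    p = hist / hist.sum()
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        f"{prefix}_mean": mean,
        f"{prefix}_variance": var,
        f"{prefix}_skewness": skew,
        f"{prefix}_kurtosis": kurt,
        f"{prefix}_energy": energy,
        f"{prefix}_entropy": entropy,
    }


def histogram_features(img: np.ndarray) -> dict[str, float]:
    """Lower-order (intensity) and higher-order (gradient magnitude)
    histogram statistics plus intensity percentiles."""
    out = _moment_stats(img, "hist")
    gy, gx = np.gradient(img)
    out.update(_moment_stats(np.hypot(gx, gy), "grad"))
    pcts = np.percentile(img, PERCENTILES)
    for p, val in zip(PERCENTILES, pcts):
        out[f"pct_{p}"] = float(val)
    return out


def extract_features(img: np.ndarray, registry: FeatureRegistry | None = None) -> np.ndarray:
    """All 80 features of one tile image, in registry order."""
    if registry is None:
        registry = FeatureRegistry.default()
    img = np.asarray(img, dtype=float)
    values: dict[str, float] = {}
    values.update(glcm_features(img))
    values.update(gabor_features(img))
    values.update(lbp_features(img))
    values.update(tamura_features(img))
    values.update(histogram_features(img))
    return np.array([values[name] for name in registry.names])


def extract_feature_matrix(images: list[np.ndarray], registry: FeatureRegistry | None = None) -> np.ndarray:
    if registry is None:
        registry = FeatureRegistry.default()
    return np.stack([extract_features(im, registry) for im in images])


def filter_features(matrix: np.ndarray, registry: FeatureRegistry) -> np.ndarray:
    """Degenerate-column filter fit on training data only.

    Drops columns that are identically zero, contain any NA, or exactly
    duplicate an earlier retained column (first in registry order wins).
    Returns the boolean retained mask and stores it on the registry.
    """
    n, d = matrix.shape
    if d != len(registry):
        raise ValueError(f"matrix has {d} columns, registry {len(registry)}")
    retained = np.zeros(d, dtype=bool)
    kept_cols: list[int] = []
    for j in range(d):
        col = matrix[:, j]
        if np.isnan(col).any():
            continue
        if np.all(col == 0):
            continue
        if any(np.array_equal(col, matrix[:, k]) for k in kept_cols):
            continue
        retained[j] = True
        kept_cols.append(j)
    if retained.sum() == 0:
        raise ValueError("feature filtering removed every column")
    registry.retained = retained
    return retained
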