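"""Lesion descriptors: 20 GLCM texture statistics and ABCD shape/colour features.

The gray-level co-occurrence matrix (GLCM) tabulates how often pairs of
quantized gray levels co-occur at a fixed pixel offset; its second-order
statistics (Haralick 1973, Soh & Tsatsoulis 1999, Clausi 2002) summarise
texture.  The ABCD descriptors quantify the clinical melanoma signs:
Asymmetry (reflection mismatch across the principal axes), Border
irregularity, Colour variance (in HSV), and Diameter, plus lesion area and
roundness.

Conventions
-----------
* GLCM quantization: linear binning of [0, 255] into ``levels`` bins
  (default 8); matrices are symmetrized (transpose added) and normalized to
  sum 1; offsets are (dx, dy) = (column, row) displacements.
* GLCM indices ``i, j`` run 1..levels in the statistic formulas (the MATLAB
  convention); logarithms are base 2, so entropies are in bits.
* asymmetry index ASI = 100 * dAK / AL where dAK is half the symmetric
  difference between the lesion and its reflection across a principal axis
  and AL the lesion area; the mean over major and minor axes is the headline
  value.
* border irregularity I = (a*b / (2*pi*(a^2 + b^2))) * (P^2 / A) with a, b
  the major/minor axis lengths of the second-moment ellipse, P the perimeter
  and A the area; I = 1 for a circle.
* diameter = sqrt(4*A/pi), the equivalent-circle diameter.
* roundness = sqrt(4*pi*A / P^2); 1 for a circle, lower for ragged shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.color import rgb2hsv

__all__ = [
    "GlcmMatrix",
    "AsymmetryIndex",
    "ColorVariance",
    "DegenerateShapeError",
    "GLCM_FEATURE_NAMES",
    "ABCD_FEATURE_NAMES",
    "FEATURE_NAMES",
    "STANDARD_OFFSETS",
    "compute_glcm",
    "glcm_statistics",
    "asymmetry_index",
    "border_irregularity",
    "color_variance",
    "area_of_object",
    "lesion_diameter",
    "perimeter",
    "roundness",
    "extract_feature_vector",
]

STANDARD_OFFSETS: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))

GLCM_FEATURE_NAMES = [
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
]

ABCD_FEATURE_NAMES = [
    "asymmetry_index",
    "border_irregularity",
    "color_variance",
    "area",
    "diameter",
    "roundness",
]

FEATURE_NAMES = GLCM_FEATURE_NAMES + ABCD_FEATURE_NAMES


class DegenerateShapeError(ValueError):
    """The mask is too thin/small for the requested shape descriptor."""


@dataclass(frozen=True)
class GlcmMatrix:
    """Normalized, symmetrized co-occurrence matrix for one offset."""

    matrix: np.ndarray
    offset: tuple[int, int]
    levels: int


@dataclass(frozen=True)
class AsymmetryIndex:
    """Reflection asymmetry (percent) across the two principal axes."""

    major_pct: float
    minor_pct: float

    @property
    def mean_pct(self) -> float:
        return 0.5 * (self.major_pct + self.minor_pct)

    def __float__(self) -> float:
        return self.mean_pct


@dataclass(frozen=True)
class ColorVariance:
    """Per-channel HSV dispersion over the lesion.

    hue is the circular variance (1 - resultant length, unitless in [0, 1]);
    saturation variance is on the [0, 1] scale; value variance is in 8-bit
    intensity units squared.
    """

    hue: float
    saturation: float
    value: float


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of [0, 255] into ``levels`` equal-width bins."""
    return (gray.astype(np.int64) * levels) // 256


def compute_glcm(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    offset: tuple[int, int] = (1, 0),
    levels: int = 8,
) -> GlcmMatrix:
    """Co-occurrence counts of quantized gray pairs separated by ``offset``.

    Only pixel pairs with *both* members inside the mask contribute.  The raw
    count matrix is symmetrized (C + C.T) and normalized to sum 1.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    dx, dy = offset
    if dx == 0 and dy == 0:
        raise ValueError("offset must be nonzero")
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    if mask.shape != gray.shape:
        raise ValueError("mask shape must match image")
    if not mask.any():
        raise ValueError("mask is empty")
    q = quantize(gray, levels)
    h, w = gray.shape

    r0s, r0e = max(0, -dy), min(h, h - dy)
    c0s, c0e = max(0, -dx), min(w, w - dx)
    a = q[r0s:r0e, c0s:c0e]
    b = q[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
    m = mask[r0s:r0e, c0s:c0e] & mask[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
    if not m.any():
        raise ValueError("no pixel pairs at the requested offset inside the mask")
    counts = np.bincount(
        (a[m] * levels + b[m]).ravel(), minlength=levels * levels
    ).reshape(levels, levels)
    sym = counts + counts.T
    matrix = sym / sym.sum()
    return GlcmMatrix(matrix=matrix, offset=offset, levels=levels)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_statistics(glcm: GlcmMatrix) -> dict[str, float]:
    """The 20 standard second-order texture statistics of a normalized GLCM.

    Degenerate cases (single-level images) yield correlation = imc1 = 0 rather
    than NaN, keeping feature vectors finite.
    """
    P = np.asarray(glcm.matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError("GLCM must be normalized to sum 1")
    n = P.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    i = idx[:, None] * np.ones((1, n))
    j = np.ones((n, 1)) * idx[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # distributions of i+j (2..2n) and |i-j| (0..n-1)
    sum_idx = (i + j).astype(int)
    diff_idx = np.abs(i - j).astype(int)
    p_sum = np.bincount(sum_idx.ravel(), weights=P.ravel(), minlength=2 * n + 1)[2:]
    p_diff = np.bincount(diff_idx.ravel(), weights=P.ravel(), minlength=n)
    ks = np.arange(2, 2 * n + 1, dtype=float)
    kd = np.arange(0, n, dtype=float)

    autocorrelation = float((i * j * P).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    cluster_prominence = float(((i + j - mu_x - mu_y) ** 4 * P).sum())
    cluster_shade = float(((i + j - mu_x - mu_y) ** 3 * P).sum())
    dissimilarity = float((np.abs(i - j) * P).sum())
    energy = float((P**2).sum())
    entropy = _entropy_bits(P.ravel())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    maximum_probability = float(P.max())
    sum_of_squares = float(((i - mu_x) ** 2 * P).sum())
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy_bits(p_sum)
    diff_mean = float((kd * p_diff).sum())
    difference_variance = float(((kd - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    joint = np.outer(px, py)
    nz = (P > 0) & (joint > 0)
    hxy1 = float(-(P[nz] * np.log2(joint[nz])).sum())
    nzj = joint > 0
    hxy2 = float(-(joint[nzj] * np.log2(joint[nzj])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    inv_diff_norm = float((P / (1.0 + np.abs(i - j) / n)).sum())
    inv_diff_moment_norm = float((P / (1.0 + (i - j) ** 2 / n**2)).sum())

    return {
        "autocorrelation": autocorrelation,
        "contrast": contrast,
        "correlation": correlation,
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "maximum_probability": maximum_probability,
        "sum_of_squares": sum_of_squares,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference_normalized": inv_diff_norm,
        "inverse_difference_moment_normalized": inv_diff_moment_norm,
    }


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axis directions from second moments."""
    coords = np.argwhere(mask)  # (N, 2) rows of (r, c)
    centroid = coords.mean(axis=0)
    if len(coords) < 3:
        return centroid, np.array([1.0, 0.0]), np.array([0.0, 1.0])
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = eigvecs[:, np.argmax(eigvals)]
    minor = eigvecs[:, np.argmin(eigvals)]
    return centroid, major, minor


def _fold_asymmetry_pct(coords: np.ndarray, centroid: np.ndarray, axis: np.ndarray) -> float:
    """ASI for one axis: reflect pixel centers across the axis line, round to
    the grid and take half the symmetric difference over the area."""
    d = coords - centroid
    proj = d @ axis
    reflected = centroid + 2.0 * np.outer(proj, axis) - d
    orig = set(map(tuple, coords))
    refl = set(map(tuple, np.rint(reflected).astype(int)))
    delta = len(orig.symmetric_difference(refl)) / 2.0
    return 100.0 * delta / len(orig)


def asymmetry_index(mask: np.ndarray) -> AsymmetryIndex:
    """Reflection asymmetry across the fitted major and minor axes (percent)."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    coords = np.argwhere(mask)
    centroid, major, minor = _principal_axes(mask)
    return AsymmetryIndex(
        major_pct=_fold_asymmetry_pct(coords, centroid, major),
        minor_pct=_fold_asymmetry_pct(coords, centroid, minor),
    )


def _single_region(mask: np.ndarray):
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    labels = measure.label(mask)
    if labels.max() != 1:
        raise ValueError(f"expected a single-component mask, found {labels.max()} components")
    return measure.regionprops(labels)[0]


def perimeter(mask: np.ndarray, smooth_window: int = 3) -> float:
    """Boundary length from the subpixel 0.5-level contour of the mask.

    The marching-squares contour is traced, its vertices are smoothed with a
    circular moving average (default window 3) to suppress the staircase bias
    of discrete boundaries, and the polygon length is returned.  Near-unbiased
    for smooth shapes (a radius-40 disc measures within ~1% of 2*pi*40); the
    smoothing window is small enough to preserve genuine boundary lobes.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:-1]  # closed contour: drop repeated vertex
    k = smooth_window
    if k > 1 and len(contour) > k:
        kernel = np.ones(k) / k
        n = len(contour)
        smoothed = np.empty_like(contour)
        for d in range(2):
            ext = np.concatenate(
                [contour[-(k // 2):, d], contour[:, d], contour[: k // 2 + 1, d]]
            )
            smoothed[:, d] = np.convolve(ext, kernel, mode="valid")[:n]
        contour = smoothed
    deltas = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.linalg.norm(deltas, axis=1).sum())


def border_irregularity(mask: np.ndarray) -> float:
    """I = (a*b / (2*pi*(a^2+b^2))) * (P^2 / A); 1 for a circle, larger for
    eccentric or ragged borders."""
    prop = _single_region(mask)
    a = prop.axis_major_length
    b = prop.axis_minor_length
    area = prop.area
    if b < 1e-6 or area == 0:
        raise DegenerateShapeError("mask is line-like; border irregularity undefined")
    p = perimeter(mask)
    return float((a * b) / (2.0 * np.pi * (a**2 + b**2)) * p**2 / area)


def color_variance(image: np.ndarray, mask: np.ndarray) -> ColorVariance:
    """HSV channel dispersion over the lesion pixels (hue treated circularly)."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    px = image[mask].astype(float) / 255.0
    hsv = rgb2hsv(px.reshape(-1, 1, 3)).reshape(-1, 3)
    ang = 2.0 * np.pi * hsv[:, 0]
    resultant = abs(np.exp(1j * ang).mean())
    hue_var = float(1.0 - resultant)
    sat_var = float(np.var(hsv[:, 1]))
    val_var = float(np.var(hsv[:, 2] * 255.0))
    return ColorVariance(hue=hue_var, saturation=sat_var, value=val_var)


def area_of_object(mask: np.ndarray) -> int:
    """Foreground pixel count."""
    return int(np.count_nonzero(mask))


def lesion_diameter(mask: np.ndarray) -> float:
    """Equivalent-circle diameter sqrt(4*area/pi); 0 for an empty mask."""
    return float(np.sqrt(4.0 * area_of_object(mask) / np.pi))


def roundness(mask: np.ndarray) -> float:
    """sqrt(4*pi*area / perimeter^2); 1 for a circle (isoperimetric equality)."""
    prop = _single_region(mask)
    p = perimeter(mask)
    if p <= 0:
        raise DegenerateShapeError("mask perimeter is zero")
    return float(np.sqrt(4.0 * np.pi * prop.area) / p)


def extract_feature_vector(
    image: np.ndarray,
    gray: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = STANDARD_OFFSETS,
    image_id: str | None = None,
) -> pd.Series:
    """The full 26-value descriptor: 20 GLCM statistics averaged over the four
    standard offsets, then the six ABCD-derived values.

    The scalar ``color_variance`` feature is the sum of the three HSV channel
    dispersions with the value channel on the [0, 1] scale, a dimensionless
    total colour spread.  Raises if any feature is non-finite, naming it.
    """
    if gray.shape != mask.shape or image.shape[:2] != mask.shape:
        raise ValueError("image, gray and mask shapes disagree")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    stat_sets = [
        glcm_statistics(compute_glcm(gray, mask, offset=off, levels=levels))
        for off in offsets
    ]
    values: dict[str, float] = {
        name: float(np.mean([s[name] for s in stat_sets])) for name in GLCM_FEATURE_NAMES
    }
    cv = color_variance(image, mask)
    values["asymmetry_index"] = asymmetry_index(mask).mean_pct
    values["border_irregularity"] = border_irregularity(mask)
    values["color_variance"] = cv.hue + cv.saturation + cv.value / 255.0**2
    values["area"] = float(area_of_object(mask))
    values["diameter"] = lesion_diameter(mask)
    values["roundness"] = roundness(mask)
    for name, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"feature '{name}' is not finite ({v})")
    return pd.Series([values[n] for n in FEATURE_NAMES], index=FEATURE_NAMES, name=image_id)
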