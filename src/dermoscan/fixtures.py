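"""Synthetic dermoscopy-like images with exact ground truth.

Real dermoscopic images of pigmented lesions show a roughly elliptical blob that
is darker than the surrounding skin, with a fuzzy border, internal texture and
frequently occluding hairs.  This module emulates those properties with a shape
family simple enough to admit exact ground truth: an ellipse whose radius is
modulated by ``amplitude * sin(lobes * theta)``.  Benign lesions are drawn
near-symmetric, smooth and low-texture; malignant ones eccentric, lobed and
noisy, so the two classes are separable in shape/texture feature space.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.morphology import disk, dilation

__all__ = [
    "LesionSpec",
    "SyntheticSample",
    "rasterize_lesion",
    "generate_lesion_image",
    "make_hair_strokes",
    "add_hair_artifacts",
    "generate_dataset",
    "save_dataset",
]

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass(frozen=True)
class LesionSpec:
    """Geometric + photometric description of one synthetic lesion.

    center is (x, y) = (column, row); axes are the (major, minor) semi-axis
    lengths in pixels.  The lesion boundary in the ellipse frame is
    ``m(theta) = 1 + boundary_wobble * sin(wobble_lobes * theta)`` where m is
    the normalised elliptical radius.  ``border_softness`` is the Gaussian
    sigma (px) of the lesion/skin transition, mimicking the gradual fade of
    real lesion borders; the ground-truth mask is always the crisp
    rasterization.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float = 0.0
    boundary_wobble: float = 0.0
    wobble_lobes: int = 5
    lesion_color: tuple[int, int, int] = (120, 80, 60)
    skin_color: tuple[int, int, int] = (205, 165, 145)
    texture_noise_sd: float = 6.0
    label: str = BENIGN
    border_softness: float = 2.0
    skin_noise_sd: float = 4.0

    def __post_init__(self) -> None:
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.axes}")
        if not (0.0 <= self.boundary_wobble < 1.0):
            raise ValueError(
                f"boundary_wobble must be in [0, 1), got {self.boundary_wobble}"
            )
        if self.wobble_lobes < 0:
            raise ValueError("wobble_lobes must be non-negative")
        for name in ("lesion_color", "skin_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= c <= 255) for c in col):
                raise ValueError(f"{name} must be an RGB triple in [0, 255], got {col}")
        if self.texture_noise_sd < 0 or self.skin_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be '{BENIGN}' or '{MALIGNANT}', got {self.label!r}")

    @property
    def max_radius(self) -> float:
        """Largest possible distance from center to boundary, in pixels."""
        return max(self.axes) * (1.0 + self.boundary_wobble)


@dataclass
class SyntheticSample:
    """An image, its exact ground-truth lesion mask, and the spec that made it."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool
    spec: LesionSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValueError("image and truth_mask dimensions disagree")


def rasterize_lesion(spec: LesionSpec, width: int, height: int) -> np.ndarray:
    """Exact per-pixel rasterization of the perturbed ellipse.

    A pixel (row r, col c) is inside iff its normalised elliptical radius m
    satisfies m <= 1 + w*sin(k*theta), with theta the angle in the (rotated)
    ellipse frame.  Pixel centers are at integer coordinates.
    """
    a, b = spec.axes
    cx, cy = spec.center
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    t = np.deg2rad(spec.rotation)
    dx = xx - cx
    dy = yy - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    m = np.hypot(u / a, v / b)
    theta = np.arctan2(v, u)
    limit = 1.0 + spec.boundary_wobble * np.sin(spec.wobble_lobes * theta)
    return m <= limit


def generate_lesion_image(
    spec: LesionSpec, width: int = 256, height: int = 256, seed: int = 0
) -> SyntheticSample:
    """Render one lesion on skin with noise; deterministic for a fixed seed."""
    cx, cy = spec.center
    r = spec.max_radius
    if cx - r < 0 or cy - r < 0 or cx + r > width - 1 or cy + r > height - 1:
        raise ValueError(
            f"lesion geometry (center {spec.center}, max radius {r:.1f}) does not fit "
            f"inside a {width}x{height} image"
        )
    rng = np.random.default_rng(seed)
    mask = rasterize_lesion(spec, width, height)
    img = np.where(
        mask[..., None],
        np.asarray(spec.lesion_color, dtype=float),
        np.asarray(spec.skin_color, dtype=float),
    )
    if spec.border_softness > 0:
        img = ndi.gaussian_filter(img, (spec.border_softness, spec.border_softness, 0))
    sd = np.where(mask, spec.texture_noise_sd, spec.skin_noise_sd)
    img = img + rng.standard_normal(img.shape) * sd[..., None]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, truth_mask=mask, spec=spec, seed=seed)


def _stroke_width_footprint(width_px: int) -> np.ndarray | None:
    if width_px <= 1:
        return None
    if width_px == 2:
        return np.ones((2, 2), dtype=bool)
    return disk(1)


def make_hair_strokes(
    shape: tuple[int, int], n_hairs: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, tuple[int, int, int]]]:
    """Rasterize ``n_hairs`` dark curvilinear strokes for an image of ``shape``.

    Each stroke is a quadratic Bezier from one image border region to another,
    1-3 px wide, with a dark brown colour jittered per hair.  Returns a list of
    (boolean stroke mask, RGB colour) pairs, in draw order.
    """
    h, w = shape
    strokes: list[tuple[np.ndarray, tuple[int, int, int]]] = []
    for _ in range(n_hairs):
        # endpoints near opposite halves of the frame so hairs span the image
        p0 = np.array([rng.uniform(0, h - 1), rng.uniform(0, 0.3 * (w - 1))])
        p2 = np.array([rng.uniform(0, h - 1), rng.uniform(0.7 * (w - 1), w - 1)])
        if rng.random() < 0.5:  # half the hairs run top-to-bottom instead
            p0 = p0[::-1]
            p2 = p2[::-1]
        mid = (p0 + p2) / 2
        bow = rng.uniform(-0.35, 0.35) * np.linalg.norm(p2 - p0)
        normal = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
        norm = np.linalg.norm(normal)
        p1 = mid + bow * normal / norm if norm > 0 else mid
        n_steps = int(4 * np.hypot(h, w))
        t = np.linspace(0.0, 1.0, n_steps)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        fp = _stroke_width_footprint(int(rng.integers(1, 4)))
        if fp is not None:
            mask = dilation(mask, fp)
        base = np.array([35, 25, 20], dtype=float)
        color = np.clip(base + rng.uniform(-10, 10, size=3), 0, 255).astype(int)
        strokes.append((mask, tuple(int(c) for c in color)))
    return strokes


def add_hair_artifacts(sample: SyntheticSample, n_hairs: int, seed: int = 0) -> SyntheticSample:
    """Composite ``n_hairs`` opaque hair strokes over a sample's image.

    The ground-truth mask is unchanged; stroke pixels are set to the hair
    colour exactly (no blending), so the set of modified pixels equals the
    union of the rasterized strokes wherever the hair colour differs from the
    underlying image.
    """
    if n_hairs < 0:
        raise ValueError(f"n_hairs must be non-negative, got {n_hairs}")
    img = sample.image.copy()
    rng = np.random.default_rng(seed)
    for mask, color in make_hair_strokes(img.shape[:2], n_hairs, rng):
        img[mask] = color
    return SyntheticSample(
        image=img, truth_mask=sample.truth_mask, spec=sample.spec, seed=sample.seed
    )


def _draw_spec(label: str, rng: np.random.Generator, width: int, height: int) -> LesionSpec:
    """Sample a per-class lesion spec.

    Benign: near-circular, smooth border, low texture noise, lighter brown.
    Malignant: eccentric, strongly lobed border, high texture noise, darker.
    The gaps are chosen so shape (roundness/asymmetry) and texture statistics
    separate the classes, echoing the clinical ABCD signs.  Lesion geometry
    scales with the image size (reference 256 px).
    """
    scale = min(width, height) / 256.0
    cx = width / 2 + rng.uniform(-8, 8) * scale
    cy = height / 2 + rng.uniform(-8, 8) * scale
    rotation = rng.uniform(0, 180)
    skin = tuple(
        int(np.clip(c + rng.uniform(-8, 8), 0, 255)) for c in (205, 165, 145)
    )
    if label == BENIGN:
        a = rng.uniform(38, 52) * scale
        b = a * rng.uniform(0.85, 1.0)
        wobble = rng.uniform(0.04, 0.12)
        lobes = int(rng.integers(4, 7))
        lesion = tuple(
            int(np.clip(c + rng.uniform(-10, 10), 0, 255)) for c in (125, 85, 60)
        )
        noise_sd = rng.uniform(4, 8)
    elif label == MALIGNANT:
        a = rng.uniform(40, 54) * scale
        b = a * rng.uniform(0.55, 0.80)
        wobble = rng.uniform(0.25, 0.35)
        lobes = int(rng.integers(6, 10))
        lesion = tuple(
            int(np.clip(c + rng.uniform(-10, 10), 0, 255)) for c in (70, 45, 35)
        )
        noise_sd = rng.uniform(16, 24)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown label {label!r}")
    return LesionSpec(
        center=(cx, cy),
        axes=(a, b),
        rotation=rotation,
        boundary_wobble=wobble,
        wobble_lobes=lobes,
        lesion_color=lesion,
        skin_color=skin,
        texture_noise_sd=noise_sd,
        label=label,
    )


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    seed: int = 0,
    width: int = 256,
    height: int = 256,
    hair_range: tuple[int, int] = (0, 6),
) -> list[SyntheticSample]:
    """Generate a labeled synthetic dataset (benign first, then malignant).

    Each sample gets 0-6 overlaid hairs by default (``hair_range`` is an
    inclusive range).  Deterministic for a fixed seed.
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("sample counts must be non-negative")
    master = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    labels = [BENIGN] * n_benign + [MALIGNANT] * n_malignant
    for label in labels:
        sample_seed = int(master.integers(2**31))
        rng = np.random.default_rng(sample_seed)
        spec = _draw_spec(label, rng, width, height)
        sample = generate_lesion_image(spec, width, height, seed=sample_seed)
        n_hairs = int(rng.integers(hair_range[0], hair_range[1] + 1))
        if n_hairs:
            sample = add_hair_artifacts(sample, n_hairs, seed=sample_seed + 1)
        sample.seed = sample_seed
        samples.append(sample)
    return samples


def save_dataset(samples: Sequence[SyntheticSample], outdir: str | Path) -> Path:
    """Write image/mask PNG pairs and a manifest CSV; returns the manifest path.

    Manifest columns: path, mask_path, label, seed (paths relative to outdir).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_name = f"img_{i:04d}.png"
        mask_name = f"mask_{i:04d}.png"
        Image.fromarray(s.image).save(outdir / img_name)
        Image.fromarray((s.truth_mask.astype(np.uint8)) * 255).save(outdir / mask_name)
        rows.append(
            {
                "path": img_name,
                "mask_path": mask_name,
                "label": s.spec.label,
                "seed": s.seed if s.seed is not None else "",
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
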