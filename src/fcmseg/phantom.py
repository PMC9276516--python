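"""Synthetic brain-slice phantoms with known ground truth.

Patient MR data cannot ship with a library, so every algorithm and
metric here is exercised on phantoms: images built from a geometric
label map (the ground truth), per-class mean intensities, an optional
smooth multiplicative bias field, and seeded additive Gaussian noise.
The default contrast emulates a T1-weighted axial slice — dark CSF
(0.2), mid-gray GM (0.5), bright WM (0.8).

Geometries
----------
``concentric``
    Nested ellipses, classes darkest outside to brightest inside.
``blobs``
    Random disks of the upper classes on a darkest-class background.
``slice-like``
    A head ellipse with a CSF rim and central ventricle; the interior
    GM/WM boundary is carved by thresholded smoothed noise, producing
    the convoluted cortical-style boundary and class imbalance of a
    real slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import InvalidInputError
from .exceptions import InvalidConfigError

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cluster_points"]

GEOMETRIES = ("concentric", "blobs", "slice-like")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic brain slice.

    ``class_means`` must be strictly increasing within [0, 1];
    ``class_sigma`` is the additive Gaussian noise level (intensity
    units on the [0, 1] scale); ``bias_amplitude`` is the peak relative
    deviation of a smooth multiplicative bias field (0 disables it).
    """

    shape: tuple[int, int] = (128, 128)
    class_means: tuple[float, ...] = (0.2, 0.5, 0.8)
    class_sigma: float = 0.0
    bias_amplitude: float = 0.0
    geometry: str = "slice-like"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_means) < 2:
            raise InvalidConfigError("a phantom needs at least 2 classes")
        means = np.asarray(self.class_means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise InvalidConfigError("class_means must be strictly increasing")
        if means.min() < 0 or means.max() > 1:
            raise InvalidConfigError("class_means must lie within [0, 1]")
        if self.class_sigma < 0:
            raise InvalidConfigError("class_sigma must be >= 0")
        if not 0.0 <= self.bias_amplitude < 0.5:
            raise InvalidConfigError("bias_amplitude must be in [0, 0.5)")
        if self.geometry not in GEOMETRIES:
            raise InvalidConfigError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )
        if len(self.shape) != 2 or min(self.shape) < 8:
            raise InvalidConfigError("shape must be 2-D, at least 8x8")


@dataclass
class Phantom:
    """A generated image together with its ground-truth label map."""

    image: np.ndarray
    truth: np.ndarray
    spec: PhantomSpec
    noiseless: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _unit_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = shape
    y = np.linspace(-1.0, 1.0, rows)[:, None]
    x = np.linspace(-1.0, 1.0, cols)[None, :]
    return y, x


def _truth_concentric(spec: PhantomSpec) -> np.ndarray:
    y, x = _unit_coords(spec.shape)
    r = np.sqrt((x / 0.95) ** 2 + (y / 0.95) ** 2)
    c = len(spec.class_means)
    # class 0 outside, innermost ellipse gets the brightest class
    edges = np.linspace(1.0, 0.0, c + 1)[1:-1]
    truth = np.zeros(spec.shape, dtype=np.intp)
    for k, edge in enumerate(edges, start=1):
        truth[r <= edge] = k
    return truth


def _truth_blobs(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    y, x = _unit_coords(spec.shape)
    c = len(spec.class_means)
    truth = np.zeros(spec.shape, dtype=np.intp)
    for k in range(1, c):
        for _ in range(3):
            cy, cx = rng.uniform(-0.6, 0.6, size=2)
            radius = rng.uniform(0.15, 0.3)
            truth[(x - cx) ** 2 + (y - cy) ** 2 <= radius**2] = k
    return truth


def _truth_slice_like(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Head ellipse + CSF rim/ventricle + convoluted GM/WM split."""
    y, x = _unit_coords(spec.shape)
    c = len(spec.class_means)
    head = (x / 0.85) ** 2 + (y / 0.95) ** 2 <= 1.0
    inner = (x / 0.75) ** 2 + (y / 0.85) ** 2 <= 1.0  # inside the CSF rim
    ventricle = (x / 0.12) ** 2 + (y / 0.25) ** 2 <= 1.0

    truth = np.zeros(spec.shape, dtype=np.intp)  # class 0: background + CSF
    field_ = gaussian_filter(rng.standard_normal(spec.shape), sigma=4.0)
    interior = head & inner & ~ventricle
    if c == 2:
        truth[interior] = 1
        return truth
    # split interior between GM (1) and WM (2) with realistic imbalance
    thr = np.percentile(field_[interior], 45.0)
    gm = interior & (field_ <= thr)
    wm = interior & (field_ > thr)
    truth[gm] = 1
    truth[wm] = 2
    # any extra classes beyond 3 become nested bright cores
    for k in range(3, c):
        core = (x / (0.4 / (k - 1))) ** 2 + ((y - 0.3) / (0.3 / (k - 1))) ** 2 <= 1.0
        truth[core & interior] = k
    return truth


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, 1 +/- bias_amplitude at its extremes."""
    y, x = _unit_coords(spec.shape)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    raw = np.sin(np.pi * x / 2.0 + p1) * np.sin(np.pi * y / 2.0 + p2)
    return 1.0 + spec.bias_amplitude * raw


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build a phantom from its spec; identical seeds give identical arrays.

    Pipeline: geometric label map -> per-class mean intensities ->
    optional smooth multiplicative bias -> seeded additive Gaussian
    noise -> clip to [0, 1] (noise tails are slightly truncated at the
    intensity bounds).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "concentric":
        truth = _truth_concentric(spec)
    elif spec.geometry == "blobs":
        truth = _truth_blobs(spec, rng)
    else:
        truth = _truth_slice_like(spec, rng)

    means = np.asarray(spec.class_means, dtype=float)
    clean = means[truth]
    if spec.bias_amplitude > 0:
        clean = clean * _bias_field(spec, rng)
    image = clean.copy()
    if spec.class_sigma > 0:
        image = image + rng.normal(0.0, spec.class_sigma, size=spec.shape)
    image = np.clip(image, 0.0, 1.0)
    return Phantom(image=image, truth=truth, spec=spec, noiseless=clean)


def generate_cluster_points(
    n: int, means: Sequence[float], sigma: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 1-D Gaussian mixture with equal component weights.

    Returns ``(features, labels)`` where ``labels`` are the generating
    component indices.  Used as a small fixture for clustering and PSO
    tests.
    """
    means = np.asarray(means, dtype=float)
    if n < means.size:
        raise InvalidInputError(f"need n >= {means.size} points, got {n}")
    if sigma < 0:
        raise InvalidInputError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n, dtype=np.intp) % means.size
    x = means[labels] + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)
    return x, labels
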