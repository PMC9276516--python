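"""Image loading, normalization and artifact writing.

All images are brought to a common substrate before clustering: a 2-D
float array normalized to [0, 1] by the min-max rule, with the
normalization parameters recorded so intensities can be mapped back.
Supported inputs are 8/16-bit grayscale PNG/TIFF and NIfTI volumes or
slices (a slice index selects an axial slice from a 3-D volume).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "GrayImage",
    "load_image",
    "save_image_png",
    "save_labels_png",
    "load_labels_png",
    "LABEL_PALETTE",
]

#: Fixed label palette for visual diffing: background/CSF, GM, WM, extra.
LABEL_PALETTE = [
    (0, 0, 0),        # 0: background / CSF (dark)
    (128, 128, 128),  # 1: gray matter
    (255, 255, 255),  # 2: white matter
    (255, 64, 64),    # 3+: additional classes
    (64, 64, 255),
    (64, 255, 64),
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class GrayImage:
    """A normalized 2-D gray image plus its provenance record."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _normalize(raw: np.ndarray, provenance: dict) -> GrayImage:
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise InvalidInputError("image contains non-finite values")
    vmin, vmax = float(raw.min()), float(raw.max())
    provenance.update({"vmin": vmin, "vmax": vmax})
    if vmax == vmin:
        logger.warning("constant image: normalization degenerate, defined as zeros")
        provenance["constant"] = True
        return GrayImage(np.zeros_like(raw), provenance)
    return GrayImage((raw - vmin) / (vmax - vmin), provenance)


def load_image(path: str | Path, slice_index: int | None = None) -> GrayImage:
    """Load a PNG/TIFF/NIfTI image, min-max normalized to [0, 1].

    For a 3-D NIfTI volume ``slice_index`` selects an axial slice (last
    axis); it is required in that case.  The source path, dtype and
    normalization parameters are recorded in ``provenance``.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    name = path.name.lower()
    prov: dict = {"path": str(path)}

    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim == 3:
            if slice_index is None:
                raise InvalidInputError(
                    f"{path} is a 3-D volume; a slice index is required"
                )
            if not 0 <= slice_index < data.shape[2]:
                raise InvalidInputError(
                    f"slice index {slice_index} out of range for {data.shape}"
                )
            prov["slice_index"] = slice_index
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise InvalidInputError(
                f"NIfTI data of shape {data.shape} is not a 2-D slice"
            )
        prov["format"] = "nifti"
        return _normalize(data, prov)

    if name.endswith(_RASTER_SUFFIXES):
        import imageio.v3 as iio

        raw = iio.imread(path)
        if raw.ndim == 3 and raw.shape[-1] in (3, 4):
            rgb = raw[..., :3]
            if not (rgb[..., 0] == rgb[..., 1]).all() or not (
                rgb[..., 1] == rgb[..., 2]
            ).all():
                raise InvalidInputError(
                    f"{path}: color images are unsupported (grayscale PNG/TIFF only)"
                )
            raw = rgb[..., 0]
        if raw.ndim != 2:
            raise InvalidInputError(f"{path}: expected a 2-D grayscale image")
        if raw.dtype not in (np.uint8, np.uint16):
            raise InvalidInputError(
                f"{path}: unsupported bit depth {raw.dtype} (8/16-bit grayscale only)"
            )
        prov["format"] = "png/tiff"
        prov["dtype"] = str(raw.dtype)
        return _normalize(raw, prov)

    raise InvalidInputError(
        f"unsupported image format: {path} (PNG, TIFF or NIfTI expected)"
    )


def save_image_png(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def save_labels_png(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as a paletted PNG with the fixed tissue palette."""
    from PIL import Image

    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() >= len(LABEL_PALETTE):
        raise InvalidInputError(
            f"labels must lie in [0, {len(LABEL_PALETTE)}) for the fixed palette"
        )
    im = Image.fromarray(lab.astype(np.uint8), mode="P")
    palette = [v for rgb in LABEL_PALETTE for v in rgb]
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(Path(path))


def load_labels_png(path: str | Path) -> np.ndarray:
    """Read a label map written by :func:`save_labels_png` (or any indexed PNG)."""
    from PIL import Image

    with Image.open(Path(path)) as im:
        if im.mode != "P":
            im = im.convert("L")
        return np.asarray(im, dtype=np.intp)
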