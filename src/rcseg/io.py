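"""Image and mask I/O for multimodal (FLU/VIS) plant phenotyping data.

Images are held internally as floating-point RGB arrays on the [0, 1]
scale regardless of the source bit depth (8- or 16-bit); every formula
downstream is written against this scale.  Pixel coordinates are 0-based
``(row, col)`` with the origin at the top-left corner.  Binary masks are
stored on disk as 8-bit single-channel PNG with 0 = background and
255 = plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

#: Recognized camera modalities.
MODALITIES = ("FLU", "VIS")


@dataclass
class RasterImage:
    """An RGB raster image normalized to the [0, 1] scale.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array with every channel value in [0, 1].
    bit_depth_source
        Bit depth of the file the image was loaded from (8 or 16).
    modality
        Camera modality tag, ``"FLU"`` or ``"VIS"`` (optional).
    """

    pixels: np.ndarray
    bit_depth_source: int = 8
    modality: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must have at least one row and one column")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("channel values must lie in [0, 1]")
        if self.bit_depth_source not in (8, 16):
            raise ValidationError("bit_depth_source must be 8 or 16")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """Image height and width."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A boolean per-pixel mask tied to one modality frame."""

    pixels: np.ndarray
    frame: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {px.shape}")
        self.pixels = px.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())


@dataclass
class MultimodalPair:
    """One FLU/VIS image pair plus the matching empty-background references.

    The FLU and VIS frames may have different sizes (the two cameras need
    not share a sensor), but each image must match its own reference.
    """

    flu: RasterImage
    vis: RasterImage
    flu_ref: RasterImage
    vis_ref: RasterImage
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flu.shape != self.flu_ref.shape:
            raise ValidationError(
                f"FLU image {self.flu.shape} does not match its reference "
                f"{self.flu_ref.shape}"
            )
        if self.vis.shape != self.vis_ref.shape:
            raise ValidationError(
                f"VIS image {self.vis.shape} does not match its reference "
                f"{self.vis_ref.shape}"
            )


def _normalize(arr: np.ndarray, path: str | Path) -> tuple[np.ndarray, int]:
    """Map a decoded array to float RGB in [0, 1]; return (pixels, bit depth)."""
    if arr.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        depth, scale = 16, 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        depth, scale = 8, 1.0
    else:
        raise InputError(f"unsupported pixel dtype {arr.dtype} in {path}")
    px = arr.astype(np.float64) / scale
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise InputError(f"cannot interpret {path} with shape {arr.shape} as RGB")
    return np.clip(px, 0.0, 1.0), depth


def load_image(path: str | Path, modality: str | None = None) -> RasterImage:
    """Load a PNG/TIFF image and normalize it to the internal representation."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoding failure
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    px, depth = _normalize(arr, path)
    return RasterImage(px, bit_depth_source=depth, modality=modality)


def load_pair(
    flu_path: str | Path,
    vis_path: str | Path,
    flu_ref_path: str | Path,
    vis_ref_path: str | Path,
) -> MultimodalPair:
    """Load a FLU/VIS pair and its reference images from disk.

    Raises :class:`~rcseg.errors.InputError` when a file is missing and
    :class:`~rcseg.errors.ValidationError` when an image does not match
    the dimensions of its own reference.
    """
    return MultimodalPair(
        flu=load_image(flu_path, "FLU"),
        vis=load_image(vis_path, "VIS"),
        flu_ref=load_image(flu_ref_path, "FLU"),
        vis_ref=load_image(vis_ref_path, "VIS"),
    )


def make_reference_from_color(
    height: int, width: int, rgb_color, modality: str | None = None
) -> RasterImage:
    """Synthesize a constant-color reference image.

    Users without recorded empty-background frames can approximate them
    with a black FLU and a light-gray VIS reference.
    """
    if height < 1 or width < 1:
        raise ValidationError("reference image must have positive dimensions")
    color = np.asarray(rgb_color, dtype=np.float64)
    if color.shape != (3,) or color.min() < 0.0 or color.max() > 1.0:
        raise ValidationError("rgb_color must be three components in [0, 1]")
    px = np.broadcast_to(color, (height, width, 3)).copy()
    return RasterImage(px, modality=modality)


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF (values rounded from the [0,1] scale)."""
    arr = np.rint(image.pixels * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as single-channel 8-bit PNG, 0=background / 255=plant."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_mask(path: str | Path, frame: str | None = None) -> BinaryMask:
    """Read a mask written by :func:`save_mask` (any value > 127 is plant)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask(arr > 127, frame=frame)
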