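"""Reading, pairing, and writing of single-channel image batches.

The analysis consumes two folders of 2-D fluorescence images: a MARKER
channel (a nuclear or cell marker such as DAPI, NeuN, or TDP-43) and a
DNA-damage channel (a damage marker such as gamma-H2AX).  Images are paired
positionally after a lexicographic sort of the filenames in each folder,
normalised to 8-bit grayscale, and carried through the pipeline as plain
``uint8`` numpy arrays wrapped in :class:`GrayImage`.

Diagnostic outputs (label maps and overlays) are always written as lossless
8-bit RGB PNG regardless of the input format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import (
    BatchMismatchError,
    DecodeError,
    EmptyBatchError,
    InvalidInputError,
    ShapeMismatchError,
)

logger = logging.getLogger(__name__)

#: File extensions accepted as batch members (JPEG, PNG, TIFF).
IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}

#: BT.601 luminance weights used to collapse RGB inputs to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Fixed colour palette for rendering label maps; label ``k`` is drawn with
#: ``PALETTE[(k - 1) % len(PALETTE)]``, background stays black.
PALETTE = np.array(
    [
        (230, 25, 75),
        (60, 180, 75),
        (255, 225, 25),
        (0, 130, 200),
        (245, 130, 48),
        (145, 30, 180),
        (70, 240, 240),
        (240, 50, 230),
        (210, 245, 60),
        (250, 190, 212),
        (0, 128, 128),
        (220, 190, 255),
        (170, 110, 40),
        (255, 250, 200),
        (128, 0, 0),
        (170, 255, 195),
        (128, 128, 0),
        (255, 215, 180),
        (0, 0, 128),
        (128, 128, 128),
    ],
    dtype=np.uint8,
)


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit raster plus the name of the file it came from."""

    pixels: np.ndarray  # uint8, shape (H, W)
    source_name: str = ""

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.size == 0:
            raise InvalidInputError(
                f"grayscale image must be non-empty 2-D, got shape {p.shape}"
            )
        if p.dtype != np.uint8:
            raise InvalidInputError(f"grayscale image must be uint8, got {p.dtype}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ChannelBatch:
    """Positionally paired marker/damage images from two input folders."""

    pairs: tuple[tuple[GrayImage, GrayImage], ...]
    marker_dir: Path = field(default=Path("."))
    damage_dir: Path = field(default=Path("."))

    def __len__(self) -> int:
        return len(self.pairs)


def _to_uint8(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse channels and rescale bit depth to a uint8 2-D raster."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise DecodeError(f"{path}: unsupported channel count {arr.shape[2]}")
        if arr.dtype == np.uint16:
            arr = np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5)
        luma = arr.astype(np.float64) @ _LUMA
        return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)
    if arr.ndim != 2:
        raise DecodeError(f"{path}: expected 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        scaled = np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5)
        return scaled.astype(np.uint8)
    if np.issubdtype(arr.dtype, np.bool_):
        return arr.astype(np.uint8) * 255
    raise DecodeError(f"{path}: unsupported pixel dtype {arr.dtype}")


def load_gray_image(path: str | Path) -> GrayImage:
    """Load a JPEG/PNG/TIFF file as an 8-bit grayscale image.

    RGB inputs are converted by BT.601 luminance weighting
    (0.299 R + 0.587 G + 0.114 B, rounded half-up); 16-bit rasters are
    linearly rescaled so 65535 maps to 255.
    """
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific failure
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    if arr.size == 0:
        raise InvalidInputError(f"{path}: zero-sized image")
    return GrayImage(_to_uint8(arr, path), source_name=path.name)


def list_image_files(directory: str | Path) -> list[Path]:
    """Image files in a directory, sorted lexicographically by filename."""
    directory = Path(directory)
    if not directory.is_dir():
        raise InvalidInputError(f"not a directory: {directory}")
    files = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    return sorted(files, key=lambda p: p.name)


def discover_batch(marker_dir: str | Path, damage_dir: str | Path) -> ChannelBatch:
    """Enumerate, pair, load, and shape-check the two input folders.

    Files are paired by rank after a lexicographic sort of each folder's
    filenames.  A warning is logged when the stripped basenames of a pair
    differ, since that usually means the folders are not parallel exports.
    """
    marker_dir, damage_dir = Path(marker_dir), Path(damage_dir)
    marker_files = list_image_files(marker_dir)
    damage_files = list_image_files(damage_dir)
    if not marker_files or not damage_files:
        empty = marker_dir if not marker_files else damage_dir
        raise EmptyBatchError(f"no images found in {empty}")
    if len(marker_files) != len(damage_files):
        raise BatchMismatchError(
            f"unequal image counts: {len(marker_files)} marker images in "
            f"{marker_dir} vs {len(damage_files)} damage images in {damage_dir}"
        )
    pairs = []
    for mf, df in zip(marker_files, damage_files):
        if mf.stem != df.stem:
            logger.warning("pairing files with differing basenames: %s / %s", mf.name, df.name)
        marker, damage = load_gray_image(mf), load_gray_image(df)
        if marker.pixels.shape != damage.pixels.shape:
            raise ShapeMismatchError(
                f"shape mismatch: {mf.name} is {marker.pixels.shape}, "
                f"{df.name} is {damage.pixels.shape}"
            )
        pairs.append((marker, damage))
    return ChannelBatch(tuple(pairs), marker_dir=marker_dir, damage_dir=damage_dir)


def label_colors(labels: np.ndarray) -> np.ndarray:
    """Render an integer label map as an RGB array via the fixed palette."""
    labels = np.asarray(labels)
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    fg = labels > 0
    if fg.any():
        rgb[fg] = PALETTE[(labels[fg] - 1) % len(PALETTE)]
    return rgb


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as a colour PNG (background black)."""
    iio.imwrite(Path(path), label_colors(labels), extension=".png")


def write_overlay(raw: GrayImage, foci_labels: np.ndarray, path: str | Path) -> None:
    """Write the raw image in grayscale with labelled pixels re-coloured."""
    foci_labels = np.asarray(foci_labels)
    if raw.pixels.shape != foci_labels.shape:
        raise InvalidInputError(
            f"overlay shape mismatch: raw {raw.pixels.shape} vs labels {foci_labels.shape}"
        )
    rgb = np.repeat(raw.pixels[:, :, None], 3, axis=2)
    fg = foci_labels > 0
    if fg.any():
        rgb[fg] = PALETTE[(foci_labels[fg] - 1) % len(PALETTE)]
    iio.imwrite(Path(path), rgb, extension=".png")
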