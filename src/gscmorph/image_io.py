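"""Label-mask and image-stack I/O, projections, and centered single-cell crops.

The crop extraction mirrors the segmentation-to-morphometrics hand-off of
the analysis pipeline: every labelled cell is placed singularly at the
center of a fresh square array whose side is the largest bounding-box side
over all kept cells, so downstream feature extraction sees one cell per
array on a common canvas.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from gscmorph.errors import FormatError, ValidationError

__all__ = [
    "CellCrop",
    "LabelImage",
    "ZStack",
    "extract_cell_crops",
    "max_intensity_projection",
    "read_label_tiff",
    "write_label_tiff",
    "write_crop_manifest",
]

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 1.0


@dataclass
class LabelImage:
    """Integer-labelled segmentation output (0 = background)."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("label image must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError("label image must be integer-typed")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("labels must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def labels(self) -> np.ndarray:
        vals = np.unique(self.pixels)
        return vals[vals > 0]


@dataclass
class ZStack:
    """Multi-plane intensity stack (plane, row, col)."""

    planes: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValidationError("stack must be 3-D with at least one plane")


@dataclass
class CellCrop:
    """A single cell centered in its own square binary array.

    ``offset`` is the (row, col) of the crop origin in the source image, so
    ``source[r + offset[0], c + offset[1]]`` corresponds to ``mask[r, c]``.
    Border-touching and multi-component source labels are kept but flagged.
    """

    mask: np.ndarray
    source_label: int
    offset: tuple[int, int]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    border: bool = False
    n_components: int = 1

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def write_label_tiff(image: LabelImage, path: str | Path) -> None:
    """Write a label image as a single-page unsigned-integer TIFF.

    The pixel size is stored as JSON in the ImageDescription tag so the
    round trip is bit-exact, metadata included.
    """
    pixels = image.pixels
    if pixels.size and pixels.max() > np.iinfo(np.uint32).max:
        raise ValidationError("labels exceed uint32 range")
    dtype = np.uint16 if (pixels.size == 0 or pixels.max() <= 65535) else np.uint32
    tifffile.imwrite(
        str(path),
        pixels.astype(dtype),
        description=json.dumps({"pixel_size_um": image.pixel_size_um}),
    )


def read_label_tiff(path: str | Path) -> LabelImage:
    """Read a single-page integer TIFF written by :func:`write_label_tiff`.

    Float-typed or RGB TIFFs raise :class:`FormatError`.  When no pixel-size
    metadata is present, 1.0 µm/px is assumed with a logged warning.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        description = page.tags.get("ImageDescription")
        desc_value = description.value if description is not None else ""
    if data.ndim == 3:
        raise FormatError(f"{path}: multi-channel (RGB) TIFF is not a label mask")
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: float-typed TIFF is not a label mask")
    pixel_size = None
    try:
        meta = json.loads(desc_value)
        pixel_size = float(meta["pixel_size_um"])
    except (json.JSONDecodeError, TypeError, KeyError, ValueError):
        pass
    if pixel_size is None:
        logger.warning("%s: no pixel-size metadata, assuming 1.0 um/px", path)
        pixel_size = DEFAULT_PIXEL_SIZE_UM
    return LabelImage(pixels=data.astype(np.int64), pixel_size_um=pixel_size)


def max_intensity_projection(stack: ZStack) -> np.ndarray:
    """Per-pixel maximum over planes (the usual MIP of a confocal stack)."""
    if stack.planes.shape[0] < 1:
        raise ValidationError("cannot project an empty stack")
    return stack.planes.max(axis=0)


def extract_cell_crops(label: LabelImage, min_area_px: int = 50) -> list[CellCrop]:
    """Center every sufficiently large labelled cell in its own square array.

    All returned crops share one side length: the largest bounding-box side
    over the kept cells.  Each cell's bounding box is centered in the square,
    which places the cell centroid at the array center up to the cell's own
    asymmetry.  Labels touching the image border or split into several
    connected components are flagged (callers typically exclude them from
    morphometrics).  Returns an empty list when nothing survives the area
    filter.
    """
    pixels = label.pixels
    rows, cols = pixels.shape
    props = [p for p in regionprops(pixels) if p.area >= min_area_px]
    if not props:
        return []
    side = max(max(p.bbox[2] - p.bbox[0], p.bbox[3] - p.bbox[1]) for p in props)

    crops = []
    for p in props:
        r0, c0, r1, c1 = p.bbox
        h, w = r1 - r0, c1 - c0
        cell = pixels[r0:r1, c0:c1] == p.label
        pad_r, pad_c = (side - h) // 2, (side - w) // 2
        mask = np.zeros((side, side), dtype=bool)
        mask[pad_r : pad_r + h, pad_c : pad_c + w] = cell
        border = r0 == 0 or c0 == 0 or r1 == rows or c1 == cols
        n_comp = int(cc_label(cell, connectivity=2).max())
        crops.append(
            CellCrop(
                mask=mask,
                source_label=int(p.label),
                offset=(r0 - pad_r, c0 - pad_c),
                pixel_size_um=label.pixel_size_um,
                border=border,
                n_components=n_comp,
            )
        )
        if n_comp != 1:
            warnings.warn(
                f"label {p.label} has {n_comp} connected components", stacklevel=2
            )
    return crops


def write_crop_manifest(crops: list[CellCrop], path: str | Path) -> pd.DataFrame:
    """Write the crop manifest CSV (label, offset, area, flags) and return it."""
    df = pd.DataFrame(
        {
            "label": [c.source_label for c in crops],
            "offset_row": [c.offset[0] for c in crops],
            "offset_col": [c.offset[1] for c in crops],
            "area_px": [c.area_px for c in crops],
            "border_flag": [c.border for c in crops],
            "n_components": [c.n_components for c in crops],
        }
    )
    df.to_csv(path, index=False)
    return df
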