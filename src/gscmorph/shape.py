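"""Whole-cell shape descriptors from a binary mask.

Features follow the moment-ellipse convention: the major and minor axis
lengths are ``4 * sqrt(eigenvalue)`` of the central second-moment matrix
(the convention of ``skimage.measure.regionprops``, which the original
analysis used), eccentricity is derived from the axes, and the perimeter is
the weighted boundary-step estimator of ``regionprops``.  All outputs are in
µm / µm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from gscmorph.errors import ValidationError
from gscmorph.image_io import CellCrop

__all__ = ["ShapeFeatures", "compute_shape_features"]

_ECC_CAP = 1.0 - 1e-12
_RATIO_FLOOR = 1e-12


@dataclass
class ShapeFeatures:
    """Moment-ellipse descriptors of a single cell.

    ``eccentricity`` is 0 for a circle and approaches 1 for a line-like
    shape; ``axis_ratio`` is minor/major, the complementary elongation
    measure.
    """

    area_um2: float
    perimeter_um: float
    major_axis_um: float
    minor_axis_um: float
    eccentricity: float
    axis_ratio: float


def compute_shape_features(
    mask: np.ndarray | CellCrop, pixel_size_um: float | None = None
) -> ShapeFeatures:
    """Compute shape descriptors for one single-component binary mask.

    Accepts either a boolean array (with ``pixel_size_um``) or a
    :class:`CellCrop` (whose own pixel size is used unless overridden).
    Raises on empty, multi-component, or sub-5-pixel masks, whose central
    moments are degenerate.
    """
    if isinstance(mask, CellCrop):
        if pixel_size_um is None:
            pixel_size_um = mask.pixel_size_um
        mask = mask.mask
    if pixel_size_um is None:
        pixel_size_um = 1.0
    if not pixel_size_um > 0:
        raise ValidationError("pixel_size_um must be > 0")
    mask = np.asarray(mask, dtype=bool)

    n_comp = int(cc_label(mask, connectivity=2).max())
    if n_comp == 0:
        raise ValidationError("mask is empty")
    if n_comp > 1:
        raise ValidationError(f"mask has {n_comp} connected components, expected 1")
    if mask.sum() < 5:
        raise ValidationError("mask has fewer than 5 pixels (degenerate moments)")

    (props,) = regionprops(mask.astype(np.uint8))
    major_px = float(props.axis_major_length)
    minor_px = float(props.axis_minor_length)

    if major_px <= 0:
        raise ValidationError("degenerate mask: zero major axis")
    ratio = minor_px / major_px
    if ratio < _RATIO_FLOOR:
        ratio = _RATIO_FLOOR
    ecc = float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))
    if ecc > _ECC_CAP:
        ecc = _ECC_CAP

    s = pixel_size_um
    return ShapeFeatures(
        area_um2=float(props.area) * s * s,
        perimeter_um=float(props.perimeter) * s,
        major_axis_um=major_px * s,
        minor_axis_um=minor_px * s,
        eccentricity=ecc,
        axis_ratio=ratio,
    )
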