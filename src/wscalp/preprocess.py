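"""Bias correction and neck cropping.

Both operate on volumes in canonical orientation (axis 2 runs inferior to
superior).  Physical positions are expressed in grid millimetres, i.e. voxel
index times spacing along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import cc_filter
from .errors import PipelineError
from .grid import Mask, Volume
from .morphology import box_mean
from .threshold import DegenerateHistogramError, otsu_threshold


@dataclass
class CropResult:
    """Output of :func:`crop_neck`.

    volume
        The input with inferior slices blanked (zeroed); same grid.
    com_top
        Centre of mass (grid mm, unweighted) of the most superior slab of the
        largest head component; the anchor point for all marker geometry.
    blanked_mask
        Mask of the blanked slices (all-False when nothing was blanked).
    largest_cc_top_mm
        Superior coordinate (grid mm) of the head component's top slice.
    """

    volume: Volume
    com_top: np.ndarray
    blanked_mask: Mask
    largest_cc_top_mm: float


def correct_bias(v: Volume, radius_mm: float = 30.0) -> Volume:
    """Divide out the low-spatial-frequency brightness field.

    The field is estimated as a large box mean of the image (half-extent
    ``radius_mm``); the quotient is rescaled by the field's mean so overall
    brightness is preserved.  Where the field is not positive the output is 0.
    """
    if not np.any(v.data > 0):
        raise PipelineError("bias-correction", "image has no positive intensities")
    field = box_mean(v, radius_mm).data.astype(np.float64)
    scale = float(field.mean())
    out = np.zeros(v.shape, dtype=np.float32)
    np.divide(v.data * scale, field, out=out, where=field > 0, casting="unsafe")
    return v.with_data(out)


def crop_neck(v: Volume, crop_extent_mm: float = 180.0, com_slab_mm: float = 35.0) -> CropResult:
    """Blank slices far below the top of the head and locate COM_top.

    Procedure: Otsu-threshold the image, keep the largest connected
    component (the head); find its superior-most slice; zero every axial
    slice more than ``crop_extent_mm`` inferior to it.  COM_top is the
    unweighted centre of mass of the component's most superior
    ``com_slab_mm`` millimetres.  The step has no effect on images whose
    inferior edge is within ``crop_extent_mm`` of the head top.
    """
    try:
        thr = otsu_threshold(v)
    except DegenerateHistogramError as e:
        raise PipelineError("neck-crop", f"cannot threshold the image: {e}") from e
    fg = v.new_mask(v.data > thr)
    head = cc_filter(fg, "keep_largest")
    if not head.data.any():
        raise PipelineError("neck-crop", "Otsu foreground is empty")
    sp_z = v.spacing[2]
    z_any = np.flatnonzero(head.data.any(axis=(0, 1)))
    z_top = int(z_any[-1])
    top_mm = z_top * sp_z

    z_idx = np.arange(v.shape[2])
    blank_slices = (top_mm - z_idx * sp_z) > crop_extent_mm
    blanked = np.zeros(v.shape, dtype=bool)
    data = v.data
    if blank_slices.any():
        blanked[:, :, blank_slices] = True
        data = v.data.copy()
        data[:, :, blank_slices] = 0.0

    slab_slices = (top_mm - z_idx * sp_z) <= com_slab_mm
    slab = head.data & slab_slices[None, None, :]
    idx = np.argwhere(slab)
    com_top = idx.mean(axis=0) * np.array(v.spacing)
    return CropResult(
        volume=v.with_data(data),
        com_top=com_top,
        blanked_mask=v.new_mask(blanked),
        largest_cc_top_mm=float(top_mm),
    )
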