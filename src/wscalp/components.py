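"""Connected-component shape filtering (6-connectivity throughout)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import Mask

_STRUCT = ndimage.generate_binary_structure(3, 1)


def label_components(m: Mask):
    """Label 6-connected components; returns (labels, n)."""
    return ndimage.label(m.data, structure=_STRUCT)


def cc_filter(m: Mask, mode: str, arg=None) -> Mask:
    """Filter connected components of a mask.

    Modes
    -----
    ``keep_largest``
        Retain the single largest component (ties broken toward the lowest
        label id, i.e. first in scan order).  Empty input stays empty.
    ``min_volume``
        Discard every component whose physical volume (voxel count x voxel
        volume) is strictly below ``arg`` mm^3.
    ``keep_touching``
        Retain every component overlapping the reference :class:`Mask`
        ``arg`` in at least one voxel.
    """
    labels, n = ndimage.label(m.data, structure=_STRUCT)
    if n == 0:
        return m.with_data(np.zeros(m.shape, dtype=bool))
    if mode == "keep_largest":
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = int(np.argmax(counts))  # argmax -> first/lowest label on ties
        return m.with_data(labels == keep)
    if mode == "min_volume":
        cutoff_mm3 = float(arg)
        counts = np.bincount(labels.ravel())
        vox = m.voxel_volume
        good = (counts * vox) >= cutoff_mm3
        good[0] = False
        return m.with_data(good[labels])
    if mode == "keep_touching":
        if not isinstance(arg, Mask):
            raise TypeError("keep_touching expects a reference Mask")
        if not m.same_grid(arg):
            raise ValueError("cc_filter: reference mask grid differs")
        ids = np.unique(labels[arg.data])
        ids = ids[ids > 0]
        keep = np.zeros(n + 1, dtype=bool)
        keep[ids] = True
        return m.with_data(keep[labels])
    raise ValueError(f"unknown cc_filter mode {mode!r}")
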