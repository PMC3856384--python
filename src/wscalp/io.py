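"""NIfTI reading and writing.

Volumes keep their native grid on disk and in the :class:`Volume` container;
orientation canonicalisation happens inside the pipelines, and every output
mask is written back on the input grid.
"""

from __future__ import annotations

import numpy as np

from .grid import Mask, Volume


class IOError_(ValueError):
    """Raised for unreadable or unsupported image files."""


def read_volume(path) -> Volume:
    """Load a 3D NIfTI-1/2 volume (4D with a singleton trailing axis is
    squeezed); spacing and affine are taken from the header."""
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as e:  # noqa: BLE001 - map loader errors to one type
        raise IOError_(f"cannot read image {path!r}: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError_(f"expected a 3D volume, got shape {data.shape} in {path!r}")
    affine = img.affine
    if affine is None:
        raise IOError_(f"image {path!r} has no affine")
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(data, dtype=np.float32), tuple(float(z) for z in zooms), affine)


def write_mask(m: Mask, path, like: Volume) -> None:
    """Write a mask as uint8 NIfTI on the grid of ``like`` (the input)."""
    import nibabel as nib

    if not m.same_grid(like):
        raise IOError_("write_mask: mask grid does not match the reference volume")
    img = nib.Nifti1Image(m.data.astype(np.uint8), like.affine)
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))


def write_volume(v: Volume, path) -> None:
    """Write a volume as float32 NIfTI."""
    import nibabel as nib

    img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
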