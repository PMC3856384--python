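"""Ordered record of pipeline intermediates for QC and debugging.

Every named intermediate of the extraction pipelines (M_A, N_F, B_1, MN_2,
R_2, ...) is stored under its symbol name in the order produced, and the whole
record can be dumped as NIfTI files for visual inspection.
"""

from __future__ import annotations

from typing import Dict, Iterator, Union

import numpy as np

from .grid import MarkerImage, Mask, Volume

Image = Union[Volume, Mask, MarkerImage]


class StageTrace:
    """Insertion-ordered mapping of symbol name -> image."""

    def __init__(self) -> None:
        self._items: Dict[str, Image] = {}

    def add(self, name: str, image: Image) -> None:
        self._items[name] = image

    def __contains__(self, name: str) -> bool:
        return name in self._items

    def __getitem__(self, name: str) -> Image:
        return self._items[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._items)

    def keys(self):
        return self._items.keys()

    def items(self):
        return self._items.items()

    def dump(self, directory) -> None:
        """Write every recorded image as ``<name>.nii.gz`` in ``directory``."""
        import os

        import nibabel as nib

        os.makedirs(directory, exist_ok=True)
        for name, img in self._items.items():
            data = img.data
            if data.dtype == bool or data.dtype == np.uint8:
                data = data.astype(np.uint8)
            else:
                data = data.astype(np.float32)
            nib.save(
                nib.Nifti1Image(data, img.affine),
                os.path.join(directory, f"{name}.nii.gz"),
            )
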