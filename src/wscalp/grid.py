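"""Grid-aware image containers and physical-unit helpers.

Every image in the package is a 3D array tied to a physical grid: a per-axis
voxel spacing in millimetres and an affine mapping voxel indices to anatomical
coordinates.  All structuring-element sizes, crop extents and volume cutoffs
throughout the pipelines are specified in millimetres and converted to voxel
units against the grid they are applied to, so the same parameterisation works
on anisotropic grids.

Pipelines operate internally in a canonical RAS-like orientation (axis 0 ->
left-to-right, axis 1 -> posterior-to-anterior, axis 2 -> inferior-to-superior)
obtained from the affine; :func:`to_canonical` / :func:`from_canonical` perform
the round trip so outputs land back on the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence, Tuple

import numpy as np
from nibabel import orientations as nio


class GridError(ValueError):
    """Raised for invalid grids or mismatched grid metadata."""


def _as_spacing(spacing: Sequence[float]) -> Tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise GridError(f"spacing must have 3 components, got {len(sp)}")
    if any(not np.isfinite(s) or s <= 0 for s in sp):
        raise GridError(f"spacing components must be finite and > 0, got {sp}")
    return sp  # type: ignore[return-value]


def _check_3d(data: np.ndarray, name: str) -> None:
    if data.ndim != 3:
        raise GridError(f"{name} data must be 3D, got shape {data.shape}")
    if any(s < 1 for s in data.shape):
        raise GridError(f"{name} data must be non-empty along every axis")


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and an affine.

    Parameters
    ----------
    data :
        3D array of finite scalars (float arrays are used as-is; integer
        input is converted to float32).
    spacing :
        Per-axis voxel size in millimetres, all > 0.
    affine :
        4x4 voxel-to-world matrix.  Defaults to ``diag(spacing, 1)``, i.e. an
        already-canonical RAS grid.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        _check_3d(self.data, "Volume")
        if not np.all(np.isfinite(self.data)):
            raise GridError("Volume data contains NaN or Inf")
        self.spacing = _as_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GridError("affine must be 4x4")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.affine)

    def same_grid(self, other: "Volume | Mask | MarkerImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def new_mask(self, data: np.ndarray) -> "Mask":
        return Mask(data, self.spacing, self.affine)


@dataclass
class Mask:
    """A binary image on the grid of an associated :class:`Volume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise GridError("Mask data must be binary")
            self.data = self.data.astype(bool)
        _check_3d(self.data, "Mask")
        self.spacing = _as_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Mask":
        return Mask(data, self.spacing, self.affine)

    def same_grid(self, other: "Volume | Mask | MarkerImage") -> bool:
        return Volume.same_grid(self, other)  # type: ignore[arg-type]

    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume


@dataclass
class MarkerImage:
    """Small-integer label image; 0 means unassigned.  The extraction
    pipelines use exactly two labels: 1 = brain, 2 = background."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype.kind not in "iub" or (
            self.data.size and (self.data.min() < 0 or self.data.max() > 255)
        ):
            raise GridError("MarkerImage labels must be integers in [0, 255]")
        self.data = self.data.astype(np.uint8)
        _check_3d(self.data, "MarkerImage")
        self.spacing = _as_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume | Mask | MarkerImage") -> bool:
        return Volume.same_grid(self, other)  # type: ignore[arg-type]

    def label_mask(self, label: int) -> np.ndarray:
        return self.data == label


@dataclass(frozen=True)
class KernelSpec:
    """Structuring-element description: a sphere (radius, mm) or box (edges, mm)."""

    shape: Literal["sphere", "box"]
    size_mm: float | Tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "box"):
            raise GridError(f"unknown kernel shape {self.shape!r}")
        if self.shape == "sphere":
            if not np.isscalar(self.size_mm):
                raise GridError("sphere kernels take a scalar radius")
            if self.size_mm < 0:
                raise GridError("kernel size must be >= 0")
        else:
            size = self.size_mm if not np.isscalar(self.size_mm) else (self.size_mm,) * 3
            object.__setattr__(self, "size_mm", tuple(float(s) for s in size))
            if any(s < 0 for s in self.size_mm):  # type: ignore[union-attr]
                raise GridError("kernel size must be >= 0")

    def footprint(self, spacing: Sequence[float]) -> np.ndarray:
        """Boolean voxel footprint of the kernel on a grid with this spacing."""
        spacing = _as_spacing(spacing)
        if self.shape == "box":
            ext = box_extents(self.size_mm, spacing)  # type: ignore[arg-type]
            return np.ones(tuple(ext), dtype=bool)
        r = float(self.size_mm)  # type: ignore[arg-type]
        half = np.array([int(np.floor(r / s)) for s in spacing])
        grids = np.meshgrid(
            *(np.arange(-h, h + 1) * s for h, s in zip(half, spacing)), indexing="ij"
        )
        d2 = sum(g * g for g in grids)
        fp = d2 <= r * r + 1e-9
        fp[tuple(half)] = True  # centre always included
        return fp


def mm_to_voxels(length_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Convert a physical length to per-axis voxel counts.

    Rounds half-up per axis; a strictly positive length never maps to zero
    voxels on any axis (coarse axes get at least one voxel so the operator
    keeps an effect there).
    """
    if length_mm < 0:
        raise GridError(f"length must be >= 0, got {length_mm}")
    spacing = _as_spacing(spacing)
    n = np.floor(np.asarray(length_mm) / np.array(spacing) + 0.5).astype(int)
    if length_mm > 0:
        n = np.maximum(n, 1)
    return n


def box_extents(edges_mm: Sequence[float] | float, spacing: Sequence[float]) -> np.ndarray:
    """Odd per-axis window extents (voxels) for a box kernel sized in mm."""
    spacing = _as_spacing(spacing)
    if np.isscalar(edges_mm):
        edges_mm = (edges_mm,) * 3  # type: ignore[assignment]
    ext = np.array(
        [int(mm_to_voxels(e, (s, s, s))[0]) for e, s in zip(edges_mm, spacing)]  # type: ignore[arg-type]
    )
    ext = np.maximum(ext, 1)
    ext += (ext + 1) % 2  # force odd
    return ext


# ---------------------------------------------------------------------------
# Orientation canonicalisation

_RAS_ORNT = np.array([[0, 1], [1, 1], [2, 1]], dtype=float)


def invert_ornt(ornt: np.ndarray) -> np.ndarray:
    """Inverse of an nibabel orientation array, such that applying ``ornt``
    then the inverse reproduces the original array."""
    inv = np.empty_like(ornt)
    for i, (j, flip) in enumerate(ornt):
        inv[int(j)] = (i, flip)
    return inv


def to_canonical(vol: Volume) -> Tuple[Volume, np.ndarray]:
    """Reorient a volume to canonical RAS-like axis order.

    Returns the reoriented volume and the orientation transform needed by
    :func:`from_canonical` to map results back onto the input grid.
    """
    ornt = nio.io_orientation(vol.affine)
    if np.any(np.isnan(ornt)):
        raise GridError("affine does not define anatomical directions")
    data = nio.apply_orientation(vol.data, ornt)
    aff = vol.affine @ nio.inv_ornt_aff(ornt, vol.shape)
    new_spacing = [0.0, 0.0, 0.0]
    for i, (j, _flip) in enumerate(ornt):
        new_spacing[int(j)] = vol.spacing[i]
    return Volume(data, tuple(new_spacing), aff), ornt


def from_canonical(data: np.ndarray, ornt: np.ndarray) -> np.ndarray:
    """Map an array produced in canonical orientation back to the input axes."""
    return nio.apply_orientation(data, invert_ornt(ornt))
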