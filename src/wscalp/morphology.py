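"""Morphological and smoothing primitives with millimetre-sized kernels.

Binary erosion and dilation use the *exact* Euclidean metric ball: the
operation is realised by thresholding a squared Euclidean distance transform
at the radius, rather than by a rasterised ball footprint.  The squared EDT is
computed with the separable lower-envelope (parabolic) algorithm, which runs
in O(n) per axis independent of distance magnitudes, so large radii (10-30 mm,
used heavily by the marker-generation steps) cost the same as small ones.

Boundary conventions, fixed so behaviour is well defined at the image edge:

* binary erosion treats out-of-grid voxels as foreground (masks touching the
  image edge are not eaten away from outside the field of view);
* binary dilation treats out-of-grid voxels as background;
* grayscale min/max filters consider in-bounds voxels only;
* box means average the in-bounds part of the window.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from numba import njit
from scipy import ndimage

from .grid import KernelSpec, Mask, Volume, box_extents, mm_to_voxels

_INF = 1e30  # "no site" sentinel for f-values (stays finite in float64 arithmetic)
_SENT = 1e300  # envelope boundary sentinel; must dwarf any spacing-scaled f-value

_UNIT_CROSS = ndimage.generate_binary_structure(3, 1)


@njit(cache=True)
def _dt_lines(F: np.ndarray) -> None:
    """In-place 1D squared distance transform of each row of ``F``.

    Rows hold f(q) sampled at unit abscissa spacing; on return each row holds
    min_q ((p - q)^2 + f(q)) (Felzenszwalb-Huttenlocher lower envelope).
    """
    m, n = F.shape
    v = np.empty(n, np.int64)
    z = np.empty(n + 1, np.float64)
    d = np.empty(n, np.float64)
    for i in range(m):
        f = F[i]
        k = 0
        v[0] = 0
        z[0] = -_SENT
        z[1] = _SENT
        for q in range(1, n):
            s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2.0 * (q - v[k]))
            while k > 0 and s <= z[k]:
                k -= 1
                s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2.0 * (q - v[k]))
            k += 1
            v[k] = q
            z[k] = s
            z[k + 1] = _SENT
        k = 0
        for q in range(n):
            while z[k + 1] < q:
                k += 1
            d[q] = (q - v[k]) * (q - v[k]) + f[v[k]]
        for q in range(n):
            f[q] = d[q]


def squared_edt(sites: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Squared Euclidean distance (mm^2) from every voxel to the nearest
    ``True`` voxel of ``sites``.  Voxels with no site anywhere get a huge
    sentinel value (compares greater than any physical radius)."""
    f = np.where(sites, 0.0, _INF)
    for ax in range(f.ndim):
        s2 = float(spacing[ax]) ** 2
        moved = np.moveaxis(f, ax, -1)
        lines = np.ascontiguousarray(moved).reshape(-1, f.shape[ax])
        lines /= s2
        _dt_lines(lines)
        lines *= s2
        f = np.moveaxis(lines.reshape(moved.shape), -1, ax)
    return np.ascontiguousarray(f)


# ---------------------------------------------------------------------------
# Binary morphology (metric-exact spheres)


def _binary_erode(m: np.ndarray, radius: float, spacing) -> np.ndarray:
    if radius <= 0:
        return m.copy()
    d2 = squared_edt(~m, spacing)
    return m & (d2 > radius * radius)


def _binary_dilate(m: np.ndarray, radius: float, spacing) -> np.ndarray:
    if radius <= 0:
        return m.copy()
    if not m.any():
        return m.copy()
    d2 = squared_edt(m, spacing)
    return d2 <= radius * radius


def binary_morph(m: Mask, op: str, radius_mm: float) -> Mask:
    """Binary erosion/dilation/opening/closing by an exact sphere of the given
    radius in mm.  ``open`` is erode-then-dilate, ``close`` the reverse."""
    if radius_mm < 0:
        raise ValueError(f"radius must be >= 0, got {radius_mm}")
    data = m.data
    if op == "erode":
        out = _binary_erode(data, radius_mm, m.spacing)
    elif op == "dilate":
        out = _binary_dilate(data, radius_mm, m.spacing)
    elif op == "open":
        out = _binary_dilate(_binary_erode(data, radius_mm, m.spacing), radius_mm, m.spacing)
    elif op == "close":
        out = _binary_erode(_binary_dilate(data, radius_mm, m.spacing), radius_mm, m.spacing)
    else:
        raise ValueError(f"unknown binary op {op!r}")
    return m.with_data(out)


# ---------------------------------------------------------------------------
# Grayscale morphology


def _gray_apply(data: np.ndarray, op: str, kernel: KernelSpec, spacing) -> np.ndarray:
    data = np.asarray(data, dtype=np.float32)
    if kernel.shape == "box":
        size = tuple(int(s) for s in box_extents(kernel.size_mm, spacing))
        ero = lambda a: ndimage.grey_erosion(a, size=size, mode="constant", cval=np.inf)
        dil = lambda a: ndimage.grey_dilation(a, size=size, mode="constant", cval=-np.inf)
    else:
        fp = kernel.footprint(spacing)
        ero = lambda a: ndimage.grey_erosion(a, footprint=fp, mode="constant", cval=np.inf)
        dil = lambda a: ndimage.grey_dilation(a, footprint=fp, mode="constant", cval=-np.inf)
    if op == "erode":
        return ero(data)
    if op == "dilate":
        return dil(data)
    if op == "open":
        return dil(ero(data))
    if op == "close":
        return ero(dil(data))
    raise ValueError(f"unknown grayscale op {op!r}")


def gray_morph(v: Volume, op: str, kernel: KernelSpec) -> Volume:
    """Grayscale moving-min/max (and compositions) over the kernel footprint."""
    return v.with_data(_gray_apply(v.data, op, kernel, v.spacing))


# ---------------------------------------------------------------------------
# Box means


def _box_sum(a: np.ndarray, half: Sequence[int]) -> np.ndarray:
    """Sliding-window sum with the window truncated at image borders."""
    out = np.asarray(a, dtype=np.float64)
    for ax, h in enumerate(half):
        h = int(h)
        if h == 0:
            continue
        c = np.cumsum(out, axis=ax)
        n = out.shape[ax]
        hi = np.minimum(np.arange(n) + h, n - 1)
        upper = np.take(c, hi, axis=ax)
        lo = np.arange(n) - h - 1
        valid = lo >= 0
        lower = np.take(c, np.maximum(lo, 0), axis=ax)
        shape = [1, 1, 1]
        shape[ax] = n
        lower = lower * valid.reshape(shape)
        out = upper - lower
    return out


def box_mean(v: Volume, radius_mm: float) -> Volume:
    """Mean over a box window of half-extent ``radius_mm`` per axis; at the
    image border only the in-bounds part of the window is averaged."""
    if radius_mm <= 0:
        raise ValueError("box_mean radius must be > 0")
    half = mm_to_voxels(radius_mm, v.spacing)
    num = _box_sum(v.data, half)
    den = _box_sum(np.ones(v.shape, dtype=np.float64), half)
    return v.with_data((num / den).astype(np.float32))


def masked_mean(v: Volume, m: Mask, kernel: KernelSpec) -> Volume:
    """Windowed mean that ignores voxels outside ``m``.

    At each voxel the output is the mean of in-mask voxels inside the window;
    where the window contains no in-mask voxel the output is 0 (such voxels
    lie outside any region the pipelines later read).
    """
    if not v.same_grid(m):
        raise ValueError("masked_mean: volume and mask grids differ")
    if kernel.shape != "box":
        raise NotImplementedError("masked_mean supports box kernels")
    half = box_extents(kernel.size_mm, v.spacing) // 2
    md = m.data.astype(np.float64)
    num = _box_sum(v.data * md, half)
    den = _box_sum(md, half)
    out = np.zeros(v.shape, dtype=np.float32)
    np.divide(num, den, out=out, where=den > 0, casting="unsafe")
    return v.with_data(out)


# ---------------------------------------------------------------------------
# Masked morphological gradient


def gradient_smooth(v: Volume, sigma_mm: float, within: Mask) -> Volume:
    """Gaussian-smoothed morphological gradient restricted to a mask.

    The unit-structuring-element dilation and erosion treat outside-mask
    voxels as absent (masked max/min), which avoids spurious edge responses at
    the mask border; the gradient is then convolved with a Gaussian of
    ``sigma_mm`` standard deviation.  Output is non-negative, zero outside the
    mask (before smoothing).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    if not v.same_grid(within):
        raise ValueError("gradient_smooth: volume and mask grids differ")
    m = within.data
    hi = ndimage.grey_dilation(
        np.where(m, v.data, -np.inf).astype(np.float32),
        footprint=_UNIT_CROSS,
        mode="constant",
        cval=-np.inf,
    )
    lo = ndimage.grey_erosion(
        np.where(m, v.data, np.inf).astype(np.float32),
        footprint=_UNIT_CROSS,
        mode="constant",
        cval=np.inf,
    )
    grad = np.where(m, hi - lo, 0.0).astype(np.float32)
    sigma_vox = [sigma_mm / s for s in v.spacing]
    out = ndimage.gaussian_filter(grad, sigma=sigma_vox)
    return v.with_data(np.maximum(out, 0.0))
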