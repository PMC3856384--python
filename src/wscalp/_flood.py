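"""Priority-flood engine for the watershed transform from markers.

A single binary heap ordered by (control value, insertion age) floods the
control surface from all marker voxels simultaneously.  The tie rule is fully
specified so results are bit-reproducible:

* seeds are pushed in raster (C scan) order, ages 0, 1, 2, ...;
* the heap pops the smallest (value, age) pair — FIFO within equal priority;
* when a voxel pops, its 6 face neighbours are visited in the fixed order
  (-x, +x, -y, +y, -z, +z); unlabelled neighbours inherit the label, are
  pushed with their own control value, and are never revisited.

Every voxel is pushed at most once, so the heap is preallocated at grid size.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sift_up(val, age, pos, n):
    i = n
    while i > 0:
        p = (i - 1) // 2
        if (val[p] < val[i]) or (val[p] == val[i] and age[p] < age[i]):
            break
        val[i], val[p] = val[p], val[i]
        age[i], age[p] = age[p], age[i]
        pos[i], pos[p] = pos[p], pos[i]
        i = p


@njit(cache=True)
def _sift_down(val, age, pos, n):
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        s = i
        if l < n and ((val[l] < val[s]) or (val[l] == val[s] and age[l] < age[s])):
            s = l
        if r < n and ((val[r] < val[s]) or (val[r] == val[s] and age[r] < age[s])):
            s = r
        if s == i:
            break
        val[i], val[s] = val[s], val[i]
        age[i], age[s] = age[s], age[i]
        pos[i], pos[s] = pos[s], pos[i]
        i = s


@njit(cache=True)
def priority_flood(control: np.ndarray, labels: np.ndarray) -> None:
    """Flood ``control`` (float64, C-contiguous 3D) in place from the nonzero
    voxels of ``labels`` (int32, same shape); every voxel ends up labelled."""
    nx, ny, nz = control.shape
    n = nx * ny * nz
    flat_ctrl = control.ravel()
    flat_lab = labels.ravel()

    heap_val = np.empty(n, np.float64)
    heap_age = np.empty(n, np.int64)
    heap_pos = np.empty(n, np.int64)
    hn = 0
    age = 0

    # seed the heap at the global minimum: markers are holes in the surface
    vmin = flat_ctrl[0]
    for i in range(n):
        if flat_ctrl[i] < vmin:
            vmin = flat_ctrl[i]
    for i in range(n):
        if flat_lab[i] != 0:
            heap_val[hn] = vmin
            heap_age[hn] = age
            heap_pos[hn] = i
            _sift_up(heap_val, heap_age, heap_pos, hn)
            hn += 1
            age += 1

    sy = nz
    sx = ny * nz
    while hn > 0:
        p = heap_pos[0]
        hn -= 1
        heap_val[0] = heap_val[hn]
        heap_age[0] = heap_age[hn]
        heap_pos[0] = heap_pos[hn]
        _sift_down(heap_val, heap_age, heap_pos, hn)

        lab = flat_lab[p]
        i = p // sx
        rem = p - i * sx
        j = rem // sy
        k = rem - j * sy
        for d in range(6):
            if d == 0:
                if i == 0:
                    continue
                q = p - sx
            elif d == 1:
                if i == nx - 1:
                    continue
                q = p + sx
            elif d == 2:
                if j == 0:
                    continue
                q = p - sy
            elif d == 3:
                if j == ny - 1:
                    continue
                q = p + sy
            elif d == 4:
                if k == 0:
                    continue
                q = p - 1
            else:
                if k == nz - 1:
                    continue
                q = p + 1
            if flat_lab[q] == 0:
                flat_lab[q] = lab
                heap_val[hn] = flat_ctrl[q]
                heap_age[hn] = age
                heap_pos[hn] = q
                _sift_up(heap_val, heap_age, heap_pos, hn)
                hn += 1
                age += 1
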