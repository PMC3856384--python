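"""Brute-force reference implementations of every core primitive.

These oracles share only the *contracts* with the package (window sizing
rules, tie rules, boundary conventions), not the algorithms: morphology is
done by explicit offset enumeration, Otsu by an exhaustive threshold scan,
quantiles by sorting, connected components by BFS, and the watershed by a
pure-Python heapq flood.  They are deliberately slow and simple.
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# window/footprint sizing (independent restatement of the mm->voxel contract:
# round half-up per axis, minimum 1 voxel for positive lengths)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def length_to_voxels(length_mm: float, spacing) -> list:
    out = []
    for s in spacing:
        n = _round_half_up(length_mm / s)
        if length_mm > 0 and n < 1:
            n = 1
        out.append(n)
    return out


def odd_box_extents(edges_mm, spacing) -> list:
    if np.isscalar(edges_mm):
        edges_mm = (edges_mm,) * 3
    ext = []
    for e, s in zip(edges_mm, spacing):
        n = max(_round_half_up(e / s), 1) if e > 0 else 1
        if e > 0 and n < 1:
            n = 1
        if n % 2 == 0:
            n += 1
        ext.append(n)
    return ext


def sphere_offsets(radius_mm: float, spacing) -> list:
    """Integer offsets whose physical distance is <= radius (centre always in)."""
    half = [int(math.floor(radius_mm / s)) for s in spacing]
    offs = []
    for o in itertools.product(*(range(-h, h + 1) for h in half)):
        d2 = sum((oi * si) ** 2 for oi, si in zip(o, spacing))
        if d2 <= radius_mm * radius_mm + 1e-9:
            offs.append(o)
    if (0, 0, 0) not in offs:
        offs.append((0, 0, 0))
    return offs


def ball_offsets_exact(radius_mm: float, spacing) -> list:
    """Offsets for the metric ball used by binary morphology (no floor cap:
    enumerate everything within ceil(r/s) and keep exact-distance hits)."""
    half = [int(math.ceil(radius_mm / s)) for s in spacing]
    offs = []
    for o in itertools.product(*(range(-h, h + 1) for h in half)):
        d2 = sum((oi * si) ** 2 for oi, si in zip(o, spacing))
        if d2 <= radius_mm * radius_mm:
            offs.append(o)
    return offs


def box_offsets(extents) -> list:
    halves = [e // 2 for e in extents]
    return list(itertools.product(*(range(-h, h + 1) for h in halves)))


def _shift_valid(shape, off):
    """Slicing pair for an offset: out[dst] looks at in[src]."""
    dst, src = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            dst.append(slice(0, max(0, n - o)))
            src.append(slice(min(o, n), n))
        else:
            dst.append(slice(min(-o, n), n))
            src.append(slice(0, max(0, n + o)))
    return tuple(dst), tuple(src)


# ---------------------------------------------------------------------------
# binary morphology (Minkowski with the metric ball)


def binary_erode_oracle(m: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Voxel survives iff every in-grid voxel within the ball is foreground
    (out-of-grid counts as foreground)."""
    if radius_mm <= 0:
        return m.copy()
    out = m.copy()
    for off in ball_offsets_exact(radius_mm, spacing):
        dst, src = _shift_valid(m.shape, off)
        shifted = np.ones(m.shape, dtype=bool)
        shifted[dst] = m[src]
        out &= shifted
    return out


def binary_dilate_oracle(m: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    """Union of balls around foreground voxels (out-of-grid is background)."""
    if radius_mm <= 0 or not m.any():
        return m.copy()
    out = np.zeros(m.shape, dtype=bool)
    for off in ball_offsets_exact(radius_mm, spacing):
        dst, src = _shift_valid(m.shape, off)
        out[dst] |= m[src]
    return out


def binary_morph_oracle(m: np.ndarray, op: str, radius_mm: float, spacing) -> np.ndarray:
    if op == "erode":
        return binary_erode_oracle(m, radius_mm, spacing)
    if op == "dilate":
        return binary_dilate_oracle(m, radius_mm, spacing)
    if op == "open":
        return binary_dilate_oracle(binary_erode_oracle(m, radius_mm, spacing), radius_mm, spacing)
    if op == "close":
        return binary_erode_oracle(binary_dilate_oracle(m, radius_mm, spacing), radius_mm, spacing)
    raise ValueError(op)


# ---------------------------------------------------------------------------
# grayscale morphology (in-bounds min/max over the footprint)


def _gray_extreme(v: np.ndarray, offsets, kind: str) -> np.ndarray:
    fill = np.inf if kind == "min" else -np.inf
    out = np.full(v.shape, fill, dtype=np.float64)
    for off in offsets:
        dst, src = _shift_valid(v.shape, off)
        shifted = np.full(v.shape, fill, dtype=np.float64)
        shifted[dst] = v[src]
        out = np.minimum(out, shifted) if kind == "min" else np.maximum(out, shifted)
    return out


def gray_morph_oracle(v: np.ndarray, op: str, shape: str, size_mm, spacing) -> np.ndarray:
    if shape == "box":
        offsets = box_offsets(odd_box_extents(size_mm, spacing))
    else:
        offsets = sphere_offsets(float(size_mm), spacing)
    v = np.asarray(v, dtype=np.float64)
    if op == "erode":
        return _gray_extreme(v, offsets, "min")
    if op == "dilate":
        return _gray_extreme(v, offsets, "max")
    if op == "open":
        return _gray_extreme(_gray_extreme(v, offsets, "min"), offsets, "max")
    if op == "close":
        return _gray_extreme(_gray_extreme(v, offsets, "max"), offsets, "min")
    raise ValueError(op)


# ---------------------------------------------------------------------------
# means


def box_mean_oracle(v: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    half = length_to_voxels(radius_mm, spacing)
    offsets = list(itertools.product(*(range(-h, h + 1) for h in half)))
    total = np.zeros(v.shape, dtype=np.float64)
    count = np.zeros(v.shape, dtype=np.float64)
    for off in offsets:
        dst, src = _shift_valid(v.shape, off)
        total[dst] += v[src]
        count[dst] += 1.0
    return total / count


def masked_mean_oracle(v: np.ndarray, m: np.ndarray, edges_mm, spacing) -> np.ndarray:
    offsets = box_offsets(odd_box_extents(edges_mm, spacing))
    total = np.zeros(v.shape, dtype=np.float64)
    count = np.zeros(v.shape, dtype=np.float64)
    for off in offsets:
        dst, src = _shift_valid(v.shape, off)
        total[dst] += np.where(m[src], v[src], 0.0)
        count[dst] += m[src]
    out = np.zeros(v.shape, dtype=np.float64)
    np.divide(total, count, out=out, where=count > 0)
    return out


# ---------------------------------------------------------------------------
# thresholds and quantiles


def otsu_oracle(values: np.ndarray, bins: int = 128) -> float:
    """Exhaustive scan: try every histogram cut, maximise between-class
    variance computed from scratch each time; first maximum wins."""
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError("constant region")
    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var, best_idx = -1.0, 0
    for cut in range(bins - 1):
        w1 = hist[: cut + 1].sum()
        w2 = hist[cut + 1 :].sum()
        if w1 == 0 or w2 == 0:
            var = 0.0
        else:
            mu1 = (hist[: cut + 1] * centers[: cut + 1]).sum() / w1
            mu2 = (hist[cut + 1 :] * centers[cut + 1 :]).sum() / w2
            var = w1 * w2 * (mu1 - mu2) ** 2
        if var > best_var:
            best_var, best_idx = var, cut
    return float(centers[best_idx])


def quantile_oracle(values: np.ndarray, q: float) -> float:
    """Nearest-rank: the ceil(q*n)-th order statistic (1-based)."""
    vals = np.sort(np.asarray(values).ravel())
    n = vals.size
    rank = int(math.ceil(q * n))
    rank = min(max(rank, 1), n)
    return float(vals[rank - 1])


# ---------------------------------------------------------------------------
# connected components (BFS, 6-connectivity, raster seeding order)

_NEIGHBOURS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def label_oracle(m: np.ndarray):
    labels = np.zeros(m.shape, dtype=np.int32)
    nxt = 0
    for idx in np.ndindex(m.shape):
        if m[idx] and labels[idx] == 0:
            nxt += 1
            stack = [idx]
            labels[idx] = nxt
            while stack:
                i, j, k = stack.pop()
                for di, dj, dk in _NEIGHBOURS:
                    q = (i + di, j + dj, k + dk)
                    if (
                        0 <= q[0] < m.shape[0]
                        and 0 <= q[1] < m.shape[1]
                        and 0 <= q[2] < m.shape[2]
                        and m[q]
                        and labels[q] == 0
                    ):
                        labels[q] = nxt
                        stack.append(q)
    return labels, nxt


def cc_filter_oracle(m: np.ndarray, mode: str, arg, spacing) -> np.ndarray:
    labels, n = label_oracle(m)
    if n == 0:
        return np.zeros(m.shape, dtype=bool)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    if mode == "keep_largest":
        keep = 1 + int(np.argmax(sizes[1:]))  # first label on ties
        return labels == keep
    if mode == "min_volume":
        vox = float(np.prod(spacing))
        good = np.zeros(n + 1, dtype=bool)
        for lbl in range(1, n + 1):
            good[lbl] = sizes[lbl] * vox >= float(arg)
        return good[labels]
    if mode == "keep_touching":
        good = np.zeros(n + 1, dtype=bool)
        for lbl in np.unique(labels[np.asarray(arg, dtype=bool)]):
            if lbl > 0:
                good[lbl] = True
        return good[labels]
    raise ValueError(mode)


# ---------------------------------------------------------------------------
# watershed (pure-Python priority flood with the package's documented tie rule)


def watershed_oracle(control: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Flood ``control`` from nonzero ``markers``.

    Tie rule (the package contract): seeds enter the queue at the global
    minimum in raster order; the queue pops the smallest (value, age) pair;
    a popped voxel labels its unlabelled 6-neighbours in the fixed order
    (-x, +x, -y, +y, -z, +z), pushing each with its own control value.
    """
    control = np.asarray(control, dtype=np.float64)
    out = np.asarray(markers).astype(np.int32).copy()
    heap = []
    age = 0
    vmin = float(control.min())
    for idx in np.ndindex(out.shape):
        if out[idx] != 0:
            heapq.heappush(heap, (vmin, age, idx))
            age += 1
    nx, ny, nz = control.shape
    while heap:
        _, _, (i, j, k) = heapq.heappop(heap)
        lab = out[i, j, k]
        for di, dj, dk in _NEIGHBOURS:
            q = (i + di, j + dj, k + dk)
            if 0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz and out[q] == 0:
                out[q] = lab
                heapq.heappush(heap, (float(control[q]), age, q))
                age += 1
    return out


def regional_minima_oracle(v: np.ndarray) -> np.ndarray:
    """Boolean mask of regional minima: connected equal-value plateaus with
    no strictly lower neighbour."""
    v = np.asarray(v, dtype=np.float64)
    visited = np.zeros(v.shape, dtype=bool)
    out = np.zeros(v.shape, dtype=bool)
    nx, ny, nz = v.shape
    for idx in np.ndindex(v.shape):
        if visited[idx]:
            continue
        level = v[idx]
        plateau = [idx]
        visited[idx] = True
        is_min = True
        head = 0
        while head < len(plateau):
            i, j, k = plateau[head]
            head += 1
            for di, dj, dk in _NEIGHBOURS:
                q = (i + di, j + dj, k + dk)
                if not (0 <= q[0] < nx and 0 <= q[1] < ny and 0 <= q[2] < nz):
                    continue
                if v[q] == level:
                    if not visited[q]:
                        visited[q] = True
                        plateau.append(q)
                elif v[q] < level:
                    is_min = False
        if is_min:
            for p in plateau:
                out[p] = True
    return out
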