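"""Histogram thresholding and order statistics within masks."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .grid import Mask, Volume

OTSU_BINS = 128


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested for a (near-)constant region."""


def otsu_threshold(v: Volume, region: Optional[Mask] = None, bins: int = OTSU_BINS) -> float:
    """Otsu threshold of the volume's intensities, optionally restricted to a
    mask.

    The histogram uses ``bins`` equal-width bins over the region's [min, max];
    the returned value is the bin centre maximising the between-class
    variance (first maximum on ties).  Voxels strictly above the threshold are
    the "bright" class.
    """
    if region is not None:
        if not v.same_grid(region):
            raise ValueError("otsu_threshold: volume and mask grids differ")
        vals = v.data[region.data]
    else:
        vals = v.data.ravel()
    if vals.size == 0:
        raise DegenerateHistogramError("otsu_threshold: empty region")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        raise DegenerateHistogramError("otsu_threshold: constant region")
    hist, edges = np.histogram(vals, bins=bins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w1 = np.cumsum(hist)
    w2 = np.cumsum(hist[::-1])[::-1]
    mu1 = np.cumsum(hist * centers) / w1
    mu2 = (np.cumsum((hist * centers)[::-1]) / np.cumsum(hist[::-1]))[::-1]
    var_between = w1[:-1] * w2[1:] * (mu1[:-1] - mu2[1:]) ** 2
    idx = int(np.argmax(var_between))
    return float(centers[idx])


def quantile_in_mask(v: Volume, region: Optional[Mask], q: float) -> float:
    """Nearest-rank quantile of in-region intensities.

    Uses the ceil(q*n)-th order statistic; q=0 gives the minimum and q=1 the
    maximum.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"quantile must be in [0, 1], got {q}")
    if region is not None:
        if not v.same_grid(region):
            raise ValueError("quantile_in_mask: volume and mask grids differ")
        vals = v.data[region.data]
    else:
        vals = v.data.ravel()
    n = vals.size
    if n == 0:
        raise ValueError("quantile_in_mask: empty region")
    rank = int(np.ceil(q * n)) - 1
    rank = min(max(rank, 0), n - 1)
    return float(np.partition(vals, rank)[rank])


def median_in_mask(v: Volume, region: Optional[Mask]) -> float:
    """The 50% brightness level of a region (nearest-rank median)."""
    return quantile_in_mask(v, region, 0.5)
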