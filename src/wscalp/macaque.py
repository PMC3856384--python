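"""Macaque brain extraction: geometry-driven markers, same two-flood backbone.

Macaque scans are small and often severely bias-contaminated, so the marker
strategy is simpler and more geometric than the human one: the whole grid is
a background marker except for a blanked box around the brain, dark anterior
cavities (eyes) receive explicit background markers, and the brain marker is
a small box below COM_top.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence, Tuple

import numpy as np

from .components import cc_filter
from .errors import PipelineError
from .grid import KernelSpec, MarkerImage, Mask, Volume, from_canonical, to_canonical
from .human import (
    ScalpResult,
    box_mask,
    invert_volume,
    merge_markers,
    smooth_mask,
    stage2_control,
)
from .human import HumanParams
from .morphology import binary_morph, gray_morph
from .preprocess import correct_bias, crop_neck
from .threshold import median_in_mask, quantile_in_mask
from .trace import StageTrace
from .watershed import watershed_from_markers


@dataclass(frozen=True)
class MacaqueParams:
    """Tunable sizes (mm), quantiles and cutoffs of the macaque pipeline."""

    crop_extent_mm: float = 80.0
    com_slab_mm: float = 15.0
    brainbox_mm: Tuple[float, float, float] = (70.0, 90.0, 65.0)
    box_below_com_mm: float = 35.0
    close_box_mm: float = 8.0
    bg_quantile_lo: float = 0.01
    bg_quantile: float = 0.25
    anterior_limit_mm: float = 20.0
    min_cc_mm3: float = 100.0
    cc_dilate_mm: float = 3.0
    brain_seed_box_mm: Tuple[float, float, float] = (10.0, 10.0, 15.0)
    stage2_erode_mm: float = 5.0
    grad_sigma_mm: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            vals = val if isinstance(val, tuple) else (val,)
            if any(x < 0 for x in vals):
                raise ValueError(f"MacaqueParams.{f.name} must be >= 0")
        for name in ("bg_quantile_lo", "bg_quantile"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"MacaqueParams.{name} must be in (0, 1)")


def macaque_stage1_markers(
    R0: Volume,
    com_top: Sequence[float],
    params: MacaqueParams = MacaqueParams(),
    trace: Optional[StageTrace] = None,
) -> Tuple[MarkerImage, Volume]:
    """Stage-1 marker image MN_1 and the closed image R_A.

    Background: the whole grid (label 2) minus a blanked box around the
    brain, plus markers in large dark anterior cavities (eyes) found on the
    box-closed image R_A via two quantile thresholds, restricted to the
    region anterior of COM_top, volume-filtered and dilated.  Brain: a small
    box below COM_top filled with label 1.
    """
    center = np.array(com_top, dtype=float)
    center[2] -= params.box_below_com_mm
    # brain-box mapping: (left-right, anterior-posterior, superior-inferior)
    edges = (params.brainbox_mm[0], params.brainbox_mm[1], params.brainbox_mm[2])
    blank_box = box_mask(R0, center, edges)
    n_b = Mask(~blank_box.data, R0.spacing, R0.affine)

    r_a = gray_morph(R0, "close", KernelSpec("box", params.close_box_mm))
    q_lo = quantile_in_mask(r_a, None, params.bg_quantile_lo)
    b_a = R0.new_mask(r_a.data > q_lo)
    q25 = quantile_in_mask(r_a, b_a, params.bg_quantile)
    b_b = R0.new_mask(r_a.data < q25)
    b_c = R0.new_mask(b_b.data | ~b_a.data)
    # blank everything posterior of the plane anterior_limit_mm in front of COM_top
    y_mm = np.arange(R0.shape[1]) * R0.spacing[1]
    anterior = y_mm > float(com_top[1]) + params.anterior_limit_mm
    b_c = b_c.with_data(b_c.data & anterior[None, :, None])
    b_d = binary_morph(cc_filter(b_c, "min_volume", params.min_cc_mm3), "dilate", params.cc_dilate_mm)
    n_c = R0.new_mask(n_b.data | b_d.data)

    seed_box = box_mask(R0, center, params.brain_seed_box_mm)
    if not seed_box.data.any():
        raise PipelineError("stage1-markers", "brain seed box lies outside the image")
    out = np.zeros(R0.shape, dtype=np.uint8)
    out[n_c.data] = 2
    out[seed_box.data] = 1
    mn1 = MarkerImage(out, R0.spacing, R0.affine)
    if trace is not None:
        trace.add("R_A", r_a)
        trace.add("B_C", b_c)
        trace.add("B_D", b_d)
        trace.add("N_C", n_c)
        trace.add("MN_1", mn1)
    return mn1, r_a


def macaque_stage2_markers(
    R0: Volume,
    R_A: Volume,
    stage1_labels: MarkerImage,
    params: MacaqueParams = MacaqueParams(),
    trace: Optional[StageTrace] = None,
) -> MarkerImage:
    """Stage-2 markers: M_C = (R_A > t_50) inside the eroded Stage-1 brain;
    the Stage-1 background region N_D is reused as the background marker."""
    m_b = Mask(stage1_labels.data == 1, R0.spacing, R0.affine)
    if not m_b.data.any():
        raise PipelineError("stage2-markers", "stage-1 brain region is empty")
    b_e = binary_morph(m_b, "erode", params.stage2_erode_mm)
    t50 = median_in_mask(R0, m_b)
    m_c = Mask((R_A.data > t50) & b_e.data, R0.spacing, R0.affine)
    if not m_c.data.any():
        raise PipelineError("stage2-markers", "stage-2 brain marker is empty")
    n_d = Mask(stage1_labels.data == 2, R0.spacing, R0.affine)
    mn2 = merge_markers(m_c, n_d)
    if trace is not None:
        trace.add("B_E", b_e)
        trace.add("M_C", m_c)
        trace.add("MN_2", mn2)
    return mn2


def extract_brain_macaque(
    v: Volume,
    params: MacaqueParams = MacaqueParams(),
    *,
    bias_correct: bool = True,
    smooth: bool = False,
    stage: int = 2,
    trace: Optional[StageTrace] = None,
) -> ScalpResult:
    """Run the full macaque pipeline; masks are on the input grid.

    Bias correction is on by default (macaque inhomogeneity is typically
    severe); smoothing is opt-in.  The stage-2 control skips the initial
    erosion and no final dilation is applied, so stage 2 is a subset of
    stage 1.
    """
    if trace is None:
        trace = StageTrace()
    vcan, ornt = to_canonical(v)

    def back(m: Mask) -> Mask:
        return Mask(from_canonical(m.data, ornt), v.spacing, v.affine)

    r = correct_bias(vcan) if bias_correct else vcan
    crop = crop_neck(r, params.crop_extent_mm, params.com_slab_mm)
    r0 = crop.volume
    trace.add("R_0", r0)

    mn1, r_a = macaque_stage1_markers(r0, crop.com_top, params, trace)
    ws1 = watershed_from_markers(invert_volume(r0), mn1, required_labels=(1, 2))
    b1 = Mask(ws1.data == 1, r0.spacing, r0.affine)
    trace.add("B_1", b1)

    b2 = None
    if stage >= 2:
        mn2 = macaque_stage2_markers(r0, r_a, ws1, params, trace)
        t50 = median_in_mask(r0, b1)
        hp = HumanParams(grad_sigma_mm=params.grad_sigma_mm)
        r2 = stage2_control(r0, b1, t50, hp, erode_mm=0.0, trace=trace)
        ws2 = watershed_from_markers(r2, mn2, required_labels=(1, 2))
        b2 = Mask(ws2.data == 1, r0.spacing, r0.affine)
        trace.add("B_2", b2)

    s1 = s2 = None
    if smooth:
        s1 = smooth_mask(b1, 1)
        if b2 is not None:
            s2 = smooth_mask(b2, 2)

    return ScalpResult(
        stage1_mask=back(b1),
        stage2_mask=back(b2) if b2 is not None else None,
        stage1_smoothed=back(s1) if s1 is not None else None,
        stage2_smoothed=back(s2) if s2 is not None else None,
        trace=trace,
    )
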