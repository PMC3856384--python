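"""Two-stage human brain extraction.

Stage 1 builds one conservative brain marker and one background marker with
aggressive large-kernel morphology, then floods the inverted T1: the boundary
falls in the dark CSF/bone gap and the result includes all brain tissue plus
some surrounding dura/bone.  Stage 2 re-floods a gradient-based control
surface from refined markers placed near the Stage-1 boundary, trimming the
over-segmentation without moving boundaries that were already right.

All geometric reasoning is done in grid millimetres (voxel index x spacing)
on a volume in canonical orientation (axis 0 left-right, axis 1
posterior-anterior, axis 2 inferior-superior).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .components import cc_filter
from .errors import PipelineError
from .grid import KernelSpec, MarkerImage, Mask, Volume, from_canonical, to_canonical
from .morphology import binary_morph, gradient_smooth, gray_morph, masked_mean
from .preprocess import correct_bias, crop_neck
from .threshold import median_in_mask, otsu_threshold
from .trace import StageTrace
from .watershed import watershed_from_markers

_UNIT_CROSS = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class HumanParams:
    """All tunable sizes (mm), ratios and cutoffs of the human pipeline."""

    box_edge_mm: float = 40.0
    box_below_com_mm: float = 50.0
    bright_ratio: float = 1.25
    open_brain_mm: float = 2.0
    bg_erode_mm: float = 10.0
    bg_open_mm: float = 30.0
    gs_open_box_mm: float = 5.0
    bg_erode2_mm: float = 5.0
    bg_dilate_mm: float = 6.0
    border_zone_mm: float = 10.0
    dark_erode_mm: float = 1.0
    local_mean_box_mm: float = 30.0
    dark_fraction: float = 0.6
    bz2_erode_mm: float = 3.3
    sup_zone_mm: float = 90.0
    min_cc_mm3: float = 10.0
    final_dilate_mm: float = 1.0
    smooth_open_mm: float = 5.0
    smooth_close_mm: float = 6.5
    grad_sigma_mm: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"HumanParams.{f.name} must be >= 0")
        if self.bright_ratio <= 1:
            raise ValueError("bright_ratio must be > 1")
        if not 0 < self.dark_fraction < 1:
            raise ValueError("dark_fraction must be in (0, 1)")


@dataclass
class ScalpResult:
    """Outputs of a full extraction run; masks are on the input grid."""

    stage1_mask: Mask
    stage2_mask: Optional[Mask]
    stage1_smoothed: Optional[Mask]
    stage2_smoothed: Optional[Mask]
    trace: StageTrace


def box_mask(like: "Volume | Mask", center_mm: Sequence[float], edges_mm: Sequence[float] | float) -> Mask:
    """Axis-aligned box: voxels whose grid-mm position is within half an edge
    of the centre along every axis."""
    if np.isscalar(edges_mm):
        edges_mm = (edges_mm,) * 3  # type: ignore[assignment]
    m = np.ones(like.shape, dtype=bool)
    for ax in range(3):
        pos = np.arange(like.shape[ax]) * like.spacing[ax]
        inside = np.abs(pos - float(center_mm[ax])) <= float(edges_mm[ax]) / 2.0  # type: ignore[index]
        shape = [1, 1, 1]
        shape[ax] = like.shape[ax]
        m &= inside.reshape(shape)
    return Mask(m, like.spacing, like.affine)


def inner_border(m: Mask) -> Mask:
    """One-voxel-thick inner border (6-connectivity; out-of-grid counts as
    foreground, matching the binary-erosion convention)."""
    eroded = ndimage.binary_erosion(m.data, structure=_UNIT_CROSS, border_value=1)
    return m.with_data(m.data & ~eroded)


# ---------------------------------------------------------------------------
# Stage 1


def stage1_brain_marker(
    R0: Volume,
    com_top: Sequence[float],
    params: HumanParams = HumanParams(),
    trace: Optional[StageTrace] = None,
) -> Mask:
    """Brain marker M_A: mid-brightness voxels near the box below COM_top.

    A box (edge ``box_edge_mm``) is centred ``box_below_com_mm`` below
    COM_top; T1_med is the 50% brightness level of R_0 inside the box; the
    band [T1_med, bright_ratio*T1_med] is masked, opened by a small sphere,
    and components touching the box are kept.
    """
    center = np.array(com_top, dtype=float)
    center[2] -= params.box_below_com_mm
    box = box_mask(R0, center, params.box_edge_mm)
    if not box.data.any():
        raise PipelineError("stage1-markers", "marker box lies outside the image")
    t1_med = median_in_mask(R0, box)
    band = R0.new_mask((R0.data >= t1_med) & (R0.data <= params.bright_ratio * t1_med))
    opened = binary_morph(band, "open", params.open_brain_mm)
    m_a = cc_filter(opened, "keep_touching", box)
    if not m_a.data.any():
        raise PipelineError("stage1-markers", "stage-1 brain marker not found")
    if trace is not None:
        trace.add("box", box)
        trace.add("M_A", m_a)
    return m_a


def stage1_background_marker(
    R0: Volume,
    M_A: Mask,
    blanked: Mask,
    params: HumanParams = HumanParams(),
    trace: Optional[StageTrace] = None,
) -> Mask:
    """Background marker N_F: air plus a thin margin of scalp.

    Chain: complement of M_A eroded by a large sphere (N_A); opening by a
    very large sphere and largest component (N_B); bright voxels (Otsu of the
    box-opened image R_A inside N_B) removed (N_C); erosion + largest
    component (N_D); dilation slightly larger than that erosion (N_E); slices
    blanked by neck cropping filled back in (N_F).
    """
    n_a = binary_morph(M_A.with_data(~M_A.data), "erode", params.bg_erode_mm)
    n_b = cc_filter(binary_morph(n_a, "open", params.bg_open_mm), "keep_largest")
    if not n_b.data.any():
        raise PipelineError("stage1-markers", "background region empty after opening")
    r_a = gray_morph(R0, "open", KernelSpec("box", params.gs_open_box_mm))
    thr = otsu_threshold(r_a, region=n_b)
    n_c = n_b.with_data(n_b.data & ~(r_a.data > thr))
    n_d = cc_filter(binary_morph(n_c, "erode", params.bg_erode2_mm), "keep_largest")
    if not n_d.data.any():
        raise PipelineError("stage1-markers", "background marker empty after erosion")
    n_e = binary_morph(n_d, "dilate", params.bg_dilate_mm)
    n_f = n_e.with_data(n_e.data | blanked.data)
    if trace is not None:
        trace.add("N_A", n_a)
        trace.add("N_B", n_b)
        trace.add("R_A", r_a)
        trace.add("N_C", n_c)
        trace.add("N_D", n_d)
        trace.add("N_E", n_e)
        trace.add("N_F", n_f)
    return n_f


def merge_markers(brain: Mask, background: Mask) -> MarkerImage:
    """Combine brain (label 1) and background (label 2) into a marker image."""
    if not brain.same_grid(background):
        raise ValueError("merge_markers: marker grids differ")
    if (brain.data & background.data).any():
        raise ValueError("merge_markers: brain and background markers overlap")
    out = np.zeros(brain.shape, dtype=np.uint8)
    out[brain.data] = 1
    out[background.data] = 2
    return MarkerImage(out, brain.spacing, brain.affine)


def invert_volume(v: Volume) -> Volume:
    """Order-reversing intensity map (max - v); the stage-1 control image."""
    return v.with_data(float(v.data.max()) - v.data)


def stage1_segment(R0: Volume, MN1: MarkerImage) -> Mask:
    """Flood the inverted T1 from MN_1; B_1 is the label-1 region."""
    ws = watershed_from_markers(invert_volume(R0), MN1, required_labels=(1, 2))
    return Mask(ws.data == 1, R0.spacing, R0.affine)


# ---------------------------------------------------------------------------
# Stage 2


def stage2_markers(
    R0: Volume,
    B1: Mask,
    params: HumanParams = HumanParams(),
    trace: Optional[StageTrace] = None,
) -> Tuple[MarkerImage, Mask]:
    """Refined stage-2 markers near the Stage-1 boundary.

    Brain marker M_2: above-median voxels deep inside B_1.  Background
    additions N_bz: very dark voxels (relative to a masked local mean) and
    very bright superior voxels (marrow) in border zones of B_1, small
    components discarded.  N_2 = (complement of B_1) union N_bz.  Returns
    (MN_2, N_bright); N_bright is needed again after the final dilation.
    """
    if not B1.data.any():
        raise PipelineError("stage2-markers", "stage-1 mask is empty")
    sp = R0.spacing
    t50 = median_in_mask(R0, B1)
    b1e = binary_morph(B1, "erode", params.border_zone_mm)
    bz1 = B1.with_data(B1.data & ~b1e.data)
    m2 = B1.with_data((R0.data >= t50) & b1e.data)
    if not m2.data.any():
        raise PipelineError("stage2-markers", "stage-2 brain marker is empty")

    # dark markers: locally dark voxels in the border zone
    r_e1 = gray_morph(R0, "erode", KernelSpec("sphere", params.dark_erode_mm))
    r_b = r_e1.with_data(np.where(B1.data, r_e1.data, 0.0))
    r_lb = masked_mean(R0, B1, KernelSpec("box", params.local_mean_box_mm))
    r_ladj = np.zeros(R0.shape, dtype=np.float32)
    np.divide(r_b.data, r_lb.data, out=r_ladj, where=r_lb.data > 0, casting="unsafe")
    n_dark = B1.with_data((r_ladj < params.dark_fraction) & bz1.data)

    # bright markers: marrow-like voxels in the superior thin border zone
    b2e = binary_morph(B1, "erode", params.bz2_erode_mm)
    bz2 = B1.with_data(B1.data & ~b2e.data)
    n_bright_data = np.zeros(R0.shape, dtype=bool)
    if b1e.data.any():
        z_any = np.flatnonzero(b1e.data.any(axis=(0, 1)))
        inf_mm = z_any[0] * sp[2]
        z_idx = np.arange(R0.shape[2])
        b_sup = (z_idx * sp[2] - inf_mm) >= params.sup_zone_mm
        t50_2 = median_in_mask(R0, m2)
        n_bright_data = (
            (R0.data > params.bright_ratio * t50_2) & bz2.data & b_sup[None, None, :]
        )
    n_bright = B1.with_data(n_bright_data)

    n_bz = cc_filter(B1.with_data(n_dark.data | n_bright.data), "min_volume", params.min_cc_mm3)
    n2 = B1.with_data(~B1.data | n_bz.data)
    mn2 = merge_markers(m2, n2)
    if trace is not None:
        trace.add("B_1e", b1e)
        trace.add("M_2", m2)
        trace.add("R_B", r_b)
        trace.add("R_lb", r_lb)
        trace.add("N_dark", n_dark)
        trace.add("N_bright", n_bright)
        trace.add("N_bz", n_bz)
        trace.add("N_2", n2)
        trace.add("MN_2", mn2)
    return mn2, n_bright


def stage2_control(
    R0: Volume,
    B1: Mask,
    t50: float,
    params: HumanParams = HumanParams(),
    erode_mm: Optional[float] = None,
    trace: Optional[StageTrace] = None,
) -> Volume:
    """Stage-2 control surface R_2 = max(R_D, R_E).

    R_B is the (optionally eroded) T1 masked by B_1; R_C clips R_B at t_50;
    R_D is the bright excess (over their median) of the Stage-1 border
    voxels; R_E is the Gaussian-smoothed masked morphological gradient of
    R_C.  ``erode_mm`` defaults to the dark-marker erosion; pass 0 to skip
    the initial erosion (macaque mode).
    """
    if not B1.data.any():
        raise PipelineError("stage2-control", "stage-1 mask is empty")
    if erode_mm is None:
        erode_mm = params.dark_erode_mm
    base = gray_morph(R0, "erode", KernelSpec("sphere", erode_mm)) if erode_mm > 0 else R0
    r_b = np.where(B1.data, base.data, 0.0).astype(np.float32)
    r_c = np.minimum(r_b, np.float32(t50))
    border = inner_border(B1)
    r_d = np.zeros(R0.shape, dtype=np.float32)
    if border.data.any():
        med = float(np.median(r_c[border.data]))
        r_d[border.data] = np.maximum(r_c[border.data] - med, 0.0)
    r_e = gradient_smooth(R0.with_data(r_c), params.grad_sigma_mm, B1)
    r2 = R0.with_data(np.maximum(r_d, r_e.data))
    if trace is not None:
        trace.add("R_C", R0.with_data(r_c))
        trace.add("R_D", R0.with_data(r_d))
        trace.add("R_E", r_e)
        trace.add("R_2", r2)
    return r2


def stage2_segment(
    R2: Volume,
    MN2: MarkerImage,
    N_bright: Mask,
    final_dilate_mm: float = 1.0,
) -> Mask:
    """Flood R_2 from MN_2; dilate the label-1 region to undo the control
    erosion; remove bright-marker voxels the dilation may have re-included."""
    ws = watershed_from_markers(R2, MN2, required_labels=(1, 2))
    b = Mask(ws.data == 1, R2.spacing, R2.affine)
    if final_dilate_mm > 0:
        b = binary_morph(b, "dilate", final_dilate_mm)
    return b.with_data(b.data & ~N_bright.data)


def smooth_mask(m: Mask, stage: int, params: HumanParams = HumanParams()) -> Mask:
    """Stage 1: opening then closing; stage 2: closing only."""
    if stage == 1:
        return binary_morph(binary_morph(m, "open", params.smooth_open_mm), "close", params.smooth_close_mm)
    if stage == 2:
        return binary_morph(m, "close", params.smooth_close_mm)
    raise ValueError(f"stage must be 1 or 2, got {stage}")


# ---------------------------------------------------------------------------
# Full pipeline


def extract_brain_human(
    v: Volume,
    params: HumanParams = HumanParams(),
    *,
    bias_correct: bool = False,
    smooth: bool = True,
    stage: int = 2,
    crop_extent_mm: float = 180.0,
    com_slab_mm: float = 35.0,
    trace: Optional[StageTrace] = None,
) -> ScalpResult:
    """Run the full human pipeline; all output masks are on the input grid.

    ``stage=1`` stops after the Stage-1 segmentation (stage-2 fields are
    None); ``smooth=False`` skips the smoothing step (smoothed fields None).
    """
    if trace is None:
        trace = StageTrace()
    vcan, ornt = to_canonical(v)

    def back(m: Mask) -> Mask:
        return Mask(from_canonical(m.data, ornt), v.spacing, v.affine)

    r = correct_bias(vcan) if bias_correct else vcan
    crop = crop_neck(r, crop_extent_mm, com_slab_mm)
    r0 = crop.volume
    trace.add("R_0", r0)
    trace.add("blanked", crop.blanked_mask)

    m_a = stage1_brain_marker(r0, crop.com_top, params, trace)
    n_f = stage1_background_marker(r0, m_a, crop.blanked_mask, params, trace)
    try:
        mn1 = merge_markers(m_a, n_f)
    except ValueError as e:
        raise PipelineError("stage1-markers", str(e)) from e
    trace.add("MN_1", mn1)
    b1 = stage1_segment(r0, mn1)
    trace.add("B_1", b1)

    b2 = None
    if stage >= 2:
        mn2, n_bright = stage2_markers(r0, b1, params, trace)
        t50 = median_in_mask(r0, b1)
        r2 = stage2_control(r0, b1, t50, params, trace=trace)
        b2 = stage2_segment(r2, mn2, n_bright, params.final_dilate_mm)
        trace.add("B_2", b2)

    s1 = s2 = None
    if smooth:
        s1 = smooth_mask(b1, 1, params)
        trace.add("B_1_smooth", s1)
        if b2 is not None:
            s2 = smooth_mask(b2, 2, params)
            trace.add("B_2_smooth", s2)

    return ScalpResult(
        stage1_mask=back(b1),
        stage2_mask=back(b2) if b2 is not None else None,
        stage1_smoothed=back(s1) if s1 is not None else None,
        stage2_smoothed=back(s2) if s2 is not None else None,
        trace=trace,
    )
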