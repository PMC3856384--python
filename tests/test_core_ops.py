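"""Unit and property tests for the core primitives (oracle checks, the
spec'd examples, and structural invariants)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wscalp import (
    DegenerateHistogramError,
    KernelSpec,
    MarkerError,
    MarkerImage,
    Mask,
    Volume,
    binary_morph,
    box_mean,
    cc_filter,
    gradient_smooth,
    gray_morph,
    impose_minima,
    masked_mean,
    otsu_threshold,
    quantile_in_mask,
    watershed_from_markers,
)
from wscalp.grid import GridError, box_extents, mm_to_voxels

import oracles


def vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.float32), spacing)


def mask(data, spacing=(1.0, 1.0, 1.0)):
    return Mask(np.asarray(data, dtype=bool), spacing)


# ---------------------------------------------------------------------------
# mm -> voxel conversion


def test_mm_to_voxels_unit_spacing():
    assert tuple(mm_to_voxels(2.0, (1, 1, 1))) == (2, 2, 2)


def test_mm_to_voxels_zero():
    assert tuple(mm_to_voxels(0.0, (0.5, 1, 3))) == (0, 0, 0)


def test_mm_to_voxels_aniso_floor_to_one():
    assert tuple(mm_to_voxels(2.0, (0.9, 0.9, 3.0))) == (2, 2, 1)


def test_mm_to_voxels_negative_rejected():
    with pytest.raises(GridError):
        mm_to_voxels(-1.0, (1, 1, 1))


def test_box_extents_odd():
    ext = box_extents((5.0, 4.0, 0.0), (1, 1, 1))
    assert all(e % 2 == 1 for e in ext)
    assert tuple(ext) == (5, 5, 1)


# ---------------------------------------------------------------------------
# binary morphology


def test_binary_erode_zero_radius_identity():
    rng = np.random.default_rng(0)
    m = mask(rng.random((8, 8, 8)) > 0.5)
    assert np.array_equal(binary_morph(m, "erode", 0.0).data, m.data)


def test_binary_erode_empty_stays_empty():
    m = mask(np.zeros((6, 6, 6)))
    assert not binary_morph(m, "erode", 3.0).data.any()


def test_binary_erode_solid_cube_matches_oracle():
    m = np.zeros((11, 11, 11), dtype=bool)
    m[1:10, 1:10, 1:10] = True
    got = binary_morph(mask(m), "erode", 2.0).data
    want = oracles.binary_erode_oracle(m, 2.0, (1, 1, 1))
    assert np.array_equal(got, want)


@given(st.integers(0, 10_000))
def test_binary_morph_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 12, size=3))
    sp = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
    m = rng.random(shape) > rng.uniform(0.3, 0.7)
    r = float(rng.uniform(0.4, 3.1))
    op = str(rng.choice(["erode", "dilate", "open", "close"]))
    got = binary_morph(Mask(m, sp), op, r).data
    want = oracles.binary_morph_oracle(m, op, r, sp)
    assert np.array_equal(got, want)


def test_binary_duality_on_padded_grid():
    rng = np.random.default_rng(3)
    inner = rng.random((6, 6, 6)) > 0.5
    m = np.zeros((14, 14, 14), dtype=bool)
    m[4:10, 4:10, 4:10] = inner
    a = binary_morph(mask(m), "dilate", 1.8).data
    b = ~binary_morph(mask(~m), "erode", 1.8).data
    assert np.array_equal(a, b)


def test_binary_open_close_idempotent():
    rng = np.random.default_rng(4)
    m = mask(rng.random((10, 10, 10)) > 0.5)
    for op in ("open", "close"):
        once = binary_morph(m, op, 1.5)
        twice = binary_morph(once, op, 1.5)
        assert np.array_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# grayscale morphology


def test_gray_constant_fixed_point():
    v = vol(np.full((8, 8, 8), 7.0))
    for op in ("erode", "dilate", "open", "close"):
        out = gray_morph(v, op, KernelSpec("box", 3.0))
        assert np.allclose(out.data, 7.0)


def test_gray_dilate_impulse_box_plateau():
    v = np.zeros((9, 9, 9), dtype=np.float32)
    v[4, 4, 4] = 5.0
    out = gray_morph(vol(v), "dilate", KernelSpec("box", 3.0)).data
    want = np.zeros_like(v)
    want[3:6, 3:6, 3:6] = 5.0
    assert np.array_equal(out, want)


def test_gray_open_anti_extensive():
    rng = np.random.default_rng(5)
    v = vol(rng.random((16, 16, 16)).astype(np.float32))
    out = gray_morph(v, "open", KernelSpec("sphere", 1.5))
    assert np.all(out.data <= v.data + 1e-6)


@given(st.integers(0, 10_000))
def test_gray_morph_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 10, size=3))
    sp = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
    v = rng.random(shape).astype(np.float32) * 100
    op = str(rng.choice(["erode", "dilate", "open", "close"]))
    if rng.random() < 0.5:
        kernel, kshape, ksize = KernelSpec("sphere", 1.7), "sphere", 1.7
    else:
        edges = tuple(float(e) for e in rng.uniform(1, 5, size=3))
        kernel, kshape, ksize = KernelSpec("box", edges), "box", edges
    got = gray_morph(Volume(v, sp), op, kernel).data
    want = oracles.gray_morph_oracle(v, op, kshape, ksize, sp)
    assert np.allclose(got, want)


# ---------------------------------------------------------------------------
# means


def test_box_mean_constant():
    v = vol(np.full((8, 8, 8), 3.5))
    assert np.allclose(box_mean(v, 5.0).data, 3.5)


def test_box_mean_impulse_counting():
    v = np.zeros((9, 9, 9), dtype=np.float32)
    v[4, 4, 4] = 27.0
    out = box_mean(vol(v), 1.0).data
    assert out[4, 4, 4] == pytest.approx(27.0 / 27.0)


@given(st.integers(0, 10_000))
def test_box_mean_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 13, size=3))
    sp = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
    v = rng.random(shape).astype(np.float32) * 10
    r = float(rng.uniform(0.5, 4.0))
    got = box_mean(Volume(v, sp), r).data
    want = oracles.box_mean_oracle(v, r, sp)
    assert np.allclose(got, want, rtol=1e-5, atol=1e-5)


def test_masked_mean_full_mask_equals_box_mean():
    rng = np.random.default_rng(7)
    v = Volume(rng.random((8, 8, 8)).astype(np.float32), (1, 1, 1))
    m = Mask(np.ones((8, 8, 8), dtype=bool), (1, 1, 1))
    a = masked_mean(v, m, KernelSpec("box", 5.0)).data
    b = box_mean(v, 2.0).data  # 5 mm edge -> 5-voxel window -> half-extent 2
    assert np.allclose(a, b, rtol=1e-5, atol=1e-5)


def test_masked_mean_single_voxel_mask():
    v = np.zeros((7, 7, 7), dtype=np.float32)
    v[3, 3, 3] = 42.0
    m = np.zeros((7, 7, 7), dtype=bool)
    m[3, 3, 3] = True
    out = masked_mean(vol(v), mask(m), KernelSpec("box", 3.0)).data
    assert out[2, 2, 2] == pytest.approx(42.0)
    assert out[3, 3, 3] == pytest.approx(42.0)
    assert out[0, 0, 0] == 0.0  # window does not reach the voxel -> 0


@given(st.integers(0, 10_000))
def test_masked_mean_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 11, size=3))
    sp = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
    v = rng.random(shape).astype(np.float32) * 10
    m = rng.random(shape) > 0.6
    edges = tuple(float(e) for e in rng.uniform(1, 6, size=3))
    got = masked_mean(Volume(v, sp), Mask(m, sp), KernelSpec("box", edges)).data
    want = oracles.masked_mean_oracle(v, m, edges, sp)
    assert np.allclose(got, want, rtol=1e-5, atol=1e-5)


# ---------------------------------------------------------------------------
# thresholds and quantiles


def test_otsu_bimodal_between_modes():
    data = np.concatenate([np.full(50, 10.0), np.full(50, 90.0)])
    rng = np.random.default_rng(0)
    rng.shuffle(data)
    v = vol(np.resize(data, (5, 5, 4)))
    t = otsu_threshold(v)
    assert 10.0 < t < 90.0


def test_otsu_constant_region_errors():
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(vol(np.full((4, 4, 4), 5.0)))


@given(st.integers(0, 10_000))
def test_otsu_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 12, size=3))
    v = (rng.random(shape) * rng.uniform(5, 500)).astype(np.float32)
    got = otsu_threshold(Volume(v, (1, 1, 1)))
    want = oracles.otsu_oracle(v)
    assert got == pytest.approx(want)


def test_otsu_scale_covariance_within_one_bin():
    rng = np.random.default_rng(11)
    v = rng.random((10, 10, 10)).astype(np.float32) * 100
    a, b = 3.0, 17.0
    t0 = otsu_threshold(Volume(v, (1, 1, 1)))
    t1 = otsu_threshold(Volume((a * v + b).astype(np.float32), (1, 1, 1)))
    bin_width = a * (v.max() - v.min()) / 128
    assert abs(t1 - (a * t0 + b)) <= bin_width + 1e-3


def test_quantile_extremes_and_median():
    v = vol(np.arange(1, 101, dtype=np.float32).reshape(5, 5, 4))
    assert quantile_in_mask(v, None, 0.0) == 1.0
    assert quantile_in_mask(v, None, 1.0) == 100.0
    assert quantile_in_mask(v, None, 0.5) == 50.0  # nearest rank: ceil(50)=50th


@given(st.integers(0, 10_000))
def test_quantile_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 10, size=3))
    v = rng.random(shape).astype(np.float32)
    m = rng.random(shape) > 0.4
    if not m.any():
        m.flat[0] = True
    q = float(rng.random())
    got = quantile_in_mask(Volume(v, (1, 1, 1)), Mask(m, (1, 1, 1)), q)
    assert got == pytest.approx(oracles.quantile_oracle(v[m], q))


def test_quantile_empty_region_errors():
    with pytest.raises(ValueError):
        quantile_in_mask(vol(np.ones((3, 3, 3))), mask(np.zeros((3, 3, 3))), 0.5)


# ---------------------------------------------------------------------------
# connected-component filtering


def test_cc_empty_mask():
    m = mask(np.zeros((5, 5, 5)))
    assert not cc_filter(m, "keep_largest").data.any()


def test_cc_keep_largest_two_components():
    m = np.zeros((10, 5, 5), dtype=bool)
    m[0:2, 0, 0] = True  # 2 voxels
    m[5:9, 0:2, 0] = True  # 8 voxels
    out = cc_filter(mask(m), "keep_largest").data
    assert out.sum() == 8 and not out[0, 0, 0]


def test_cc_min_volume_spacing_aware():
    m = np.zeros((8, 8, 8), dtype=bool)
    m[0, 0, 0] = True  # 1 voxel = 8 mm^3 at 2 mm spacing -> dropped
    m[4, 4, 4:6] = True  # 2 voxels = 16 mm^3 -> kept
    out = cc_filter(Mask(m, (2, 2, 2)), "min_volume", 10.0).data
    assert not out[0, 0, 0] and out[4, 4, 4] and out[4, 4, 5]


@given(st.integers(0, 10_000))
def test_cc_filter_oracle_random(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 12, size=3))
    sp = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
    m = rng.random(shape) > 0.7
    mode = str(rng.choice(["keep_largest", "min_volume", "keep_touching"]))
    if mode == "min_volume":
        arg = float(rng.uniform(0.5, 20.0))
        got = cc_filter(Mask(m, sp), mode, arg).data
        want = oracles.cc_filter_oracle(m, mode, arg, sp)
    elif mode == "keep_touching":
        ref = rng.random(shape) > 0.8
        got = cc_filter(Mask(m, sp), mode, Mask(ref, sp)).data
        want = oracles.cc_filter_oracle(m, mode, ref, sp)
    else:
        got = cc_filter(Mask(m, sp), mode).data
        want = oracles.cc_filter_oracle(m, mode, None, sp)
    if mode == "keep_largest" and m.any():
        # tie rule: both keep exactly one component of maximal size
        assert got.sum() == want.sum()
        assert np.array_equal(got, want)
    else:
        assert np.array_equal(got, want)


# ---------------------------------------------------------------------------
# gradient


def test_gradient_constant_zero():
    v = vol(np.full((8, 8, 8), 4.0))
    m = mask(np.ones((8, 8, 8)))
    assert np.allclose(gradient_smooth(v, 1.0, m).data, 0.0)


def test_gradient_step_edge_peaks_at_edge():
    v = np.zeros((8, 8, 8), dtype=np.float32)
    v[4:, :, :] = 10.0
    m = mask(np.ones((8, 8, 8)))
    out = gradient_smooth(vol(v), 1.0, m).data
    profile = out[:, 4, 4]
    peak = np.argmax(profile)
    assert peak in (3, 4)
    assert profile[0] < profile[3] and profile[7] < profile[4]


def test_gradient_nonnegative_random():
    rng = np.random.default_rng(13)
    v = vol(rng.random((10, 10, 10)).astype(np.float32))
    m = mask(rng.random((10, 10, 10)) > 0.3)
    assert np.all(gradient_smooth(v, 1.0, m).data >= 0)


def test_gradient_masked_no_border_response():
    # constant inside the mask: the masked min/max sees no outside voxels,
    # so there is no spurious edge at the mask border
    v = vol(np.where(np.arange(8)[:, None, None] < 4, 5.0, 100.0) * np.ones((8, 8, 8)))
    m = mask(np.arange(8)[:, None, None] < 4 * np.ones((8, 8, 8), dtype=int))
    out = gradient_smooth(v, 1.0, m)
    assert np.allclose(out.data, 0.0, atol=1e-5)


# ---------------------------------------------------------------------------
# watershed + imposition


def ws(control, markers, spacing=(1, 1, 1)):
    return watershed_from_markers(
        Volume(np.asarray(control, dtype=np.float32), spacing),
        MarkerImage(np.asarray(markers, dtype=np.uint8), spacing),
    )


def test_watershed_single_marker_floods_all():
    rng = np.random.default_rng(0)
    control = rng.random((6, 6, 6))
    markers = np.zeros((6, 6, 6), dtype=np.uint8)
    markers[3, 3, 3] = 1
    out = ws(control, markers)
    assert np.all(out.data == 1)


def test_watershed_1d_ridge_fifo():
    control = np.array([0.0, 1.0, 5.0, 1.0, 0.0]).reshape(5, 1, 1)
    markers = np.zeros((5, 1, 1), dtype=np.uint8)
    markers[0], markers[4] = 1, 2
    out = ws(control, markers).data[:, 0, 0]
    assert list(out[:2]) == [1, 1] and list(out[3:]) == [2, 2]
    # the ridge voxel goes to the front whose entry was pushed first (label 1,
    # pushed when index 1 popped before index 3 by seed age)
    assert out[2] == 1


def test_watershed_marker_preservation_random():
    rng = np.random.default_rng(1)
    control = rng.standard_normal((12, 12, 12))
    markers = np.zeros((12, 12, 12), dtype=np.uint8)
    for lbl in (1, 2, 3):
        i, j, k = rng.integers(0, 12, size=3)
        markers[i, j, k] = lbl
    out = ws(control, markers)
    keep = markers > 0
    assert np.array_equal(out.data[keep], markers[keep])
    assert np.all(out.data > 0)


def test_watershed_missing_required_label():
    markers = np.zeros((4, 4, 4), dtype=np.uint8)
    markers[0, 0, 0] = 1
    v = Volume(np.zeros((4, 4, 4), dtype=np.float32) + np.arange(4)[None, None, :], (1, 1, 1))
    with pytest.raises(MarkerError):
        watershed_from_markers(v, MarkerImage(markers, (1, 1, 1)), required_labels=(1, 2))


def test_watershed_empty_markers_error():
    markers = np.zeros((4, 4, 4), dtype=np.uint8)
    v = Volume(np.ones((4, 4, 4), dtype=np.float32), (1, 1, 1))
    v.data[0, 0, 0] = 0
    with pytest.raises(MarkerError):
        watershed_from_markers(v, MarkerImage(markers, (1, 1, 1)))


@given(st.integers(0, 10_000))
def test_watershed_matches_pure_python_oracle(seed):
    rng = np.random.default_rng(seed)
    control = rng.standard_normal((8, 8, 8))
    markers = np.zeros((8, 8, 8), dtype=np.uint8)
    n_labels = int(rng.integers(2, 5))
    for lbl in range(1, n_labels + 1):
        i, j, k = rng.integers(0, 8, size=3)
        markers[i, j, k] = lbl
    got = ws(control.astype(np.float32), markers).data
    want = oracles.watershed_oracle(
        Volume(control.astype(np.float32), (1, 1, 1)).data, markers
    )
    assert np.array_equal(got, want)


def test_impose_minima_all_marker_flat():
    control = np.arange(27, dtype=float).reshape(3, 3, 3)
    out = impose_minima(control, np.ones((3, 3, 3), dtype=bool))
    assert np.allclose(out, out.min())


def test_impose_minima_1d_two_wells():
    # two wells, only one marked: the unmarked well must be filled
    sig = np.array([3, 1, 3, 0, 3, 2, 3], dtype=float).reshape(-1, 1, 1)
    markers = np.zeros(sig.shape, dtype=bool)
    markers[3] = True  # mark the 0-well only
    out = impose_minima(sig, markers)
    minima = oracles.regional_minima_oracle(out)
    lab, n = oracles.label_oracle(minima)
    for lbl in range(1, n + 1):
        assert (markers & (lab == lbl)).any()


def test_impose_minima_bounds():
    rng = np.random.default_rng(2)
    control = rng.random((6, 6, 6))
    markers = rng.random((6, 6, 6)) > 0.8
    if not markers.any():
        markers[0, 0, 0] = True
    out = impose_minima(control, markers)
    nonmark = ~markers
    # reconstruction-by-erosion fills spurious wells: values only go up
    assert np.all(out[nonmark] >= control[nonmark] - 1e-9)
    assert np.all(out[nonmark] <= control.max() + 1e-9)
    assert np.all(out[markers] < control.min())
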