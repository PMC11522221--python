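import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skelseg import (
    CTVolume,
    MarginLines,
    PhantomSpec,
    RegionBands,
    adapt_mask_to_slice,
    binarize_slice,
    build_margin_polyline,
    fill_stretcher_mask,
    generate_phantom,
    locate_margin_lines,
    remove_stretcher,
)
from skelseg.errors import NoStretcherError
from skelseg.phantom import Tissue


# ---------------------------------------------------------------------- binarize


def test_binarize_threshold_is_inclusive():
    slice_hu = np.array([[97.0, 98.0, 99.0, -1000.0]])
    np.testing.assert_array_equal(binarize_slice(slice_hu), [[0, 1, 1, 0]])


def test_binarize_all_air_is_all_zero():
    assert binarize_slice(np.full((8, 8), -1000.0)).sum() == 0


def test_binarize_matches_per_pixel_rule_on_phantom(phantom_pair):
    ct, truth = phantom_pair
    s = ct.voxels[0]
    expected = (s >= 98).astype(np.uint8)  # brute-force per-pixel oracle
    np.testing.assert_array_equal(binarize_slice(s), expected)


# ------------------------------------------------------------------ margin lines


def _bar_slice(height=64, width=64, bar=(5, 10), body=40):
    binary = np.zeros((height, width), dtype=np.uint8)
    binary[:, bar[0] : bar[1] + 1] = 1
    binary[:, body:] = 1
    return binary


def test_vertical_bar_gives_equal_midpoint_lines():
    lines = locate_margin_lines(_bar_slice())
    assert lines.i1 == lines.i2 == lines.i3
    assert 10 < lines.i3 < 40


def test_curved_stretcher_gives_ordered_lines(phantom_pair):
    ct, _ = phantom_pair
    lines = locate_margin_lines(binarize_slice(ct.voxels[0]))
    assert lines.i3 < lines.i2 < lines.i1


def test_all_background_raises_no_stretcher():
    with pytest.raises(NoStretcherError):
        locate_margin_lines(np.zeros((64, 64), dtype=np.uint8))


def test_body_only_slice_raises_no_stretcher():
    binary = np.zeros((64, 64), dtype=np.uint8)
    binary[:, 40:] = 1  # foreground only in the right part
    with pytest.raises(NoStretcherError):
        locate_margin_lines(binary)


def test_margin_sandwich_on_phantom_bands(phantom_pair):
    """Each line sits strictly between couch inner edge and body edge in its bands."""
    ct, truth = phantom_pair
    binary = binarize_slice(ct.voxels[0])
    lines = locate_margin_lines(binary)
    bands = RegionBands.from_height(64)
    stretcher = truth.labels[0] == Tissue.STRETCHER
    bone = np.isin(truth.labels[0], (Tissue.CORTICAL, Tissue.MARROW))
    cols = np.arange(64)
    for line, band_ids in [(lines.i1, (3, 4)), (lines.i2, (2, 5)), (lines.i3, (1, 6))]:
        rows = np.zeros(64, dtype=bool)
        for b in band_ids:
            rows[bands.boundaries[b] : bands.boundaries[b + 1]] = True
        inner = cols[stretcher[rows].any(axis=0)].max()
        body = cols[bone[rows].any(axis=0)].min()
        assert inner < line < body


# --------------------------------------------------------------------- polyline


def test_degenerate_polyline_is_single_vertical_line():
    lines = MarginLines(i1=7, i2=7, i3=7, width=64)
    poly = build_margin_polyline(lines, RegionBands.from_height(64))
    assert poly.points == ((0, 7), (63, 7))
    assert set(poly.columns) == {7}


def test_polyline_vertices_follow_band_schedule():
    lines = MarginLines(i1=50, i2=40, i3=30, width=80)
    poly = build_margin_polyline(lines, RegionBands.from_height(80))
    assert [p[0] for p in poly.points] == [0, 20, 30, 50, 60, 79]
    assert [p[1] for p in poly.points] == [30, 40, 50, 50, 40, 30]
    # schedule i3,i3,i2,i1,i1,i2,i3,i3 over the eight bands
    assert poly.columns[5] == 30 and poly.columns[25] == 40 and poly.columns[45] == 50
    assert poly.columns[55] == 40 and poly.columns[75] == 30


def test_height8_staircase_has_monotone_rows():
    lines = MarginLines(i1=5, i2=4, i3=3, width=8)
    poly = build_margin_polyline(lines, RegionBands.from_height(8))
    rows = [p[0] for p in poly.points]
    assert rows == sorted(rows) and len(set(rows)) == len(rows)
    assert rows[0] == 0 and rows[-1] == 7
    assert set(poly.columns) <= {3, 4, 5}
    assert all(c in {3, 4, 5} for _, c in poly.points)


def test_polyline_labels_traverse_in_paper_order():
    lines = MarginLines(i1=50, i2=40, i3=30, width=80)
    poly = build_margin_polyline(lines, RegionBands.from_height(80))
    assert [name for name, _ in poly.labels] == [
        "Pe1", "Pi1", "Pi3", "Pe3", "Pe4", "Pi4", "Pi2", "Pe2",
    ]
    label_rows = [pt[0] for _, pt in poly.labels]
    assert label_rows == sorted(label_rows)


# ------------------------------------------------------------------------- fill


def test_fill_vertical_polyline_counts():
    bands = RegionBands.from_height(16)
    for c in (0, 5):
        poly = build_margin_polyline(MarginLines(c, c, c, width=16), bands)
        mask = fill_stretcher_mask(poly, (16, 16))
        assert mask.sum() == 16 * (c + 1)
        np.testing.assert_array_equal(mask[:, : c + 1], 1)


def test_fill_staircase_matches_left_flood_fill():
    lines = MarginLines(i1=50, i2=40, i3=30, width=80)
    bands = RegionBands.from_height(80)
    poly = build_margin_polyline(lines, bands)
    mask = fill_stretcher_mask(poly, (80, 80))
    assert mask.sum() == sum(c + 1 for c in poly.columns)


@given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
def test_fill_is_row_wise_left_anchored(a, b, c):
    i3, i2, i1 = sorted((a, b, c))
    poly = build_margin_polyline(MarginLines(i1, i2, i3, width=16), RegionBands.from_height(16))
    mask = fill_stretcher_mask(poly, (16, 16))
    # if mask[r, c] = 1 and c > 0 then mask[r, c-1] = 1
    assert np.all(np.diff(mask.astype(int), axis=1) <= 0)


# ------------------------------------------------------------------------ adapt


def test_adapt_radius_zero_no_accessory_is_identity():
    ref = np.zeros((16, 16), dtype=np.uint8)
    ref[:, :4] = 1
    out = adapt_mask_to_slice(ref, np.zeros_like(ref), dilation_radius=0)
    np.testing.assert_array_equal(out, ref)


def test_adapt_single_pixel_radius_one_square_gives_nine():
    ref = np.zeros((9, 9), dtype=np.uint8)
    ref[4, 4] = 1
    out = adapt_mask_to_slice(ref, np.zeros_like(ref), dilation_radius=1)
    assert out.sum() == 9
    np.testing.assert_array_equal(out[3:6, 3:6], 1)


def test_adapt_absorbs_mostly_overlapping_accessory():
    ref = np.zeros((20, 20), dtype=np.uint8)
    ref[:, :8] = 1
    blob = np.zeros_like(ref)
    blob[5:10, 4:9] = 1  # 25 px; 5x4 = 20 overlap ref cols 0..7 -> 80% > 50%
    out = adapt_mask_to_slice(ref, blob, dilation_radius=0, accessory_fraction=0.5)
    assert np.all(out[blob.astype(bool)] == 1)
    far = np.zeros_like(ref)
    far[5:10, 14:19] = 1  # 0% overlap -> not absorbed
    out2 = adapt_mask_to_slice(ref, far, dilation_radius=0, accessory_fraction=0.5)
    assert np.all(out2[far.astype(bool)] == 0)


# -------------------------------------------------------------- remove_stretcher


def test_remove_without_stretcher_returns_identity(caplog):
    voxels = np.full((3, 64, 64), -1000.0)
    voxels[:, 20:40, 30:50] = 40.0  # body only, below 98 HU
    vol = CTVolume(voxels)
    out, mask = remove_stretcher(vol)
    np.testing.assert_array_equal(out.voxels, vol.voxels)
    assert mask.voxels.sum() == 0


def test_remove_strips_all_slices_and_zeroes_region(phantom_pair):
    ct, truth = phantom_pair
    out, mask = remove_stretcher(ct)
    m = mask.voxels.astype(bool)
    assert np.all(out.voxels[m] == 0)
    # untouched pixels are bit-identical
    np.testing.assert_array_equal(out.voxels[~m], ct.voxels[~m])
    # every slice's couch is fully inside the adapted mask
    for s in range(ct.slice_count):
        true_s = truth.stretcher.voxels[s].astype(bool)
        assert np.all(m[s][true_s])


def test_remove_zeroes_accessory_only_on_its_slice():
    spec = PhantomSpec(seed=9, noise_sd=0.0, accessory_slices=(2,))
    ct, truth = generate_phantom(spec)
    out, mask = remove_stretcher(ct)
    acc = truth.labels == Tissue.ACCESSORY
    assert acc[2].any() and not acc[1].any()
    assert np.all(out.voxels[2][acc[2]] == 0)


def test_mask_never_touches_bone_across_random_phantoms(small_cohort):
    from skelseg.phantom import random_spec

    rng = np.random.default_rng(20240)
    for _ in range(5):
        spec = random_spec(rng)
        ct, truth = generate_phantom(spec)
        _, mask = remove_stretcher(ct)
        m = mask.voxels.astype(bool)
        bone = truth.skeleton.voxels.astype(bool)
        stretcher = truth.stretcher.voxels.astype(bool)
        assert (m & bone).sum() == 0
        assert (m & stretcher).sum() / stretcher.sum() >= 0.99
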