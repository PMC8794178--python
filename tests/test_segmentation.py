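"""Segmentation-stage contracts, with brute-force oracles for Otsu."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from cellchannel.segmentation import (
    RegionLabelMap,
    binarize_and_clean,
    filter_by_area,
    match_regions,
    otsu_threshold,
    pixels_to_um2,
    segment_field,
    split_touching,
)


def otsu_brute_force(image, nbins=256):
    """Independent exhaustive search over all histogram cut points."""
    image = np.asarray(image)
    lo, hi = float(image.min()), float(image.max())
    counts, edges = np.histogram(image.ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_v = None, -1.0
    for t in range(nbins - 1):
        if counts[t] == 0:
            continue  # same partition as the cut after the previous bin
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        m1 = (counts[t + 1:] * centers[t + 1:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return float(centers[best_t])


def test_otsu_two_level_image():
    img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
    thr = otsu_threshold(img)
    assert 10 < thr < 200


def test_otsu_three_value_skewed_counts():
    img = np.concatenate([np.zeros(100), [100.0], [101.0]])
    thr = otsu_threshold(img)
    assert 0 < thr < 100  # separates 0 from {100, 101}


def test_otsu_constant_image_raises():
    with pytest.raises(ValueError):
        otsu_threshold(np.full((5, 5), 7.0))


@pytest.mark.parametrize("seed", range(25))
def test_otsu_equals_brute_force_random_images(seed):
    rng = np.random.default_rng(seed)
    kind = seed % 3
    if kind == 0:
        img = rng.integers(0, 256, (24, 24)).astype(float)
    elif kind == 1:
        img = np.concatenate([rng.normal(40, 5, 300), rng.normal(160, 20, 200)])
    else:
        img = rng.exponential(50, (20, 20))
    assert otsu_threshold(img) == pytest.approx(otsu_brute_force(img))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.integers(0, 255), min_size=4, max_size=120).filter(
    lambda v: len(set(v)) > 1))
def test_otsu_equals_brute_force_property(values):
    img = np.asarray(values, dtype=float)
    assert otsu_threshold(img) == pytest.approx(otsu_brute_force(img))


def test_border_touching_component_removed():
    img = np.full((60, 60), 100.0)
    img[0:12, 0:12] = 10.0     # touches the border
    img[30:42, 30:42] = 10.0   # interior
    mask = binarize_and_clean(img, otsu_threshold(img), closing_radius=0)
    lab, n = ndi.label(mask)
    assert n == 1
    assert mask[35, 35] and not mask[5, 5]


def test_hole_filled_area_increases_by_hole_size():
    img = np.full((40, 40), 100.0)
    img[10:20, 10:20] = 10.0
    img[14, 14:19] = 100.0  # 5-px hole
    mask = binarize_and_clean(img, 50.0, closing_radius=0)
    assert mask.sum() == 100  # hole of 5 px filled back to the full square


def test_closing_bridges_small_gap():
    """A 1-px gap between two blobs closes with the radius-3 disc; the
    oracle is dilation-then-erosion by the same element."""
    from skimage.morphology import dilation, disk, erosion

    img = np.full((40, 60), 100.0)
    img[15:25, 10:29] = 10.0
    img[15:25, 30:50] = 10.0  # 1-px bright gap at column 29
    raw = img <= 50.0
    mask = binarize_and_clean(img, 50.0, closing_radius=3)
    oracle = erosion(dilation(raw, disk(3)), disk(3))
    lab, n = ndi.label(mask)
    assert n == 1
    lab_o, n_o = ndi.label(oracle)
    assert n_o == 1


def _disc_mask(shape, center, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def test_split_touching_two_overlapping_discs():
    mask = np.zeros((120, 160), dtype=bool)
    c1, c2 = (60, 50), (60, 94)  # radius 25, overlap 6 px along the axis
    mask |= _disc_mask(mask.shape, c1, 25)
    mask |= _disc_mask(mask.shape, c2, 25)
    regions = split_touching(mask)
    assert len(regions) == 2
    l1 = regions.labels[c1]
    l2 = regions.labels[c2]
    assert l1 != l2 and l1 > 0 and l2 > 0


def test_split_single_disc_passes_through():
    mask = np.zeros((100, 100), dtype=bool)
    mask |= _disc_mask(mask.shape, (50, 50), 30)
    regions = split_touching(mask)
    assert len(regions) == 1
    assert regions.labels.astype(bool).sum() == mask.sum()


def test_split_empty_mask():
    regions = split_touching(np.zeros((50, 50), dtype=bool))
    assert len(regions) == 0


def test_split_partitions_foreground(small_field):
    img, _ = small_field
    ph = img.plane("ph")
    mask = binarize_and_clean(ph, otsu_threshold(ph))
    regions = split_touching(mask)
    assert np.array_equal(regions.labels > 0, mask)
    areas = np.bincount(regions.labels.ravel())[1:]
    assert np.array_equal(np.sort(areas),
                          np.sort(regions.table.area_px.to_numpy()))


def test_area_filter_bounds_exclusive():
    labels = np.zeros((200, 600), dtype=np.int32)
    sizes = {1: 2000, 2: 2001, 3: 7999, 4: 8000}
    col = 0
    for lab, size in sizes.items():
        rows = size // 40
        labels[0:40, col:col + rows] = lab  # 40*rows px
        rem = size - 40 * rows
        if rem:
            labels[40:40 + rem, col] = lab
        col += rows + 2
    regions = RegionLabelMap.from_labels(labels)
    assert sorted(regions.table.area_px) == [2000, 2001, 7999, 8000]
    kept = filter_by_area(regions)
    assert sorted(kept.table.area_px) == [2001, 7999]
    assert sorted(kept.table.label) == [1, 2]  # relabelled consecutively


def test_area_filter_empty_input():
    empty = RegionLabelMap.from_labels(np.zeros((10, 10), dtype=np.int32))
    assert len(filter_by_area(empty)) == 0


def test_pixel_to_physical_area_conversion():
    assert f"{pixels_to_um2(2000):.4g}" == "52.81"
    assert f"{pixels_to_um2(8000):.4g}" == "211.2"


def test_polarity_flag_handles_bright_cells(small_field):
    img, truth = small_field
    ph = img.plane("ph")
    inverted = ph.max() - ph  # bright cell bodies
    thr = otsu_threshold(inverted)
    mask = binarize_and_clean(inverted, thr, polarity="bright")
    regions = split_touching(mask)
    m = match_regions(truth.label_mask, regions.labels)
    assert (m.iou > 0.6).mean() >= 0.95


def test_full_segmentation_recovers_synthetic_cells(small_field):
    img, truth = small_field
    regions = segment_field(img.plane("ph"))
    m = match_regions(truth.label_mask, regions.labels)
    assert len(m) == len(truth.cells)
    assert (m.iou >= 0.6).all()
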