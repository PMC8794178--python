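"""Cell segmentation from the phase-contrast channel.

The stage chain is: Otsu intensity threshold, binarisation (dark cell bodies
below the threshold by default), morphological closing, removal of
border-touching components, hole filling, then watershed splitting of
touching cells seeded at local maxima of the Gaussian-smoothed Euclidean
distance transform, and finally an exclusive pixel-area band filter
(2000 < area < 8000 by default; at 162.5 nm/px those bounds correspond to
52.81 and 211.2 square microns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table
from skimage.morphology import closing as _closing, disk
from skimage.segmentation import clear_border, watershed

#: default pixel-area band (exclusive bounds) and physical pixel pitch
MIN_AREA_PX = 2000
MAX_AREA_PX = 8000
NM_PER_PIXEL = 162.5


@dataclass
class RegionLabelMap:
    """Integer label image (0 = background) plus its region table."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: label, area_px, centroid_y, centroid_x, bbox_*

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "RegionLabelMap":
        labels = np.asarray(labels)
        if labels.max() == 0:
            table = pd.DataFrame(columns=["label", "area_px", "centroid_y",
                                          "centroid_x", "bbox_r0", "bbox_c0",
                                          "bbox_r1", "bbox_c1"])
            return cls(labels=labels.astype(np.int32), table=table)
        props = regionprops_table(
            labels, properties=("label", "area", "centroid", "bbox"))
        table = pd.DataFrame({
            "label": props["label"].astype(int),
            "area_px": props["area"].astype(int),
            "centroid_y": props["centroid-0"],
            "centroid_x": props["centroid-1"],
            "bbox_r0": props["bbox-0"], "bbox_c0": props["bbox-1"],
            "bbox_r1": props["bbox-2"], "bbox_c1": props["bbox-3"],
        })
        return cls(labels=labels.astype(np.int32), table=table)

    def __len__(self) -> int:
        return len(self.table)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing intensity threshold.

    The histogram uses ``nbins`` bins over the image min–max range; the
    returned threshold is the center of the last bin of the lower class,
    with ties broken toward the lowest cut.  A constant image has no
    threshold and raises ``ValueError``.
    """
    image = np.asarray(image)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise ValueError("no threshold exists: image is constant")
    counts, edges = np.histogram(image.ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(np.float64)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=-np.inf)
    # cuts inside a run of empty bins give the same partition; keep only
    # the canonical cut right after a populated bin so the maximiser is
    # unique up to genuine ties (first maximum in scan order)
    var_between[counts[:-1] == 0] = -np.inf
    best = int(np.argmax(var_between))
    return float(centers[best])


def binarize_and_clean(image: np.ndarray, threshold: float,
                       polarity: str = "dark",
                       closing_radius: int = 3) -> np.ndarray:
    """Binary foreground mask: threshold, close, clear border, fill holes.

    ``polarity="dark"`` treats pixels at or below the threshold as
    foreground (phase-contrast cell bodies are dark); ``"bright"`` inverts.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    image = np.asarray(image)
    fg = image <= threshold if polarity == "dark" else image > threshold
    if closing_radius > 0:
        fg = _closing(fg, disk(closing_radius))
    fg = clear_border(fg)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        warnings.warn("empty foreground after cleaning", stacklevel=2)
    return fg


def split_touching(mask: np.ndarray, smoothing_sigma: float = 4.0,
                   min_peak_distance: int = 10) -> RegionLabelMap:
    """Split touching cells by marker-seeded watershed.

    Markers are local maxima of the Gaussian-smoothed Euclidean distance
    transform (one marker per plateau, first pixel in scan order); the
    watershed floods the negated smoothed EDT inside the mask with
    8-connectivity.  A component with a single peak passes through unsplit.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return RegionLabelMap.from_labels(np.zeros(mask.shape, np.int32))
    edt = ndi.distance_transform_edt(mask)
    sm = ndi.gaussian_filter(edt, smoothing_sigma) if smoothing_sigma > 0 else edt
    size = 2 * min_peak_distance + 1
    is_peak = (sm == ndi.maximum_filter(sm, size=size)) & mask
    # one marker per plateau: first pixel of each connected peak component
    plateau_labels, n_plateaus = ndi.label(is_peak,
                                           ndi.generate_binary_structure(2, 2))
    markers = np.zeros(mask.shape, np.int32)
    if n_plateaus:
        first = ndi.minimum_position(
            np.arange(mask.size).reshape(mask.shape), plateau_labels,
            index=range(1, n_plateaus + 1))
        for k, pos in enumerate(first, start=1):
            markers[tuple(pos)] = k
    # every mask component must own at least one marker (its global max is
    # a local max unless shadowed by a neighbour; re-seed such components)
    comp, ncomp = ndi.label(mask, ndi.generate_binary_structure(2, 2))
    seeded = set(np.unique(comp[markers > 0]))
    next_id = n_plateaus + 1
    for c in range(1, ncomp + 1):
        if c not in seeded:
            pos = ndi.maximum_position(sm, comp, index=c)
            markers[tuple(pos)] = next_id
            next_id += 1
    labels = watershed(-sm, markers=markers, mask=mask, connectivity=2)
    return RegionLabelMap.from_labels(labels)


def filter_by_area(regions: RegionLabelMap, min_px: int = MIN_AREA_PX,
                   max_px: int = MAX_AREA_PX) -> RegionLabelMap:
    """Keep regions with ``min_px < area < max_px`` (both bounds exclusive)
    and relabel survivors consecutively in increasing original-label order."""
    table = regions.table
    keep = table[(table.area_px > min_px) & (table.area_px < max_px)]
    mapping = np.zeros(int(regions.labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(keep.label.to_numpy(), start=1):
        mapping[old] = new
    return RegionLabelMap.from_labels(mapping[regions.labels])


def segment_field(image: np.ndarray, polarity: str = "dark",
                  closing_radius: int = 3, smoothing_sigma: float = 4.0,
                  min_peak_distance: int = 10, min_px: int = MIN_AREA_PX,
                  max_px: int = MAX_AREA_PX) -> RegionLabelMap:
    """Full segmentation chain on one 2D segmentation-channel plane."""
    thr = otsu_threshold(image)
    mask = binarize_and_clean(image, thr, polarity=polarity,
                              closing_radius=closing_radius)
    regions = split_touching(mask, smoothing_sigma=smoothing_sigma,
                             min_peak_distance=min_peak_distance)
    return filter_by_area(regions, min_px=min_px, max_px=max_px)


def pixels_to_um2(area_px: float, nm_per_pixel: float = NM_PER_PIXEL) -> float:
    """Convert a pixel count to square microns at the given pixel pitch.

    Ordered so the default pitch stays exact in binary floating point
    (162.5^2 = 26406.25): 2000 px -> 52.8125, 8000 px -> 211.25.
    """
    return area_px * nm_per_pixel * nm_per_pixel / 1e6


def match_regions(reference: np.ndarray, predicted: np.ndarray) -> pd.DataFrame:
    """Best-IoU match of each reference label to a predicted label.

    Returns a frame (ref_label, pred_label, iou); ``pred_label`` is 0 with
    iou 0 when a reference region overlaps no predicted region.
    """
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    ref_ids = np.unique(reference)
    ref_ids = ref_ids[ref_ids > 0]
    ref_areas = np.bincount(reference.ravel())
    pred_areas = np.bincount(predicted.ravel())
    both = (reference > 0) & (predicted > 0)
    pairs, counts = np.unique(
        np.stack([reference[both], predicted[both]]), axis=1, return_counts=True)
    best: dict[int, tuple[int, float]] = {}
    for (r, p), inter in zip(pairs.T, counts):
        union = ref_areas[r] + pred_areas[p] - inter
        iou = inter / union
        if iou > best.get(int(r), (0, 0.0))[1]:
            best[int(r)] = (int(p), float(iou))
    rows = [(int(r), *best.get(int(r), (0, 0.0))) for r in ref_ids]
    return pd.DataFrame(rows, columns=["ref_label", "pred_label", "iou"])
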