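"""Segmentation strategies: watershed cells from a nuclear stain,
overlapping lattice bins, and per-read spot environments; plus QC filtering.

All three strategies produce a :class:`~spotmap.core.SegmentedMap` so the
downstream normalization / clustering / typing code is agnostic to how the
units were defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import NuclearImage, SegmentedMap, SpotTable

__all__ = [
    "BinSpec",
    "segment_dapi",
    "assign_spots",
    "overlapping_bins",
    "spot_environment_bins",
    "qc_filter",
]


@dataclass
class BinSpec:
    """Regular lattice of bins: square of half-width ``radius`` (pixels)
    centered every ``spacing`` pixels.  Bins overlap when
    spacing < 2 * radius; ``circular=True`` switches to discs."""

    radius: float
    spacing: float
    circular: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.spacing <= 0:
            raise ValueError("radius and spacing must be > 0")


def segment_dapi(
    image: NuclearImage,
    *,
    tophat_radius: int = 15,
    intensity_threshold: float | None = None,
    expansion_distance: float = 10.0,
    min_area: int = 30,
    peak_min_distance: int = 7,
) -> np.ndarray:
    """Watershed cell segmentation of a nuclear-stain image.

    Pipeline: white top-hat (disk structuring element of ``tophat_radius``)
    to flatten the background, global intensity threshold (Otsu when not
    given), hole filling and removal of specks below ``min_area`` px², a
    distance-transform watershed to split touching nuclei, and finally a
    bounded nearest-nucleus expansion of every nucleus outward by
    ``expansion_distance`` pixels.  Pixels beyond the expansion stay 0 —
    space between cells is deliberately unassigned and reads landing there
    are not attributed to any cell.

    Returns an integer label mask (0 = background, 1..M = cells).
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.morphology import disk, remove_small_objects, white_tophat
    from skimage.segmentation import expand_labels, watershed

    img = np.asarray(image.pixels, float)
    if img.max() > 0 and (img == img.max()).mean() > 0.05:
        warnings.warn("image looks saturated; consider rescaling exposure")
    flat = white_tophat(img, footprint=disk(tophat_radius))
    if intensity_threshold is None:
        intensity_threshold = float(threshold_otsu(flat))
    mask = flat > intensity_threshold
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        raise ValueError(
            "nothing above the intensity threshold "
            f"({intensity_threshold:.3g}); lower it or check the image"
        )
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=peak_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros_like(dist, dtype=np.int32)
    markers[tuple(peaks.T)] = 1
    markers, _ = ndi.label(markers)
    nuclei = watershed(-dist, markers, mask=mask)
    return expand_labels(nuclei, distance=expansion_distance)


def assign_spots(spots: SpotTable, mask: np.ndarray) -> tuple[SegmentedMap, dict]:
    """Assign each read to the cell label at its pixel.

    Pixel lookup floors the continuous coordinates (image convention).
    Reads on background (label 0) are tallied but discarded; reads outside
    the image extent are dropped and counted.  Returns the cell × gene map
    (one row per mask label, including read-free cells) plus a report with
    assigned / background / out-of-extent totals.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    col = np.floor(spots.x).astype(int)
    row = np.floor(spots.y).astype(int)
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    n_out = int((~inside).sum())
    labels = np.zeros(len(spots), dtype=np.int64)
    labels[inside] = mask[row[inside], col[inside]]
    assigned = inside & (labels > 0)
    n_bg = int((inside & (labels == 0)).sum())

    n_cells = int(mask.max())
    genes = spots.gene_panel()
    gcode = pd.Categorical(spots.genes.astype(str), categories=genes).codes
    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    np.add.at(counts, (labels[assigned] - 1, gcode[assigned]), 1)

    if n_cells:
        with np.errstate(invalid="ignore"):  # gap labels yield NaN centroids
            cy, cx = np.array(ndi.center_of_mass(
                np.ones_like(mask), mask, index=np.arange(1, n_cells + 1)
            )).T
    else:
        cy, cx = np.array([]), np.array([])
    seg = SegmentedMap(
        counts=pd.DataFrame(counts, index=np.arange(1, n_cells + 1), columns=genes),
        unit_kind="cell",
        centroids=np.column_stack([cx, cy]) if n_cells else np.empty((0, 2)),
        geometry={"mask_shape": mask.shape},
    )
    report = {
        "n_assigned": int(assigned.sum()),
        "n_background": n_bg,
        "n_out_of_extent": n_out,
        "read_labels": labels,
    }
    return seg, report


def overlapping_bins(spots: SpotTable, bins: BinSpec) -> SegmentedMap:
    """Count reads in regular (possibly overlapping) bins.

    Bin centers form a lattice starting at the data minimum with the given
    spacing; a read contributes to every bin whose square
    |x - cx| <= radius and |y - cy| <= radius contains it (disc membership
    with ``circular=True``).  Empty bins are dropped.
    """
    x, y = spots.x, spots.y
    r, s = float(bins.radius), float(bins.spacing)
    x0, y0 = x.min(), y.min()

    def n_centers(span: float) -> int:
        # enough lattice points that the last bin reaches past the data max
        return max(int(np.ceil((span - r) / s)) + 1, 1)

    nx = n_centers(x.max() - x0)
    ny = n_centers(y.max() - y0)

    genes = spots.gene_panel()
    gcode = pd.Categorical(spots.genes.astype(str), categories=genes).codes

    def index_range(v: np.ndarray, v0: float, n: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.ceil((v - r - v0) / s).astype(int)
        hi = np.floor((v + r - v0) / s).astype(int)
        # lo may exceed hi after clamping: the read then matches no bin
        return np.maximum(lo, 0), np.minimum(hi, n - 1)

    ix_lo, ix_hi = index_range(x, x0, nx)
    iy_lo, iy_hi = index_range(y, y0, ny)

    counts = np.zeros((nx * ny, len(genes)), dtype=np.int64)
    max_dx = int((ix_hi - ix_lo).max()) if len(x) else 0
    max_dy = int((iy_hi - iy_lo).max()) if len(y) else 0
    for dx in range(max_dx + 1):
        ix = ix_lo + dx
        ok_x = ix <= ix_hi
        for dy in range(max_dy + 1):
            iy = iy_lo + dy
            ok = ok_x & (iy <= iy_hi)
            if bins.circular:
                cx = x0 + ix * s
                cy = y0 + iy * s
                ok = ok & ((x - cx) ** 2 + (y - cy) ** 2 <= r * r)
            if not ok.any():
                continue
            bin_idx = iy[ok] * nx + ix[ok]
            np.add.at(counts, (bin_idx, gcode[ok]), 1)

    keep = counts.sum(1) > 0
    idx = np.flatnonzero(keep)
    cx = x0 + (idx % nx) * s
    cy = y0 + (idx // nx) * s
    return SegmentedMap(
        counts=pd.DataFrame(counts[keep], index=idx, columns=genes),
        unit_kind="bin",
        centroids=np.column_stack([cx, cy]),
        geometry={"radius": r, "spacing": s, "circular": bins.circular},
    )


def spot_environment_bins(spots: SpotTable, radius: float) -> SegmentedMap:
    """Gene composition of each read's neighborhood.

    One unit per read; its row counts all reads (the focal read included)
    within Euclidean distance <= radius of the focal position.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    from scipy.spatial import cKDTree

    xy = spots.xy
    genes = spots.gene_panel()
    gcode = pd.Categorical(spots.genes.astype(str), categories=genes).codes
    tree = cKDTree(xy)
    counts = np.zeros((len(xy), len(genes)), dtype=np.int64)
    for i, nbrs in enumerate(tree.query_ball_point(xy, r=radius)):
        counts[i] = np.bincount(gcode[nbrs], minlength=len(genes))
    return SegmentedMap(
        counts=pd.DataFrame(counts, index=np.arange(len(xy)), columns=genes),
        unit_kind="spot_env",
        centroids=xy.copy(),
        geometry={"radius": float(radius)},
    )


def qc_filter(
    seg: SegmentedMap,
    *,
    min_reads_per_unit: float = 0,
    max_reads_per_unit: float = np.inf,
    min_reads_per_gene: float = 0,
) -> tuple[SegmentedMap, dict]:
    """Drop units outside [min, max] total reads, then low-count genes.

    Idempotent for fixed thresholds.  Raises if nothing survives, with a
    summary of the count distribution to guide threshold choice.
    """
    counts = seg.counts
    row_tot = counts.sum(axis=1)
    keep_u = (row_tot >= min_reads_per_unit) & (row_tot <= max_reads_per_unit)
    trimmed = counts[keep_u]
    col_tot = trimmed.sum(axis=0)
    keep_g = col_tot >= min_reads_per_gene
    out = trimmed.loc[:, keep_g]
    if out.empty or out.shape[1] == 0:
        raise ValueError(
            "qc_filter removed everything; unit read totals were "
            f"min={row_tot.min()}, median={row_tot.median()}, max={row_tot.max()}"
        )
    report = {
        "n_units_dropped": int((~keep_u).sum()),
        "n_genes_dropped": int((~keep_g).sum()),
    }
    kept_idx = np.flatnonzero(keep_u.to_numpy())
    filtered = SegmentedMap(
        counts=out,
        unit_kind=seg.unit_kind,
        centroids=seg.centroids[kept_idx],
        geometry=dict(seg.geometry),
        sample=np.asarray(seg.sample)[kept_idx],
    )
    return filtered, report
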