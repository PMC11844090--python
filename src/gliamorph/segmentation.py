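"""Masks and per-cell territories from fluorescence channels.

The segmentation stage produces, per case:

1. a binary mask per microglial marker channel by **adaptive
   thresholding** (local mean in a square window plus an offset — the
   simplest operator that tracks uneven illumination);
2. a **master mask**, the pixelwise union of the marker masks (human:
   HLA-DR + CD68 + Iba1; mouse: Iba1 only), capturing all microglial
   signal;
3. a pTDP-43 mask by a global **threshold clip**;
4. a **domain label map**: a marker-controlled watershed on the negated
   distance-to-nearest-soma surface, partitioning the ROI into one
   territory per cell. Domains approximate a Voronoi tessellation of the
   soma regions; watershed lines (label 0) are excluded from every
   downstream measurement.

All masks are restricted to the region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


@dataclass
class ChannelImage:
    """One fluorescence channel: non-negative 2D intensities + pixel size."""

    pixels: np.ndarray
    channel_name: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("channel image must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("channel image contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class BinaryMask:
    pixels: np.ndarray
    source_channels: tuple[str, ...] = ()
    threshold_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DomainLabelMap:
    """Per-cell territories: 0 = background/watershed line, 1..n = domains."""

    labels: np.ndarray
    seed_ids: dict[int, int]  # domain label -> soma label

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-typed")

    @property
    def n_domains(self) -> int:
        return int(self.labels.max())


def adaptive_threshold(
    img: ChannelImage,
    window_um: float,
    offset: float,
    roi: np.ndarray | None = None,
    min_object_area_um2: float = 5.0,
) -> BinaryMask:
    """Local-mean adaptive threshold.

    A pixel is foreground iff its intensity exceeds the mean over the
    square window of side ``2*window+1`` centred on it (borders by
    reflection) plus ``offset``. Components smaller than
    ``min_object_area_um2`` are removed as specks.
    """
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    half = int(round(window_um / img.pixel_size_um))
    side = 2 * half + 1
    if side > min(img.pixels.shape):
        raise ValueError("adaptive-threshold window larger than the image")
    local_mean = ndi.uniform_filter(img.pixels, size=side, mode="reflect")
    fg = img.pixels > local_mean + offset
    if roi is not None:
        fg &= np.asarray(roi, dtype=bool)
    if min_object_area_um2 > 0:
        min_px = int(round(min_object_area_um2 / img.pixel_size_um**2))
        if min_px > 1:
            lab, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
            counts = np.bincount(lab.ravel())
            keep = counts >= min_px
            keep[0] = False
            fg = keep[lab]
    return BinaryMask(
        fg, (img.channel_name,),
        {"method": "adaptive_mean", "window_um": window_um, "offset": offset,
         "min_object_area_um2": min_object_area_um2},
    )


def clip_threshold(
    img: ChannelImage, min_value: float, roi: np.ndarray | None = None
) -> BinaryMask:
    """Global clip threshold: foreground = intensity >= ``min_value``."""
    if min_value < 0:
        raise ValueError("min_value must be >= 0")
    fg = img.pixels >= min_value
    if roi is not None:
        fg &= np.asarray(roi, dtype=bool)
    return BinaryMask(fg, (img.channel_name,),
                      {"method": "clip", "min_value": min_value})


def build_master_mask(masks: list[BinaryMask]) -> BinaryMask:
    """Pixelwise union of marker masks; records contributing channels."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].pixels.shape
    for m in masks[1:]:
        if m.pixels.shape != shape:
            raise ValueError("mask shapes differ")
    union = np.zeros(shape, dtype=bool)
    channels: list[str] = []
    for m in masks:
        union |= m.pixels
        channels.extend(m.source_channels)
    return BinaryMask(union, tuple(channels), {"method": "union"})


def partition_domains(
    cell_body_labels: np.ndarray,
    roi: np.ndarray,
) -> DomainLabelMap:
    """Watershed partition of the ROI into one territory per soma.

    The topographic surface is the negated Euclidean distance to the
    nearest soma pixel; flooding from the soma markers then carves the
    ROI into catchment basins separated by one-pixel watershed lines
    (label 0). With well-separated somata this coincides with a
    nearest-soma (Voronoi-like) assignment.
    """
    from skimage.segmentation import watershed

    roi = np.asarray(roi, dtype=bool)
    labels = np.asarray(cell_body_labels)
    seeds = labels.copy()
    seeds[~roi] = 0
    if seeds.max() == 0:
        import warnings

        warnings.warn("no cell bodies inside the ROI; empty domain map")
        return DomainLabelMap(np.zeros_like(labels, dtype=np.int32), {})
    dist = ndi.distance_transform_edt(seeds == 0)
    ws = watershed(dist, markers=seeds, mask=roi, watershed_line=True)
    seed_ids = {int(v): int(v) for v in np.unique(seeds) if v != 0}
    return DomainLabelMap(ws.astype(np.int32), seed_ids)


def nearest_seed_labels(cell_body_labels: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Exact nearest-soma assignment of every ROI pixel (oracle for the
    watershed partition): each pixel takes the label of the nearest soma
    pixel by Euclidean distance."""
    roi = np.asarray(roi, dtype=bool)
    labels = np.asarray(cell_body_labels)
    _, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    out = labels[ir, ic].astype(np.int32)
    out[~roi] = 0
    return out


def roi_from_polygon_csv(path, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon-vertex CSV into a boolean ROI mask.

    The CSV has columns ``x,y`` (0-based pixel coordinates, origin
    top-left, x = column). Vertices are taken in row order; the polygon
    is closed automatically.
    """
    import pandas as pd
    from skimage.draw import polygon

    verts = pd.read_csv(path)
    if not {"x", "y"} <= set(verts.columns):
        raise ValueError("polygon CSV needs 'x' and 'y' columns")
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    rr, cc = polygon(verts["y"].to_numpy(float), verts["x"].to_numpy(float),
                     shape=shape)
    roi = np.zeros(shape, dtype=bool)
    roi[rr, cc] = True
    if not roi.any():
        raise ValueError("polygon rasterizes to an empty ROI")
    return roi


def flag_border_cells(cell_body_labels: np.ndarray, roi: np.ndarray) -> set[int]:
    """Labels of somata touching the ROI border (excluded from single-cell
    statistics)."""
    roi = np.asarray(roi, dtype=bool)
    interior = ndi.binary_erosion(roi, structure=np.ones((3, 3), dtype=bool))
    border_band = roi & ~interior
    labels = np.asarray(cell_body_labels)
    touching = np.unique(labels[border_band | ~roi])
    return {int(v) for v in touching if v != 0}
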