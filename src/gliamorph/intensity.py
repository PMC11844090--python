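"""Tissue-wide and per-cell marker intensity quantification.

Intensities are raw camera units: no background subtraction or inter-case
normalisation is applied (background handling lives in mask
construction). Tissue-wide expression of a marker is its integrated
intensity over the master mask divided by the ROI area; single-cell
expression is the mean intensity over (cell domain ∩ master mask).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import BinaryMask, ChannelImage, DomainLabelMap


def integrated_intensity(
    img: ChannelImage, mask: BinaryMask, roi: np.ndarray
) -> float:
    """Integrated intensity over mask ∩ ROI, normalised to ROI area.

    The pixel sum is weighted by the pixel area, so a uniform intensity c
    over a mask of area A inside a ROI of area R yields c*A/R (intensity
    units). Linear in the image and additive over disjoint masks at fixed
    ROI; independent of the pixel grid for a fixed physical field.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if mask.pixels.shape != img.pixels.shape or roi.shape != img.pixels.shape:
        raise ValueError("image, mask and ROI shapes differ")
    m = mask.pixels & roi
    total_um2 = float(img.pixels[m].sum()) * img.pixel_size_um**2
    roi_area_um2 = float(roi.sum()) * img.pixel_size_um**2
    return total_um2 / roi_area_um2


def per_cell_mean_intensity(
    img: ChannelImage,
    domains: DomainLabelMap,
    master: BinaryMask,
) -> pd.Series:
    """Mean intensity of ``img`` over (domain ∩ master mask) per cell.

    Cells whose domain contains no master-mask pixel are dropped (they
    have no measurable microglial signal). The result is indexed by
    domain label and invariant to label ordering.
    """
    labels = domains.labels
    measure = master.pixels & (labels > 0)
    present = np.unique(labels[measure])
    present = present[present > 0]
    if present.size == 0:
        return pd.Series(dtype=float, name=img.channel_name)
    means = ndi.mean(img.pixels, labels=np.where(measure, labels, 0),
                     index=present)
    return pd.Series(means, index=pd.Index(present, name="cell_label"),
                     name=img.channel_name)
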