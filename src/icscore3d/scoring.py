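"""Per-layer immune-cell (IC) scoring.

Combines the tumor-cell and immune-cell masks of one z-layer into the merged
tumor-area mask and the intratumoral immune mask, then computes the SP142-style
IC score: the percentage of tumor area covered by marker-positive
tumor-infiltrating immune cells, with the three clinical categories
(negative / borderline / positive) split at 0% and 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

CATEGORIES = ("negative", "borderline", "positive")

#: rank of each category on the clinical scale; used for ordering comparisons
CATEGORY_ORDER = {"negative": 0, "borderline": 1, "positive": 2}


def categorize(ic_score_pct: float) -> str:
    """Map an IC score (percent) to its clinical category.

    ``>= 1`` percent is positive (closed lower bound), strictly between 0 and 1
    is borderline, exactly 0 is negative.
    """
    score = float(ic_score_pct)
    if not np.isfinite(score) or score < 0 or score > 100:
        raise ValueError(f"IC score must be in [0, 100], got {ic_score_pct!r}")
    if score >= 1.0:
        return "positive"
    if score > 0.0:
        return "borderline"
    return "negative"


def _check_congruent(*masks: np.ndarray) -> None:
    shapes = {m.shape for m in masks if m is not None}
    if len(shapes) > 1:
        raise ValueError(f"masks are not congruent: shapes {sorted(shapes)}")


def merge_tumor_area(
    tumor_cell_mask: np.ndarray,
    closing_radius_px: int = 20,
    min_hole_px: int = 5000,
) -> np.ndarray:
    """Consolidate a tumor-cell mask into the merged tumor-area mask.

    Morphological closing with a disk of ``closing_radius_px`` bridges the
    intratumoral stroma between adjacent tumor cells, then enclosed holes of at
    most ``min_hole_px`` pixels are filled.  The result is a superset of the
    input and the operation is idempotent on already-merged masks.
    """
    if closing_radius_px < 0:
        raise ValueError("closing_radius_px must be >= 0")
    mask = np.asarray(tumor_cell_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2D layer mask")
    closed = binary_close(mask, closing_radius_px)
    closed |= mask
    return fill_small_holes(closed, min_hole_px)


def binary_close(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological closing with a disk, padded so nothing leaks across the
    image border (dilation followed by erosion, scipy backend)."""
    if radius_px <= 0:
        return np.asarray(mask, dtype=bool).copy()
    foot = disk(radius_px)
    pad = radius_px + 1
    padded = np.pad(np.asarray(mask, dtype=bool), pad, mode="constant")
    closed = ndi.binary_erosion(
        ndi.binary_dilation(padded, structure=foot), structure=foot
    )
    return closed[pad:-pad, pad:-pad]


def fill_small_holes(mask: np.ndarray, max_hole_px: int) -> np.ndarray:
    """Fill background components fully enclosed by ``mask`` up to a size cap."""
    if max_hole_px <= 0:
        return mask.copy()
    labels, n = ndi.label(~mask)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & ~mask])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = sizes[1:] <= max_hole_px
    fill[touching] = False
    out = mask.copy()
    out[fill[labels]] = True
    return out


def split_immune(
    immune_mask: np.ndarray, tumor_area_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partition immune pixels into intratumoral and peritumoral masks.

    Returns ``(immune_in_tumor, immune_peritumoral)``: the exact intersection
    with, and difference from, the merged tumor-area mask.
    """
    immune = np.asarray(immune_mask, dtype=bool)
    tumor = np.asarray(tumor_area_mask, dtype=bool)
    if immune.shape != tumor.shape:
        raise ValueError(
            f"shape mismatch: immune {immune.shape} vs tumor area {tumor.shape}"
        )
    return immune & tumor, immune & ~tumor


def pdl1_positive_ic(
    marker_channel: np.ndarray,
    immune_in_tumor_mask: np.ndarray,
    intensity_threshold: Optional[float] = None,
    cell_level: bool = False,
) -> np.ndarray:
    """Marker-positive intratumoral immune mask.

    Pixels of ``immune_in_tumor_mask`` whose marker intensity is at or above
    the threshold.  When ``intensity_threshold`` is None the cut is derived by
    Otsu's method on the marker histogram restricted to the immune mask.  With
    ``cell_level=True`` positivity is propagated to whole connected immune
    components (a cell is scored positive or negative as a unit, mirroring
    binary positivity independent of staining intensity).
    """
    marker = np.asarray(marker_channel, dtype=np.float64)
    mask = np.asarray(immune_in_tumor_mask, dtype=bool)
    if marker.shape != mask.shape:
        raise ValueError("marker channel not congruent with immune mask")
    if not mask.any():
        return np.zeros_like(mask)
    if intensity_threshold is None:
        values = marker[mask]
        # Otsu always splits, even a pure-noise histogram; clamp the cut to a
        # robust noise floor estimated from the background outside the immune
        # mask (median + 12 * upper half-spread) so a marker-free layer yields
        # no positives.  Quantiles are insensitive to the sparse true signal
        # that may leak into the background.
        background = marker[~mask]
        floor = 0.0
        if background.size:
            med = float(np.median(background))
            floor = med + 12.0 * (float(np.quantile(background, 0.75)) - med)
        if np.allclose(values, values.flat[0]):
            bright = float(values.flat[0]) > max(floor, 0.0)
            return mask.copy() if bright else np.zeros_like(mask)
        intensity_threshold = max(float(threshold_otsu(values)), floor)
    if not np.isfinite(intensity_threshold):
        raise ValueError("intensity threshold must be finite")
    positive = mask & (marker >= intensity_threshold)
    if cell_level and positive.any():
        labels, _ = ndi.label(mask)
        pos_ids = np.unique(labels[positive])
        pos_ids = pos_ids[pos_ids > 0]
        positive = np.isin(labels, pos_ids)
    return positive


@dataclass
class LayerMasks:
    """Working masks of one analyzed z-layer."""

    z_index: int
    tumor_cell_mask: np.ndarray
    tumor_area_mask: np.ndarray
    immune_mask: np.ndarray
    immune_in_tumor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    immune_peritumoral_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    pdl1_pos_ic_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tumor_cell_mask = np.asarray(self.tumor_cell_mask, dtype=bool)
        self.tumor_area_mask = np.asarray(self.tumor_area_mask, dtype=bool)
        self.immune_mask = np.asarray(self.immune_mask, dtype=bool)
        _check_congruent(self.tumor_cell_mask, self.tumor_area_mask, self.immune_mask)
        if self.immune_in_tumor_mask is None or self.immune_peritumoral_mask is None:
            self.immune_in_tumor_mask, self.immune_peritumoral_mask = split_immune(
                self.immune_mask, self.tumor_area_mask
            )
        if self.pdl1_pos_ic_mask is None:
            self.pdl1_pos_ic_mask = np.zeros_like(self.immune_mask)
        self.pdl1_pos_ic_mask = np.asarray(self.pdl1_pos_ic_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if (self.tumor_cell_mask & ~self.tumor_area_mask).any():
            raise ValueError("tumor_cell_mask must be a subset of tumor_area_mask")
        if (self.pdl1_pos_ic_mask & ~self.immune_in_tumor_mask).any():
            raise ValueError("pdl1_pos_ic_mask must lie within immune_in_tumor_mask")


@dataclass(frozen=True)
class LayerScore:
    """Areas and IC score of one layer.

    ``ic_score_pct`` and ``category`` are None for layers without tumor area
    (the score is undefined at a zero denominator, not zero).
    """

    z_index: int
    depth_um: float
    tumor_area_px: int
    immune_area_px: int
    pdl1_ic_area_px: int
    ic_score_pct: Optional[float]
    category: Optional[str]

    @property
    def no_tumor(self) -> bool:
        return self.ic_score_pct is None


def layer_ic_score(
    layer_masks: LayerMasks,
    z_spacing_um: float,
    dcis_mask: Optional[np.ndarray] = None,
    exclude_dcis: bool = False,
) -> LayerScore:
    """Compute the IC score of one layer from its masks.

    ``ic_score_pct = 100 * A(marker-positive intratumoral IC) / A(tumor area)``.
    With ``exclude_dcis`` set (and a DCIS mask given), in-situ pixels are
    removed from both the denominator and the numerator-eligible region, so the
    score refers to the invasive component only.
    """
    masks = layer_masks
    tumor_area = masks.tumor_area_mask
    immune_in = masks.immune_in_tumor_mask
    pdl1 = masks.pdl1_pos_ic_mask
    if exclude_dcis and dcis_mask is not None:
        dcis = np.asarray(dcis_mask, dtype=bool)
        _check_congruent(tumor_area, dcis)
        tumor_area = tumor_area & ~dcis
        immune_in = immune_in & ~dcis
        pdl1 = pdl1 & ~dcis
    a_tumor = int(np.count_nonzero(tumor_area))
    a_immune = int(np.count_nonzero(immune_in))
    a_pdl1 = int(np.count_nonzero(pdl1))
    depth = masks.z_index * float(z_spacing_um)
    if a_tumor == 0:
        return LayerScore(masks.z_index, depth, 0, a_immune, a_pdl1, None, None)
    score = 100.0 * a_pdl1 / a_tumor
    return LayerScore(
        z_index=masks.z_index,
        depth_um=depth,
        tumor_area_px=a_tumor,
        immune_area_px=a_immune,
        pdl1_ic_area_px=a_pdl1,
        ic_score_pct=score,
        category=categorize(score),
    )
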