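"""Synthetic 3-channel z-stack generator with exact ground truth.

Emulates cleared-tissue fluorescence stacks of breast-tumor tissue: tumor
nests of large, clustered, elliptical nuclei; small round immune cells inside
and around the nests; membrane rings; and a membrane-localized marker signal
on a designed per-layer fraction of the intratumoral immune cells.  Every
stack comes with congruent ground-truth masks and exact per-layer area
bookkeeping, so downstream stages can be tested without any external data.

All randomness flows from a single integer seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk as disk_footprint

from .scoring import categorize
from .stack_io import ChannelStack

Profile = Union[float, int, Sequence[float]]

# Intensity design: tumor and immune nuclei occupy disjoint ranges so that the
# two classes are separable by brightness and size alone, as the real models
# separate them from the two counterstain channels.
TUMOR_NUCLEUS_INTENSITY = (90.0, 130.0)
IMMUNE_NUCLEUS_INTENSITY = (170.0, 210.0)
TUMOR_MEMBRANE_INTENSITY = 45.0
IMMUNE_MEMBRANE_INTENSITY = 120.0
DCIS_RING_INTENSITY = 220.0
MARKER_RING_INTENSITY = (160.0, 200.0)


@dataclass
class PhantomParams:
    """Design parameters of one synthetic case."""

    image_shape: tuple[int, int, int] = (16, 256, 256)
    z_spacing_um: float = 1.4
    pixel_size_um: float = 0.621
    tumor_nest_count: int = 3
    tumor_nest_radius_px: int = 40
    nest_radius_jitter: float = 0.1
    tumor_nucleus_radius_px: tuple[int, int] = (8, 12)
    immune_radius_px: tuple[int, int] = (3, 5)
    immune_density_profile: Profile = 90
    immune_in_tumor_frac: float = 0.5
    pdl1_fraction_profile: Profile = 0.0
    dcis_count: int = 0
    dcis_radius_px: int = 40
    noise_sigma: float = 2.0
    intensity_decay_per_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_z = self.image_shape[0]
        if any(s <= 0 for s in self.image_shape):
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if self.z_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_spacing_um and pixel_size_um must be positive")
        self.immune_density_profile = _expand_profile(
            self.immune_density_profile, n_z, "immune_density_profile"
        )
        self.pdl1_fraction_profile = _expand_profile(
            self.pdl1_fraction_profile, n_z, "pdl1_fraction_profile"
        )
        if np.any(self.pdl1_fraction_profile < 0) or np.any(
            self.pdl1_fraction_profile > 1
        ):
            raise ValueError("pdl1_fraction_profile entries must be in [0, 1]")
        if np.any(self.immune_density_profile < 0):
            raise ValueError("immune densities must be non-negative")


def _expand_profile(profile: Profile, n_z: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(profile, dtype=float))
    if arr.size == 1:
        arr = np.full(n_z, float(arr[0]))
    if arr.shape != (n_z,):
        raise ValueError(f"{name} must broadcast to length n_z={n_z}, got {arr.shape}")
    return arr


def gradient_profile(start_fraction: float, end_fraction: float, n_z: int) -> np.ndarray:
    """Monotone linear depth gradient of designed marker-positive fractions."""
    for frac in (start_fraction, end_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fractions must be in [0, 1], got {frac}")
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    if n_z == 1:
        return np.asarray([start_fraction], dtype=float)
    return np.linspace(start_fraction, end_fraction, n_z)


@dataclass
class GroundTruth:
    """Per-voxel label stacks and exact per-layer bookkeeping.

    ``per_layer_truth`` holds, for each z, the voxel counts of the tumor
    region, the intratumoral immune cells and the marker-positive intratumoral
    immune cells, plus the implied true IC score in percent.
    """

    tumor_mask: np.ndarray
    immune_mask: np.ndarray
    pdl1_pos_mask: np.ndarray
    dcis_mask: np.ndarray
    per_layer_truth: pd.DataFrame

    def validate(self) -> None:
        if (self.pdl1_pos_mask & ~self.immune_mask).any():
            raise ValueError("pdl1_pos_mask must be a subset of immune_mask")
        if (self.dcis_mask & self.immune_mask).any():
            raise ValueError("dcis_mask and immune_mask must be disjoint")


def per_layer_truth_from_masks(
    tumor_mask: np.ndarray, immune_mask: np.ndarray, pdl1_pos_mask: np.ndarray
) -> pd.DataFrame:
    """Exact per-layer areas and scores by voxel counting of the masks."""
    rows = []
    for z in range(tumor_mask.shape[0]):
        a_tumor = int(np.count_nonzero(tumor_mask[z]))
        a_immune = int(np.count_nonzero(immune_mask[z] & tumor_mask[z]))
        a_pdl1 = int(np.count_nonzero(pdl1_pos_mask[z] & tumor_mask[z]))
        score = 100.0 * a_pdl1 / a_tumor if a_tumor > 0 else np.nan
        rows.append(
            {
                "z_index": z,
                "tumor_area_px": a_tumor,
                "immune_in_tumor_px": a_immune,
                "pdl1_ic_area_px": a_pdl1,
                "ic_score_pct": score,
            }
        )
    return pd.DataFrame(rows)


def render_reference_2d(truth: GroundTruth) -> tuple[float, str]:
    """Simulated 2D reference: true score and category of the most superficial
    layer (z = 0), standing in for the adjacent bright-field section."""
    if len(truth.per_layer_truth) == 0:
        raise ValueError("empty ground truth")
    score = float(truth.per_layer_truth.iloc[0]["ic_score_pct"])
    if np.isnan(score):
        raise ValueError("layer 0 has no tumor area; 2D reference undefined")
    return score, categorize(score)


def _place_discs(
    rng: np.random.Generator,
    count: int,
    radius: float,
    jitter: float,
    shape: tuple[int, int],
    existing: list[tuple[float, float, float]],
    gap: float,
    max_tries: int = 400,
) -> list[tuple[float, float, float]]:
    """Place ``count`` non-overlapping discs (min boundary gap) inside bounds."""
    h, w = shape
    for _ in range(60):  # restart the whole configuration on a dead end
        placed: list[tuple[float, float, float]] = []
        for _ in range(count):
            for _ in range(max_tries):
                r = radius * rng.uniform(1.0 - jitter, 1.0 + jitter)
                margin = r + 3
                if margin >= h - margin or margin >= w - margin:
                    break
                cy = float(round(rng.uniform(margin, h - margin)))
                cx = float(round(rng.uniform(margin, w - margin)))
                if all(
                    np.hypot(cy - oy, cx - ox) >= r + orr + gap
                    for oy, ox, orr in existing + placed
                ):
                    placed.append((cy, cx, r))
                    break
        if len(placed) == count:
            return placed
    raise RuntimeError(
        f"could not place {count} discs of radius ~{radius} with gap {gap} "
        f"in a {h}x{w} image; reduce count/radius"
    )


def _paint_discs(mask: np.ndarray, discs: list[tuple[float, float, float]]) -> None:
    for cy, cx, r in discs:
        rr, cc = draw_disk((cy, cx), r, shape=mask.shape)
        mask[rr, cc] = True


class _ImmunePlacer:
    """Samples non-overlapping immune-cell positions, either fully inside the
    invasive tumor region or fully outside the whole tumor region."""

    def __init__(
        self,
        idc_region: np.ndarray,
        tumor_region: np.ndarray,
        radii: tuple[int, int],
    ) -> None:
        self.radii = list(range(radii[0], radii[1] + 1))
        self.inside_ok = {}
        self.outside_ok = {}
        background = ~tumor_region
        background[: radii[1] + 1, :] = False
        background[-radii[1] - 1 :, :] = False
        background[:, : radii[1] + 1] = False
        background[:, -radii[1] - 1 :] = False
        for r in self.radii:
            foot = disk_footprint(r)
            self.inside_ok[r] = ndi.binary_erosion(idc_region, structure=foot)
            self.outside_ok[r] = ndi.binary_erosion(background, structure=foot)

    def sample(
        self,
        rng: np.random.Generator,
        n: int,
        inside: bool,
        taken: list[tuple[int, int, int]],
        max_tries: int = 200,
    ) -> list[tuple[int, int, int]]:
        """Return up to n (cy, cx, r) triples; fewer if space runs out."""
        pool = self.inside_ok if inside else self.outside_ok
        cells: list[tuple[int, int, int]] = []
        coords = {r: np.argwhere(pool[r]) for r in self.radii}
        for _ in range(n):
            placed = False
            for _ in range(max_tries):
                r = int(rng.choice(self.radii))
                options = coords[r]
                if len(options) == 0:
                    continue
                cy, cx = options[rng.integers(len(options))]
                if all(
                    np.hypot(float(cy - oy), float(cx - ox)) >= r + orr + 2
                    for oy, ox, orr in taken + cells
                ):
                    cells.append((int(cy), int(cx), r))
                    placed = True
                    break
            if not placed:
                break
        return cells


def _greedy_marker_selection(
    cells: list[dict], target_area: float, rng: np.random.Generator
) -> list[dict]:
    """Pick whole cells whose cumulative area best approaches the target."""
    order = rng.permutation(len(cells))
    chosen: list[dict] = []
    cum = 0.0
    for i in order:
        area = cells[i]["area"]
        if abs(cum + area - target_area) <= abs(cum - target_area):
            chosen.append(cells[i])
            cum += area
    return chosen


def generate_case(params: PhantomParams) -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic case: a 3-channel stack plus exact ground truth.

    Deterministic for a fixed seed.  The realized per-layer true IC score
    approximates ``pdl1_fraction_profile * 100`` up to whole-cell
    discretization (cells are marked positive as units).
    """
    n_z, h, w = params.image_shape
    rng = np.random.default_rng(params.seed)

    # --- static geometry: tumor nests and optional duct-like (DCIS) regions
    nests = _place_discs(
        rng,
        params.tumor_nest_count,
        params.tumor_nest_radius_px,
        params.nest_radius_jitter,
        (h, w),
        existing=[],
        gap=44,
    )
    dcis_discs = _place_discs(
        rng,
        params.dcis_count,
        params.dcis_radius_px,
        params.nest_radius_jitter,
        (h, w),
        existing=nests,
        gap=44,
    )
    idc_region = np.zeros((h, w), dtype=bool)
    _paint_discs(idc_region, nests)
    dcis_region = np.zeros((h, w), dtype=bool)
    _paint_discs(dcis_region, dcis_discs)
    tumor_region = idc_region | dcis_region

    placer = _ImmunePlacer(idc_region, tumor_region, params.immune_radius_px)

    voxels = np.zeros((n_z, h, w, 3), dtype=np.float32)
    immune_stack = np.zeros((n_z, h, w), dtype=bool)
    pdl1_stack = np.zeros((n_z, h, w), dtype=bool)

    mean_cell_area = np.pi * np.mean(params.immune_radius_px) ** 2
    idc_area = int(np.count_nonzero(idc_region))
    tumor_area = int(np.count_nonzero(tumor_region))

    for z in range(n_z):
        nuclei = np.zeros((h, w), dtype=np.float32)
        membrane = np.zeros((h, w), dtype=np.float32)
        marker = np.zeros((h, w), dtype=np.float32)

        _render_tumor_nuclei(rng, nuclei, membrane, nests + dcis_discs, params)
        for cy, cx, r in dcis_discs:  # unbroken bright boundary ring
            ring = _annulus((cy, cx), r, 3.0, (h, w))
            membrane[ring] = np.maximum(membrane[ring], DCIS_RING_INTENSITY)

        # --- immune cells: enough inside the invasive region to realize the
        # designed marker-positive fraction, the rest in peritumoral stroma
        n_total = int(round(params.immune_density_profile[z]))
        target_area = params.pdl1_fraction_profile[z] * tumor_area
        n_needed = int(np.ceil(target_area / (0.8 * mean_cell_area))) + 2
        n_in = min(
            max(int(round(n_total * params.immune_in_tumor_frac)), n_needed),
            max(int(0.5 * idc_area / mean_cell_area), n_needed),
        )
        n_out = max(n_total - n_in, 0)
        taken: list[tuple[int, int, int]] = []
        inside_cells = placer.sample(rng, n_in, inside=True, taken=taken)
        taken.extend(inside_cells)
        outside_cells = placer.sample(rng, n_out, inside=False, taken=taken)

        cells = []
        for (cy, cx, r), is_inside in [(c, True) for c in inside_cells] + [
            (c, False) for c in outside_cells
        ]:
            rr, cc = draw_disk((cy, cx), r, shape=(h, w))
            cells.append(
                {"center": (cy, cx), "r": r, "rr": rr, "cc": cc,
                 "area": len(rr), "inside": is_inside}
            )
            immune_stack[z, rr, cc] = True
            nuclei[rr, cc] = np.maximum(
                nuclei[rr, cc], rng.uniform(*IMMUNE_NUCLEUS_INTENSITY)
            )
            ring = _annulus((cy, cx), r, 1.5, (h, w))
            membrane[ring] = np.maximum(membrane[ring], IMMUNE_MEMBRANE_INTENSITY)

        positives = _greedy_marker_selection(
            [c for c in cells if c["inside"]], target_area, rng
        )
        for cell in positives:
            pdl1_stack[z, cell["rr"], cell["cc"]] = True
            ring = _annulus(cell["center"], cell["r"], 2.0, (h, w))
            marker[ring] = np.maximum(marker[ring], rng.uniform(*MARKER_RING_INTENSITY))

        layer = np.stack([nuclei, membrane, marker], axis=-1)
        if params.intensity_decay_per_um > 0:
            layer *= np.exp(-params.intensity_decay_per_um * z * params.z_spacing_um)
        if params.noise_sigma > 0:
            layer += rng.normal(0.0, params.noise_sigma, size=layer.shape)
        voxels[z] = np.clip(layer, 0.0, None)

    tumor_stack = np.broadcast_to(tumor_region, (n_z, h, w)).copy()
    dcis_stack = np.broadcast_to(dcis_region, (n_z, h, w)).copy()
    truth = GroundTruth(
        tumor_mask=tumor_stack,
        immune_mask=immune_stack,
        pdl1_pos_mask=pdl1_stack,
        dcis_mask=dcis_stack,
        per_layer_truth=per_layer_truth_from_masks(
            tumor_stack, immune_stack, pdl1_stack
        ),
    )
    truth.validate()
    stack = ChannelStack(
        voxels=voxels,
        z_spacing_um=params.z_spacing_um,
        pixel_size_um=params.pixel_size_um,
    )
    return stack, truth


def _annulus(
    center: tuple[float, float], radius: float, width: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coords of the outer ring of a drawn disc (subset of the disc)."""
    rr, cc = draw_disk(center, radius, shape=shape)
    dist = np.hypot(rr - center[0], cc - center[1])
    sel = dist > radius - width
    return rr[sel], cc[sel]


def _render_tumor_nuclei(
    rng: np.random.Generator,
    nuclei: np.ndarray,
    membrane: np.ndarray,
    nests: list[tuple[float, float, float]],
    params: PhantomParams,
) -> None:
    """Overlapping elliptical tumor nuclei packed into each nest, clipped to
    the nest disc so the region mask stays the exact tumor ground truth."""
    h, w = nuclei.shape
    r_lo, r_hi = params.tumor_nucleus_radius_px
    mean_area = np.pi * ((r_lo + r_hi) / 2) ** 2 * 0.75
    for cy, cx, nest_r in nests:
        nest_mask = np.zeros((h, w), dtype=bool)
        rr, cc = draw_disk((cy, cx), nest_r, shape=(h, w))
        nest_mask[rr, cc] = True
        n_nuclei = max(int(2.3 * np.pi * nest_r**2 / mean_area), 1)
        for _ in range(n_nuclei):
            rho = nest_r * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            ny, nx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            a = rng.uniform(r_lo, r_hi)
            b = a * rng.uniform(0.55, 0.95)
            rot = rng.uniform(0, np.pi)
            err, ecc = draw_ellipse(ny, nx, a, b, shape=(h, w), rotation=rot)
            keep = nest_mask[err, ecc]
            err, ecc = err[keep], ecc[keep]
            nuclei[err, ecc] = np.maximum(
                nuclei[err, ecc], rng.uniform(*TUMOR_NUCLEUS_INTENSITY)
            )
            oerr, oecc = draw_ellipse(
                ny, nx, a + 1.5, b + 1.5, shape=(h, w), rotation=rot
            )
            okeep = nest_mask[oerr, oecc]
            ring = np.zeros((h, w), dtype=bool)
            ring[oerr[okeep], oecc[okeep]] = True
            ring[err, ecc] = False
            membrane[ring] = np.maximum(membrane[ring], TUMOR_MEMBRANE_INTENSITY)
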