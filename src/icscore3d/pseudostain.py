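"""Virtual bright-field rendering of fluorescence channels.

A Beer-Lambert model converts fluorescence intensities into absorbance-based
RGB images on a white background: pseudo-H&E maps the nuclei channel to
hematoxylin and the membrane channel to eosin; pseudo-IHC additionally maps
the marker channel to DAB brown.  Visual QC only — no quantitative claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Published stain optical-density (absorbance) RGB vectors, unit length.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
EOSIN_OD = (0.072, 0.990, 0.105)
DAB_OD = (0.268, 0.570, 0.776)


@dataclass(frozen=True)
class StainRecipe:
    """Per-channel absorbance colors and gains; zero input renders pure white."""

    od_vectors: tuple[tuple[float, float, float], ...]
    gains: tuple[float, ...]
    channel_names: tuple[str, ...] = ("nuclei", "membrane", "marker")

    def __post_init__(self) -> None:
        if len(self.od_vectors) != len(self.gains):
            raise ValueError("one OD vector and one gain per channel required")
        for vec in self.od_vectors:
            if len(vec) != 3 or any(v < 0 for v in vec):
                raise ValueError("OD vectors must be non-negative RGB triples")

    def to_dict(self) -> dict:
        return {
            "od_vectors": [list(v) for v in self.od_vectors],
            "gains": list(self.gains),
            "channel_names": list(self.channel_names),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StainRecipe":
        return cls(
            od_vectors=tuple(tuple(v) for v in data["od_vectors"]),
            gains=tuple(data["gains"]),
            channel_names=tuple(data.get("channel_names", ("nuclei", "membrane", "marker"))),
        )


def he_recipe() -> StainRecipe:
    """Pseudo-H&E: nuclei -> hematoxylin, membrane -> eosin, marker ignored."""
    return StainRecipe(
        od_vectors=(HEMATOXYLIN_OD, EOSIN_OD, (0.0, 0.0, 0.0)),
        gains=(1.2, 0.8, 0.0),
    )


def ihc_recipe() -> StainRecipe:
    """Pseudo-IHC: hematoxylin counterstain plus DAB brown for the marker."""
    return StainRecipe(
        od_vectors=(HEMATOXYLIN_OD, EOSIN_OD, DAB_OD),
        gains=(1.0, 0.2, 1.5),
    )


def render_pseudo(channels: np.ndarray, recipe: StainRecipe) -> np.ndarray:
    """Render an RGB uint8 image from normalized fluorescence channels.

    ``channels`` is (y, x, c) with intensities in [0, 1].  Per pixel,
    ``RGB = 255 * exp(-sum_c gain_c * intensity_c * OD_c)``, so absorbances add
    across channels and all-zero pixels are exactly white.
    """
    arr = np.asarray(channels, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != len(recipe.od_vectors):
        raise ValueError(
            f"expected (y, x, {len(recipe.od_vectors)}) channel image, got {arr.shape}"
        )
    if np.nanmin(arr) < 0:
        raise ValueError("channel intensities must be non-negative")
    od = np.zeros(arr.shape[:2] + (3,), dtype=np.float64)
    for c, (vec, gain) in enumerate(zip(recipe.od_vectors, recipe.gains)):
        od += gain * arr[..., c, None] * np.asarray(vec)
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def normalize_channels(channels: np.ndarray) -> np.ndarray:
    """Scale each channel to [0, 1] by its own maximum (no-op for empty channels)."""
    arr = np.asarray(channels, dtype=np.float64).copy()
    for c in range(arr.shape[-1]):
        peak = arr[..., c].max()
        if peak > 0:
            arr[..., c] /= peak
    return arr
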