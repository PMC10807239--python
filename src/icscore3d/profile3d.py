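"""Depth-profile assembly and cohort agreement statistics.

Turns the ordered per-layer scores of one case into a 3D summary (average
score, range, 1%-threshold crossing, heterogeneity pattern), compares the 3D
average against a single-layer 2D reference, and aggregates per-case
categories into a confusion table with overall percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import CATEGORIES, CATEGORY_ORDER, LayerScore, categorize

PATTERNS = (
    "uniform_negative",
    "uniform_expressed",
    "heterogeneous_presence",
    "category_crossing",
)

DISCORDANCE = ("concordant", "3d_higher", "3d_lower")


def select_layers(n_z: int, z_spacing_um: float, analysis_interval_um: float) -> list[int]:
    """z indices analyzed at the configured depth interval.

    The stride is ``round(interval / spacing)``; indices run 0, stride,
    2*stride, ... below ``n_z``.  E.g. acquisition every 1.4 um analyzed every
    7 um gives stride 5.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    if z_spacing_um <= 0 or analysis_interval_um <= 0:
        raise ValueError("spacing and interval must be positive")
    if analysis_interval_um < z_spacing_um:
        raise ValueError("analysis interval must be >= z spacing")
    stride = int(round(analysis_interval_um / z_spacing_um))
    return list(range(0, n_z, stride))


def pattern_label(categories: Sequence[str]) -> str:
    """Heterogeneity pattern of a case from its per-layer categories.

    All layers negative -> ``uniform_negative``.  A mix of negative and
    expressed (borderline or positive) layers -> ``heterogeneous_presence``.
    All layers expressed but spanning both sides of the 1% cut (borderline and
    positive mixed) -> ``category_crossing``.  Otherwise ``uniform_expressed``.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("at least one category required")
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    has_neg = "negative" in cats
    has_expr = any(c in ("borderline", "positive") for c in cats)
    if has_neg and not has_expr:
        return "uniform_negative"
    if has_neg and has_expr:
        return "heterogeneous_presence"
    if "borderline" in cats and "positive" in cats:
        return "category_crossing"
    return "uniform_expressed"


def immune_area_variation(immune_areas: Sequence[float]) -> float:
    """Relative inter-layer spread of immune-cell area: (max - min) / max."""
    areas = np.asarray(list(immune_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("at least one layer required")
    if areas.max() <= 0:
        raise ValueError("immune area variation undefined for all-zero areas")
    return float((areas.max() - areas.min()) / areas.max())


def discordance_2d_3d(average_score_pct: float, reference_score_pct: float) -> str:
    """Categorical 2D-vs-3D comparison.

    Compares the category of the 3D average score with the category of the 2D
    reference score on the scale negative < borderline < positive.
    """
    cat3d = categorize(average_score_pct)
    cat2d = categorize(reference_score_pct)
    if cat3d == cat2d:
        return "concordant"
    return "3d_higher" if CATEGORY_ORDER[cat3d] > CATEGORY_ORDER[cat2d] else "3d_lower"


@dataclass
class CaseProfile:
    """Ordered per-layer scores of one case plus the 3D summary."""

    case_id: str
    layers: list[LayerScore]
    average_score_pct: float
    min_score_pct: float
    max_score_pct: float
    range_pct: float
    crossing_1pct: bool
    pattern: str
    immune_area_range_frac: Optional[float] = None
    reference_2d_score_pct: Optional[float] = None
    reference_2d_category: Optional[str] = None
    discordance: Optional[str] = None
    average_category: str = field(init=False)

    def __post_init__(self) -> None:
        self.average_category = categorize(self.average_score_pct)

    def summary(self) -> dict:
        return {
            "case_id": self.case_id,
            "n_layers": len(self.layers),
            "n_scored_layers": sum(not s.no_tumor for s in self.layers),
            "average_score_pct": self.average_score_pct,
            "average_category": self.average_category,
            "min_score_pct": self.min_score_pct,
            "max_score_pct": self.max_score_pct,
            "range_pct": self.range_pct,
            "crossing_1pct": self.crossing_1pct,
            "pattern": self.pattern,
            "immune_area_range_frac": self.immune_area_range_frac,
            "reference_2d_score_pct": self.reference_2d_score_pct,
            "reference_2d_category": self.reference_2d_category,
            "discordance": self.discordance,
        }


def build_profile(
    case_id: str,
    layer_scores: Sequence[LayerScore],
    reference_2d_score_pct: Optional[float] = None,
) -> CaseProfile:
    """Assemble a CaseProfile from per-layer scores kept in depth order.

    Layers flagged "no tumor" are retained in the table but excluded from the
    average, min/max, crossing flag and pattern.  The 3D average is the
    unweighted mean of the defined layer scores.
    """
    layers = sorted(layer_scores, key=lambda s: s.z_index)
    scored = [s for s in layers if not s.no_tumor]
    if not scored:
        raise ValueError("no layer with a defined score (all layers lack tumor area)")
    scores = np.asarray([s.ic_score_pct for s in scored], dtype=float)
    average = float(scores.mean())
    lo, hi = float(scores.min()), float(scores.max())
    crossing = bool(lo < 1.0 <= hi)
    pattern = pattern_label([s.category for s in scored])

    immune_areas = [s.immune_area_px for s in scored]
    variation = immune_area_variation(immune_areas) if max(immune_areas) > 0 else None

    ref_cat = None
    disc = None
    if reference_2d_score_pct is not None:
        ref_cat = categorize(reference_2d_score_pct)
        disc = discordance_2d_3d(average, reference_2d_score_pct)
    return CaseProfile(
        case_id=case_id,
        layers=layers,
        average_score_pct=average,
        min_score_pct=lo,
        max_score_pct=hi,
        range_pct=hi - lo,
        crossing_1pct=crossing,
        pattern=pattern,
        immune_area_range_frac=variation,
        reference_2d_score_pct=reference_2d_score_pct,
        reference_2d_category=ref_cat,
        discordance=disc,
    )


@dataclass(frozen=True)
class AgreementTable:
    """Reference-vs-predicted category confusion counts for a cohort."""

    categories: tuple[str, ...]
    counts: pd.DataFrame  # index = reference, columns = predicted
    n_cases: int
    overall_percent_agreement: float


def agreement_table(
    reference: Sequence[str], predicted: Sequence[str]
) -> AgreementTable:
    """Confusion table and overall percent agreement (100 * matches / n)."""
    ref = list(reference)
    pred = list(predicted)
    if len(ref) != len(pred):
        raise ValueError("reference and predicted must have equal length")
    if not ref:
        raise ValueError("empty category vectors")
    unknown = (set(ref) | set(pred)) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for r, p in zip(ref, pred):
        counts.loc[r, p] += 1
    n = len(ref)
    agreement = 100.0 * float(np.trace(counts.to_numpy())) / n
    counts.index.name = "reference"
    counts.columns.name = "predicted"
    return AgreementTable(
        categories=CATEGORIES,
        counts=counts,
        n_cases=n,
        overall_percent_agreement=agreement,
    )
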