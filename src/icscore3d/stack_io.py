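"""Stack/mask I/O, the per-case report, and the pipeline orchestrator.

Convention used throughout: voxel arrays are indexed ``(z, y, x[, channel])``,
0-based, with exactly three named channels in the fixed order
``(nuclei, membrane, marker)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd
import tifffile

from . import profile3d, scoring
from .profile3d import CaseProfile, build_profile, select_layers
from .scoring import LayerMasks, LayerScore, layer_ic_score

logger = logging.getLogger(__name__)

CHANNEL_NAMES = ("nuclei", "membrane", "marker")


@dataclass
class ChannelStack:
    """A 3-channel voxel grid with physical calibration.

    ``voxels`` is (z, y, x, channel), finite and non-negative.
    """

    voxels: np.ndarray
    z_spacing_um: float
    pixel_size_um: float
    channel_names: tuple[str, str, str] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[-1] != 3:
            raise ValueError(
                f"voxels must be (z, y, x, 3), got shape {self.voxels.shape}"
            )
        if tuple(self.channel_names) != CHANNEL_NAMES:
            raise ValueError(f"channel names must be {CHANNEL_NAMES} in order")
        if self.z_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_spacing_um and pixel_size_um must be positive")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """(z, y, x) stack of one named channel."""
        return self.voxels[..., self.channel_names.index(name)]

    def layer(self, z: int) -> np.ndarray:
        """(y, x, channel) image of one z-layer."""
        return self.voxels[z]


def write_stack(stack: ChannelStack, path: Path | str) -> Path:
    """Write an OME-TIFF with per-axis physical calibration in the metadata."""
    path = Path(path)
    data = np.moveaxis(stack.voxels, -1, 1)  # (z, c, y, x) for OME axes ZCYX
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_spacing_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path


def _ome_physical_sizes(ome_xml: str) -> dict[str, float]:
    sizes: dict[str, float] = {}
    try:
        root = ElementTree.fromstring(ome_xml)
    except ElementTree.ParseError:
        return sizes
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            for key, name in (
                ("PhysicalSizeX", "x"),
                ("PhysicalSizeZ", "z"),
            ):
                if key in elem.attrib:
                    sizes[name] = float(elem.attrib[key])
    return sizes


def read_stack(
    path: Path | str,
    channel_map: Optional[Mapping[str, int]] = None,
    pixel_size_um: Optional[float] = None,
    z_spacing_um: Optional[float] = None,
) -> ChannelStack:
    """Read a multichannel TIFF/OME-TIFF into a ChannelStack.

    ``channel_map`` maps the three canonical channel names to channel indices
    in the file (default: file order).  Calibration is taken from OME metadata
    when present, else from the ``pixel_size_um`` / ``z_spacing_um`` fallbacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZCYX"
        if tif.ome_metadata:
            meta = _ome_physical_sizes(tif.ome_metadata)
            pixel_size_um = meta.get("x", pixel_size_um)
            z_spacing_um = meta.get("z", z_spacing_um)

    if "C" not in axes:
        raise ValueError(f"missing channel axis in {path} (axes {axes!r})")
    order = [axes.index(a) for a in "ZYXC" if a in axes]
    extra = [i for i in range(data.ndim) if i not in order]
    data = np.transpose(data, extra + order)
    data = data.reshape(data.shape[len(extra):])  # drop singleton leading axes
    if "Z" not in axes:
        data = data[np.newaxis, ...]
    n_channels = data.shape[-1]
    channel_map = dict(channel_map or {name: i for i, name in enumerate(CHANNEL_NAMES)})
    missing = [n for n in CHANNEL_NAMES if channel_map.get(n, n_channels) >= n_channels]
    if missing:
        raise ValueError(f"missing channel(s) {missing} in {path} ({n_channels} found)")
    data = data[..., [channel_map[n] for n in CHANNEL_NAMES]]
    if pixel_size_um is None or z_spacing_um is None:
        raise ValueError(
            f"no calibration in {path} metadata and no config fallback given"
        )
    return ChannelStack(
        voxels=np.ascontiguousarray(data),
        z_spacing_um=float(z_spacing_um),
        pixel_size_um=float(pixel_size_um),
    )


def write_masks(masks: np.ndarray, path: Path | str, shape: Optional[tuple] = None) -> Path:
    """Write a binary (z, y, x) stack as a multi-page 0/255 uint8 TIFF."""
    path = Path(path)
    arr = np.asarray(masks)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected (z, y, x) mask stack, got shape {arr.shape}")
    if shape is not None and tuple(arr.shape) != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match image shape {shape}")
    tifffile.imwrite(
        path, (arr.astype(bool) * np.uint8(255)), photometric="minisblack"
    )
    return path


def read_masks(path: Path | str) -> np.ndarray:
    """Read a multi-page mask TIFF back to a boolean (z, y, x) stack."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    return arr > 0


@dataclass
class CaseReport:
    """Per-layer score table plus the recomputable 3D summary of one case."""

    case_id: str
    layer_table: pd.DataFrame
    summary: dict
    profile: Optional[CaseProfile] = None

    LAYER_COLUMNS = (
        "z_index",
        "depth_um",
        "tumor_area_px",
        "immune_area_px",
        "pdl1_ic_area_px",
        "ic_score_pct",
        "category",
    )

    def write(self, out_dir: Path | str) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{self.case_id}_layers.csv"
        json_path = out_dir / f"{self.case_id}_summary.json"
        self.layer_table.to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self.summary, indent=2, default=_jsonify))
        return csv_path, json_path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


DEFAULT_CONFIG = {
    "analysis_interval_um": 7.0,
    "closing_radius_px": 20,
    "min_hole_px": 5000,
    "exclude_dcis": False,
    "marker_threshold": None,  # None -> Otsu within the immune mask
    "cell_level_positivity": True,
}


def run_case(
    stack: ChannelStack,
    segmenters: Optional[dict] = None,
    oracle_truth=None,
    config: Optional[dict] = None,
    case_id: str = "case",
    reference_2d_score_pct: Optional[float] = None,
) -> CaseReport:
    """Run the full per-case pipeline: layer selection, per-layer masks
    (predicted or oracle), IC scoring, and the 3D depth profile.

    Exactly one of ``segmenters`` (dict with "tumor" and "immune" Segmenter
    objects) or ``oracle_truth`` (GroundTruth) must be provided.  Oracle mode
    scores the ground-truth masks directly and is fully deterministic.
    """
    from .segmentation import predict_mask  # deferred: heavy imports

    if (segmenters is None) == (oracle_truth is None):
        raise ValueError("provide exactly one of segmenters or oracle_truth")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})

    z_indices = select_layers(stack.n_z, stack.z_spacing_um, cfg["analysis_interval_um"])
    logger.info(
        "case %s: analyzing %d of %d layers (interval %.2f um)",
        case_id, len(z_indices), stack.n_z, cfg["analysis_interval_um"],
    )

    layer_scores: list[LayerScore] = []
    for z in z_indices:
        dcis = None
        if oracle_truth is not None:
            tumor_area = oracle_truth.tumor_mask[z]
            immune = oracle_truth.immune_mask[z]
            immune_in, immune_peri = scoring.split_immune(immune, tumor_area)
            pdl1 = oracle_truth.pdl1_pos_mask[z] & immune_in
            masks = LayerMasks(
                z_index=z,
                tumor_cell_mask=tumor_area,
                tumor_area_mask=tumor_area,
                immune_mask=immune,
                immune_in_tumor_mask=immune_in,
                immune_peritumoral_mask=immune_peri,
                pdl1_pos_ic_mask=pdl1,
            )
            dcis = oracle_truth.dcis_mask[z]
        else:
            layer = stack.layer(z)
            counterstains = layer[..., :2]
            tumor_cells = predict_mask(segmenters["tumor"], counterstains)
            tumor_area = scoring.merge_tumor_area(
                tumor_cells, cfg["closing_radius_px"], cfg["min_hole_px"]
            )
            immune = predict_mask(segmenters["immune"], counterstains)
            immune_in, immune_peri = scoring.split_immune(immune, tumor_area)
            pdl1 = scoring.pdl1_positive_ic(
                layer[..., 2],
                immune_in,
                intensity_threshold=cfg["marker_threshold"],
                cell_level=cfg["cell_level_positivity"],
            )
            masks = LayerMasks(
                z_index=z,
                tumor_cell_mask=tumor_cells & tumor_area,
                tumor_area_mask=tumor_area,
                immune_mask=immune,
                immune_in_tumor_mask=immune_in,
                immune_peritumoral_mask=immune_peri,
                pdl1_pos_ic_mask=pdl1,
            )
        score = layer_ic_score(
            masks,
            stack.z_spacing_um,
            dcis_mask=dcis,
            exclude_dcis=cfg["exclude_dcis"],
        )
        if score.no_tumor:
            logger.info("case %s layer z=%d: no tumor area, excluded", case_id, z)
        layer_scores.append(score)

    profile = build_profile(case_id, layer_scores, reference_2d_score_pct)
    table = pd.DataFrame(
        [
            {
                "z_index": s.z_index,
                "depth_um": s.depth_um,
                "tumor_area_px": s.tumor_area_px,
                "immune_area_px": s.immune_area_px,
                "pdl1_ic_area_px": s.pdl1_ic_area_px,
                "ic_score_pct": np.nan if s.no_tumor else s.ic_score_pct,
                "category": "no_tumor" if s.no_tumor else s.category,
            }
            for s in profile.layers
        ]
    )
    return CaseReport(
        case_id=case_id, layer_table=table, summary=profile.summary(), profile=profile
    )
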