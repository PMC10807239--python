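"""Two-stage cell segmentation: tumor model followed by immune model.

The trainable segmenter is a multiscale pixel classifier (scikit-image basic
features + random forest) operating on the two counterstain channels; it is
trained patch-wise on annotated layers with a seeded 8:1:1
train/validation/test split and evaluated with exact pixelwise metrics.  A
deterministic classical threshold+morphology segmenter is provided as an
oracle/fallback so the downstream pipeline is testable without training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.feature import multiscale_basic_features
from skimage.morphology import disk
from sklearn.ensemble import RandomForestClassifier

from .scoring import binary_close, fill_small_holes

SPLITS = ("train", "val", "test")


@dataclass
class PatchSet:
    """Fixed-size image crops with congruent binary labels and a split tag."""

    patches: np.ndarray  # (n, size, size, channels) float32
    labels: np.ndarray  # (n, size, size) bool
    split: np.ndarray  # (n,) unicode in {"train", "val", "test"}
    patch_size: int

    def __post_init__(self) -> None:
        if self.patches.shape[:3] != self.labels.shape:
            raise ValueError("labels not congruent with patches")
        if self.patches.shape[1] != self.patch_size or self.patches.shape[2] != self.patch_size:
            raise ValueError("patches do not match patch_size")
        if len(self.split) != len(self.patches):
            raise ValueError("split assignment length mismatch")

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == split
        return self.patches[sel], self.labels[sel]

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.split == s)) for s in SPLITS}


def _as_layer_list(arrays, n_channel_dims: int) -> list[np.ndarray]:
    """Accept a stack (z, y, x, ...) or a sequence of layers (y, x, ...)."""
    if isinstance(arrays, np.ndarray) and arrays.ndim == 2 + n_channel_dims + 1:
        return [arrays[i] for i in range(arrays.shape[0])]
    return [np.asarray(a) for a in arrays]


def make_patchset(
    images,
    label_stacks,
    patch_size: int = 256,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> PatchSet:
    """Tile annotated layers into square patches and split them 8:1:1.

    ``images`` is a (z, y, x, c) stack or a sequence of (y, x, c) layers;
    ``label_stacks`` the congruent binary masks.  Layers are tiled without
    overlap (edges padded with zeros); the split assignment is a seeded
    permutation with val/test sizes rounded from the ratio and every patch in
    exactly one split.
    """
    layers = _as_layer_list(images, 1)
    labels = _as_layer_list(label_stacks, 0)
    if len(layers) != len(labels):
        raise ValueError("images and labels must have the same number of layers")
    if not layers:
        raise ValueError("empty image set")
    patches, patch_labels = [], []
    for img, lab in zip(layers, labels):
        if img.shape[:2] != lab.shape:
            raise ValueError("label layer not congruent with image layer")
        if patch_size > max(img.shape[:2]):
            raise ValueError(
                f"patch_size {patch_size} larger than image {img.shape[:2]}"
            )
        h, w = img.shape[:2]
        for y0 in range(0, h, patch_size):
            for x0 in range(0, w, patch_size):
                tile = np.zeros((patch_size, patch_size, img.shape[2]), dtype=np.float32)
                ltile = np.zeros((patch_size, patch_size), dtype=bool)
                ys, xs = min(y0 + patch_size, h), min(x0 + patch_size, w)
                tile[: ys - y0, : xs - x0] = img[y0:ys, x0:xs]
                ltile[: ys - y0, : xs - x0] = lab[y0:ys, x0:xs]
                patches.append(tile)
                patch_labels.append(ltile)
    n = len(patches)
    total = sum(ratio)
    n_val = int(round(n * ratio[1] / total))
    n_test = int(round(n * ratio[2] / total))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.full(n, "train", dtype="U5")
    split[order[:n_val]] = "val"
    split[order[n_val : n_val + n_test]] = "test"
    return PatchSet(
        patches=np.stack(patches),
        labels=np.stack(patch_labels),
        split=split,
        patch_size=patch_size,
    )


@dataclass(frozen=True)
class PixelConfusion:
    """Exact pixel counts of a binary prediction against truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else (1.0 if self.fn == 0 else 0.0)

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 1.0

    @property
    def iou(self) -> float:
        denom = self.tp + self.fp + self.fn
        # empty target and empty prediction: perfect overlap by convention
        return self.tp / denom if denom else 1.0

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def evaluate_pixelwise(pred_mask: np.ndarray, truth_mask: np.ndarray) -> PixelConfusion:
    """Pixelwise confusion counts between congruent binary masks."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return PixelConfusion(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


DEFAULT_MODEL_CONFIG = {
    "n_estimators": 40,
    "max_depth": 14,
    "min_samples_leaf": 2,
    "sigma_min": 1.0,
    "sigma_max": 16.0,
    "num_sigma": 5,
    "pixels_per_patch": 600,
}


def _patch_features(patch: np.ndarray, config: dict) -> np.ndarray:
    return multiscale_basic_features(
        patch,
        channel_axis=-1,
        intensity=True,
        edges=True,
        texture=False,
        sigma_min=config["sigma_min"],
        sigma_max=config["sigma_max"],
        num_sigma=config["num_sigma"],
    )


@dataclass
class Segmenter:
    """A per-layer binary segmenter: patch -> probability map -> mask."""

    target: str  # "tumor" or "immune"
    predictor: Callable[[np.ndarray], np.ndarray]
    threshold: float = 0.5
    kind: str = "forest"
    model: Optional[RandomForestClassifier] = None
    config: dict = field(default_factory=dict)
    validation_accuracy: Optional[float] = None

    def predict_proba(self, patch: np.ndarray) -> np.ndarray:
        prob = np.asarray(self.predictor(patch), dtype=np.float64)
        if prob.shape != patch.shape[:2]:
            raise ValueError("predictor returned a non-congruent probability map")
        if prob.min() < 0 or prob.max() > 1:
            raise ValueError("probability map outside [0, 1]")
        return prob

    def save(self, out_dir: Path | str) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "target": self.target,
            "threshold": self.threshold,
            "kind": self.kind,
            "config": self.config,
            "validation_accuracy": self.validation_accuracy,
        }
        (out_dir / f"{self.target}_segmenter.json").write_text(json.dumps(meta, indent=2))
        if self.model is not None:
            joblib.dump(self.model, out_dir / f"{self.target}_model.joblib")
        return out_dir

    @classmethod
    def load(cls, out_dir: Path | str, target: str) -> "Segmenter":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / f"{target}_segmenter.json").read_text())
        if meta["kind"] == "classical":
            return classical_segmenter(target, meta["config"])
        model = joblib.load(out_dir / f"{target}_model.joblib")
        seg = cls(
            target=target,
            predictor=lambda patch: _forest_predict(model, patch, meta["config"]),
            threshold=meta["threshold"],
            kind=meta["kind"],
            model=model,
            config=meta["config"],
            validation_accuracy=meta.get("validation_accuracy"),
        )
        return seg


def _forest_predict(model, patch: np.ndarray, config: dict) -> np.ndarray:
    feats = _patch_features(np.asarray(patch, dtype=np.float32), config)
    flat = feats.reshape(-1, feats.shape[-1])
    prob = model.predict_proba(flat)[:, 1]
    return prob.reshape(patch.shape[:2])


def train_segmenter(
    patchset: PatchSet,
    target: str,
    model_config: Optional[dict] = None,
    seed: int = 0,
) -> Segmenter:
    """Train the pixel-classifier segmenter on the train split.

    Training pixels are subsampled per patch with foreground/background
    balancing (foreground is sparse for immune cells).  Validation pixel
    accuracy is computed on the val split and stored on the returned model.
    """
    config = dict(DEFAULT_MODEL_CONFIG)
    config.update(model_config or {})
    train_x, train_y = patchset.subset("train")
    if len(train_x) == 0:
        raise ValueError("empty train split")
    if train_y.any() == train_y.all():
        raise ValueError("single-class labels: train split must contain both classes")

    rng = np.random.default_rng(seed)
    n_per = config["pixels_per_patch"]
    feats_list, label_list = [], []
    for patch, lab in zip(train_x, train_y):
        feats = _patch_features(patch, config)
        fg = np.flatnonzero(lab.ravel())
        bg = np.flatnonzero(~lab.ravel())
        n_fg = min(len(fg), n_per // 2)
        n_bg = min(len(bg), n_per - n_fg)
        idx = np.concatenate(
            [
                rng.choice(fg, size=n_fg, replace=False) if n_fg else np.empty(0, int),
                rng.choice(bg, size=n_bg, replace=False) if n_bg else np.empty(0, int),
            ]
        )
        feats_list.append(feats.reshape(-1, feats.shape[-1])[idx])
        label_list.append(lab.ravel()[idx])
    X = np.concatenate(feats_list)
    y = np.concatenate(label_list)

    model = RandomForestClassifier(
        n_estimators=config["n_estimators"],
        max_depth=config["max_depth"],
        min_samples_leaf=config["min_samples_leaf"],
        n_jobs=1,
        random_state=seed,
    )
    model.fit(X, y)

    seg = Segmenter(
        target=target,
        predictor=lambda patch: _forest_predict(model, patch, config),
        kind="forest",
        model=model,
        config=config,
    )
    val_x, val_y = patchset.subset("val")
    if len(val_x):
        conf = sum(
            (evaluate_pixelwise(seg.predict_proba(p) >= seg.threshold, l)
             for p, l in zip(val_x, val_y)),
            PixelConfusion(0, 0, 0, 0),
        )
        seg.validation_accuracy = conf.accuracy
    return seg


def predict_mask(segmenter: Segmenter, layer_image: np.ndarray) -> np.ndarray:
    """Full-layer binary mask from tiled patch predictions.

    Tiles of the training patch size are predicted with 50% overlap, the
    probability maps averaged, and one global threshold applied, so seams do
    not create mask artifacts.  Deterministic at inference.
    """
    layer = np.asarray(layer_image, dtype=np.float32)
    if layer.ndim != 3:
        raise ValueError("layer image must be (y, x, channels)")
    if segmenter.kind == "classical":
        # rule-based predictors are size-free; tiling would bias the
        # component-size filters, so predict the whole layer at once
        return segmenter.predict_proba(layer) >= segmenter.threshold
    h, w = layer.shape[:2]
    size = segmenter.config.get("patch_size") or min(256, h, w)
    pad_h, pad_w = max(size - h, 0), max(size - w, 0)
    if pad_h or pad_w:
        layer = np.pad(layer, ((0, pad_h), (0, pad_w), (0, 0)))
    hh, ww = layer.shape[:2]

    def starts(extent: int) -> list[int]:
        step = max(size // 2, 1)
        vals = list(range(0, max(extent - size, 0) + 1, step))
        if vals[-1] != extent - size:
            vals.append(extent - size)
        return vals

    prob = np.zeros((hh, ww), dtype=np.float64)
    weight = np.zeros((hh, ww), dtype=np.float64)
    for y0 in starts(hh):
        for x0 in starts(ww):
            tile = layer[y0 : y0 + size, x0 : x0 + size]
            prob[y0 : y0 + size, x0 : x0 + size] += segmenter.predict_proba(tile)
            weight[y0 : y0 + size, x0 : x0 + size] += 1.0
    prob /= weight
    return (prob >= segmenter.threshold)[:h, :w]


CLASSICAL_DEFAULTS = {
    "tumor": {
        # band-pass on the nuclei channel: tumor nuclei are dimmer than immune
        "low": 60.0,
        "high": 150.0,
        # faint membrane evidence (tumor-cell rings) fills the nest rim
        "membrane_low": 25.0,
        "membrane_high": 100.0,
        "closing_radius": 12,
        "rim_dilation_px": 2,
        "min_size": 2500,
        "hole_px": 5000,
    },
    "immune": {
        "threshold": 150.0,
        "opening_radius": 0,
        "min_area": 12,
        "max_area": 250,
    },
}


def _drop_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def classical_segmenter(target: str, params: Optional[dict] = None) -> Segmenter:
    """Deterministic threshold + morphology segmenter (training-free oracle).

    Tumor: band-threshold the nuclei channel (large, clustered, moderate
    brightness), close to merge the nest, drop small components, fill holes.
    Immune: high-threshold the nuclei channel (small, round, bright) and keep
    components within the immune size range.
    """
    if target not in ("tumor", "immune"):
        raise ValueError(f"unknown target {target!r}")
    p = dict(CLASSICAL_DEFAULTS[target])
    p.update(params or {})
    if not p:
        raise ValueError("empty parameterization")

    def tumor_predict(patch: np.ndarray) -> np.ndarray:
        arr = np.asarray(patch, dtype=np.float64)
        nuclei = arr[..., 0]
        mask = (nuclei >= p["low"]) & (nuclei < p["high"])
        if arr.shape[-1] > 1:
            membrane = arr[..., 1]
            mask |= (membrane >= p["membrane_low"]) & (membrane < p["membrane_high"])
        mask = binary_close(mask, p["closing_radius"])
        mask = _drop_small_components(mask, p["min_size"])
        mask = fill_small_holes(mask, p["hole_px"])
        if p["rim_dilation_px"] > 0:
            mask = ndi.binary_dilation(mask, structure=disk(p["rim_dilation_px"]))
        return mask.astype(np.float64)

    def immune_predict(patch: np.ndarray) -> np.ndarray:
        nuclei = np.asarray(patch, dtype=np.float64)[..., 0]
        mask = nuclei >= p["threshold"]
        if p["opening_radius"] > 0:
            foot = disk(p["opening_radius"])
            mask = ndi.binary_dilation(
                ndi.binary_erosion(mask, structure=foot), structure=foot
            )
        labels, n = ndi.label(mask)
        if n:
            sizes = np.bincount(labels.ravel(), minlength=n + 1)
            keep = (sizes >= p["min_area"]) & (sizes <= p["max_area"])
            keep[0] = False
            mask = keep[labels]
        return mask.astype(np.float64)

    predictor = tumor_predict if target == "tumor" else immune_predict
    return Segmenter(target=target, predictor=predictor, kind="classical", config=p)
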