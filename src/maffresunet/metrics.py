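"""Segmentation evaluation metrics over the nested WT/TC/ET subregions.

Per binary mask pair (prediction P, ground truth G):

* IoU  = |P∩G| / |P∪G|
* SEN  = |P∩G| / |G|          (sensitivity / recall)
* PPV  = |P∩G| / |P|          (positive predictive value / precision)
* DSC  = 2|P∩G| / (|P|+|G|)   (Dice similarity coefficient)
* HD   = max{ max_p min_g d(p,g), max_g min_p d(g,p) }  (exact symmetric
  Hausdorff distance, Euclidean, between boundary pixel sets, in mm)

Conventions where the definitions are silent: IoU and DSC are 1.0 when both
masks are empty (agreement on absence); slices with empty G are skipped for
SEN, empty P for PPV, and either-empty for HD, with skip counts surfaced in
the report. HD uses boundary pixels (mask minus its 4-connectivity erosion)
and 1 mm isotropic spacing by default. Aggregation is slice-level
mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

SUBREGIONS = ("WT", "TC", "ET")
METRIC_NAMES = ("iou", "sen", "ppv", "dsc", "hd")

_EROSION_STRUCT = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class BinaryMaskPair:
    P: np.ndarray
    G: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.P = np.asarray(self.P).astype(bool)
        self.G = np.asarray(self.G).astype(bool)
        if self.P.shape != self.G.shape:
            raise ValueError(f"mask shape mismatch: P {self.P.shape} vs "
                             f"G {self.G.shape}")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard mask (prob >= threshold); channels are thresholded independently,
    so nesting is not enforced post hoc."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(prob) >= threshold


def iou(pair: BinaryMaskPair) -> float:
    union = np.logical_or(pair.P, pair.G).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pair.P, pair.G).sum() / union)


def sensitivity(pair: BinaryMaskPair) -> float:
    n_g = pair.G.sum()
    if n_g == 0:
        raise ValueError("sensitivity undefined: ground truth mask is empty")
    return float(np.logical_and(pair.P, pair.G).sum() / n_g)


def ppv(pair: BinaryMaskPair) -> float:
    n_p = pair.P.sum()
    if n_p == 0:
        raise ValueError("PPV undefined: predicted mask is empty")
    return float(np.logical_and(pair.P, pair.G).sum() / n_p)


def dsc(pair: BinaryMaskPair) -> float:
    total = pair.P.sum() + pair.G.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(pair.P, pair.G).sum() / total)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (row, col) of boundary pixels: mask minus its erosion."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_EROSION_STRUCT,
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(pair: BinaryMaskPair) -> float:
    """Exact symmetric Hausdorff distance between mask boundaries, in mm."""
    if not pair.P.any() or not pair.G.any():
        raise ValueError("Hausdorff distance undefined: empty mask")
    spacing = np.asarray(pair.pixel_spacing, dtype=float)
    bp = boundary_pixels(pair.P) * spacing
    bg = boundary_pixels(pair.G) * spacing
    distances = cdist(bp, bg)
    d_pg = distances.min(axis=1).max()
    d_gp = distances.min(axis=0).max()
    return float(max(d_pg, d_gp))


@dataclass
class MetricsReport:
    """Per-subregion mean ± SD of each metric over an evaluation set."""

    mean: dict[str, dict[str, float]]
    sd: dict[str, dict[str, float]]
    n_slices_evaluated: int
    n_skipped: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for region in SUBREGIONS:
            row: dict[str, object] = {"subregion": region}
            for metric in METRIC_NAMES:
                row[f"{metric}_mean"] = self.mean[region].get(metric)
                row[f"{metric}_sd"] = self.sd[region].get(metric)
                row[f"{metric}_n_skipped"] = self.n_skipped.get(
                    region, {}).get(metric, 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"mean": self.mean, "sd": self.sd,
                   "n_slices_evaluated": self.n_slices_evaluated,
                   "n_skipped": self.n_skipped}
        Path(path).write_text(json.dumps(payload, indent=1))


def evaluate_pair(pair: BinaryMaskPair) -> dict[str, float | None]:
    """All five metrics for one mask pair; None where undefined."""
    out: dict[str, float | None] = {"iou": iou(pair), "dsc": dsc(pair)}
    out["sen"] = sensitivity(pair) if pair.G.any() else None
    out["ppv"] = ppv(pair) if pair.P.any() else None
    out["hd"] = hausdorff(pair) if (pair.P.any() and pair.G.any()) else None
    return out


def evaluate_set(predictions, targets, threshold: float = 0.5,
                 pixel_spacing: tuple[float, float] = (1.0, 1.0)
                 ) -> MetricsReport:
    """Aggregate metrics over an evaluation set.

    ``predictions``: iterable of (3, H, W) probability maps (or hard masks);
    ``targets``: iterable of (3, H, W) binary subregion masks, channel order
    WT, TC, ET.
    """
    predictions = list(predictions)
    targets = list(targets)
    if len(predictions) != len(targets):
        raise ValueError(f"{len(predictions)} predictions vs "
                         f"{len(targets)} targets")
    if not predictions:
        raise ValueError("empty evaluation set")

    values: dict[str, dict[str, list[float]]] = {
        r: {m: [] for m in METRIC_NAMES} for r in SUBREGIONS}
    skipped: dict[str, dict[str, int]] = {
        r: {m: 0 for m in METRIC_NAMES} for r in SUBREGIONS}

    for prob, target in zip(predictions, targets):
        mask = binarize(np.asarray(prob), threshold)
        target = np.asarray(target).astype(bool)
        for c, region in enumerate(SUBREGIONS):
            pair = BinaryMaskPair(mask[c], target[c],
                                  pixel_spacing=pixel_spacing)
            per = evaluate_pair(pair)
            for metric, value in per.items():
                if value is None:
                    skipped[region][metric] += 1
                else:
                    values[region][metric].append(value)

    mean = {r: {m: float(np.mean(v)) for m, v in values[r].items() if v}
            for r in SUBREGIONS}
    sd = {r: {m: float(np.std(v)) for m, v in values[r].items() if v}
          for r in SUBREGIONS}
    return MetricsReport(mean=mean, sd=sd,
                         n_slices_evaluated=len(predictions),
                         n_skipped=skipped)
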