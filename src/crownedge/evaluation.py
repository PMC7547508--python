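"""Probability fusion, accuracy metrics, crown extraction, defoliation rate.

The fused label map takes the per-pixel maximum-probability class. Accuracy
is summarized by the confusion matrix over verification pixels: overall
accuracy (OA), Cohen's kappa, per-class producer accuracy, and CADP — the
producer accuracy (recall) of the damaged-pine class, i.e. the extraction
accuracy of damaged crowns. Edge preservation is scored by the mean
structural similarity index (MSSIM) between the guidance image and a
filtered probability map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.metrics import structural_similarity

from .classifier import ProbabilityStack
from .raster_io import GuidanceImage, LabelMap, SampleSet

__all__ = [
    "EvaluationReport",
    "fuse_max_probability",
    "mssim",
    "evaluate",
    "evaluate_predictions",
    "extract_crown_mask",
    "crown_components",
    "crown_polygons_geojson",
    "defoliation_rate",
]

SSIM_K1 = 0.01
SSIM_K2 = 0.03


def fuse_max_probability(stack: ProbabilityStack) -> LabelMap:
    """Per-pixel argmax over the K class maps; ties take the lowest class id."""
    if stack.n_classes < 2:
        raise ValueError("stack must have at least 2 classes")
    if np.isnan(stack.values).any():
        raise ValueError("NaN in probability stack")
    labels = np.argmax(stack.values, axis=2).astype(np.int64)
    return LabelMap(labels, stack.legend)


def mssim(
    guidance: GuidanceImage | np.ndarray,
    filtered: np.ndarray,
    window: int = 11,
    L: float = 1.0,
) -> float:
    """Mean structural similarity between guidance and a filtered map.

    Local statistics use the standard SSIM protocol: an 11×11 Gaussian
    window (sigma = 1.5), constants c1 = (K1*L)^2, c2 = (K2*L)^2 with
    K1 = 0.01, K2 = 0.03, and dynamic range L (1 for [0, 1] images).
    3-channel guidance is reduced to luminance so the comparison is
    single-channel vs single-channel.
    """
    if isinstance(guidance, GuidanceImage):
        g = guidance.luminance()
    else:
        g = np.asarray(guidance, dtype=float)
        if g.ndim == 3:
            g = GuidanceImage(np.clip(g, 0, 1)).luminance()
    q = np.asarray(filtered, dtype=float)
    if g.shape != q.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {q.shape}")
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    return float(
        structural_similarity(
            g, q,
            win_size=window,
            data_range=L,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
        )
    )


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = truth, cols = predicted) with summary scores."""

    confusion: np.ndarray
    legend: Sequence[str]
    damaged_class: int

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        k = self.confusion.shape[0]
        if self.confusion.shape != (k, k):
            raise ValueError("confusion matrix must be square")
        self.legend = list(self.legend)

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def oa(self) -> float:
        """Overall accuracy: trace / total."""
        return float(np.trace(self.confusion)) / self.total

    @property
    def kappa(self) -> float:
        """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from the marginals."""
        n = self.total
        p_o = np.trace(self.confusion) / n
        p_e = float(self.confusion.sum(axis=1) @ self.confusion.sum(axis=0)) / n**2
        if p_e == 1.0:
            return 0.0
        return float((p_o - p_e) / (1 - p_e))

    @property
    def producer_accuracy(self) -> np.ndarray:
        """Per-class recall: diagonal / row sums (NaN for absent classes)."""
        row = self.confusion.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row, np.nan)

    @property
    def cadp(self) -> float:
        """Producer accuracy of the damaged-pine class."""
        return float(self.producer_accuracy[self.damaged_class])

    def to_dict(self) -> dict:
        return {
            "legend": list(self.legend),
            "confusion": self.confusion.tolist(),
            "OA": self.oa,
            "Kappa": self.kappa,
            "producer_accuracy": [
                None if np.isnan(x) else float(x) for x in self.producer_accuracy
            ],
            "CADP": self.cadp,
            "damaged_class": int(self.damaged_class),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def evaluate_predictions(
    truth: np.ndarray,
    predicted: np.ndarray,
    n_classes: int,
    damaged_class: int,
    legend: Sequence[str] | None = None,
) -> EvaluationReport:
    """Build an EvaluationReport from aligned truth/prediction label vectors."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (truth, predicted), 1)
    if legend is None:
        legend = [f"class_{i}" for i in range(n_classes)]
    return EvaluationReport(confusion, legend, damaged_class)


def evaluate(
    pred: LabelMap,
    truth: SampleSet | LabelMap,
    damaged_class: int | str,
) -> EvaluationReport:
    """Score a predicted label map against verification samples or a truth map.

    With a SampleSet, only its verification-role pixels enter the confusion
    matrix; with a LabelMap, all non-nodata pixels do.
    """
    if isinstance(damaged_class, str):
        damaged_class = pred.class_id(damaged_class)
    k = pred.n_classes
    if isinstance(truth, SampleSet):
        verify = truth.verification
        if len(verify) == 0:
            verify = truth
        t = verify.class_ids
        p = pred.values[verify.rows, verify.cols]
    else:
        valid = truth.values != truth.nodata
        t = truth.values[valid]
        p = pred.values[valid]
    present = np.unique(t)
    if len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        raise ValueError(f"class id(s) {missing} absent from truth")
    return evaluate_predictions(t, p, n_classes=k, damaged_class=damaged_class,
                                legend=pred.legend)


# ---------------------------------------------------------------------------
# crown extraction
# ---------------------------------------------------------------------------


def extract_crown_mask(label_map: LabelMap, damaged_class: int | str) -> np.ndarray:
    """Binary mask of the damaged-crown class."""
    if isinstance(damaged_class, str):
        damaged_class = label_map.class_id(damaged_class)
    if not 0 <= damaged_class < label_map.n_classes:
        raise KeyError(f"class id {damaged_class} not in legend")
    return label_map.values == damaged_class


def crown_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling of a crown mask."""
    labeled, n = measure.label(mask, connectivity=2, return_num=True)
    return labeled, n


def crown_polygons_geojson(mask: np.ndarray, path: str | Path | None = None) -> dict:
    """Crown outlines as a GeoJSON FeatureCollection in pixel coordinates.

    Coordinates are (col, row) pairs of the 0.5-level contour around each
    8-connected component; merged crown clusters come out as one polygon.
    """
    labeled, n = crown_components(mask)
    features = []
    for comp in range(1, n + 1):
        comp_mask = (labeled == comp).astype(float)
        contours = measure.find_contours(np.pad(comp_mask, 1), 0.5)
        rings = []
        for contour in contours:
            ring = [[float(c - 1.0), float(r - 1.0)] for r, c in contour]
            if ring[0] != ring[-1]:
                ring.append(ring[0])
            rings.append(ring)
        features.append(
            {
                "type": "Feature",
                "properties": {"component": comp, "area_px": int(comp_mask.sum())},
                "geometry": {"type": "Polygon", "coordinates": rings},
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(collection) + "\n")
    return collection


# ---------------------------------------------------------------------------
# defoliation rate
# ---------------------------------------------------------------------------

LOSS_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)


def defoliation_rate(counts: np.ndarray) -> float:
    """Tree-level defoliation percentage from per-layer needle counts.

    ``counts`` is a 3×5 array: rows = branch layers (upper, middle, lower),
    columns = needle counts in the 0/25/50/75/100 % loss levels. The layer
    rate is the count-weighted mean loss; the tree rate averages the three
    layers. Returns percent in [0, 100].
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 5):
        raise ValueError(f"counts must be 3 layers × 5 loss levels, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("needle counts must be non-negative")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every layer needs a positive total needle count")
    levels = np.asarray(LOSS_LEVELS)
    per_layer = counts @ levels / totals
    return float(per_layer.sum() / 3.0)
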