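"""Per-seed classification maps and score-image rendering.

A classification map colours every pixel of a seed by the class the
discriminant model predicted for that seed (background stays 0/black), so
the spatial layout of varieties is read off the image directly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import write_map
from .segment import RoiLabelMap

__all__ = ["ClassificationMap", "DEFAULT_PALETTE", "paint_map", "map_accuracy", "render_map_png", "render_score_image"]

#: background black; classes 1/2/3 red, green, blue
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 0),
    1: (220, 50, 47),
    2: (64, 160, 43),
    3: (38, 99, 210),
}


@dataclasses.dataclass
class ClassificationMap:
    """Per-pixel predicted class in {0 background, 1, 2, 3}."""

    image: np.ndarray
    legend: Mapping[int, tuple[int, int, int]]
    provenance: str = ""


def paint_map(
    labels: RoiLabelMap,
    predictions: Mapping[int, int] | Sequence[int],
    *,
    legend: Mapping[int, tuple[int, int, int]] | None = None,
    provenance: str = "",
) -> ClassificationMap:
    """Colour each ROI by its predicted class.

    ``predictions`` maps label -> class, or is a sequence whose item r-1 is
    the class of label r.  Every ROI must have a prediction.
    """
    if not isinstance(predictions, Mapping):
        predictions = {r + 1: int(c) for r, c in enumerate(predictions)}
    missing = [r for r in range(1, labels.n_rois + 1) if r not in predictions]
    if missing:
        raise ValueError(f"missing predictions for labels {missing}")
    lut = np.zeros(labels.n_rois + 1, dtype=np.int64)
    for r in range(1, labels.n_rois + 1):
        cls = int(predictions[r])
        if cls not in (1, 2, 3):
            raise ValueError(f"label {r}: predicted class {cls} outside {{1, 2, 3}}")
        lut[r] = cls
    return ClassificationMap(
        image=lut[labels.labels], legend=legend or DEFAULT_PALETTE, provenance=provenance
    )


def map_accuracy(
    predictions: Sequence[int] | Mapping[int, int],
    truth: Sequence[int] | Mapping[int, int],
) -> tuple[float, int, int]:
    """Object-level accuracy of predicted vs true classes.

    Returns ``(percent to 1 decimal, n_correct, n_total)``.
    """
    if isinstance(predictions, Mapping):
        predictions = [predictions[k] for k in sorted(predictions)]
    if isinstance(truth, Mapping):
        truth = [truth[k] for k in sorted(truth)]
    predictions = np.asarray(list(predictions), dtype=int)
    truth = np.asarray(list(truth), dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"ROI count mismatch: {predictions.size} predictions vs {truth.size} truths"
        )
    correct = int((predictions == truth).sum())
    total = int(truth.size)
    pct = float(np.round(100.0 * correct / total, 1)) if total else 0.0
    return pct, correct, total


def render_map_png(cmap: ClassificationMap, path: str | Path) -> Path:
    """Write the classification map as a lossless paletted PNG."""
    return write_map(cmap.image, dict(cmap.legend), path)


def map_table(predictions: Mapping[int, int], truth: Mapping[int, int] | None = None) -> pd.DataFrame:
    rows = []
    for label in sorted(predictions):
        row = {"roi_label": label, "predicted_class": int(predictions[label])}
        if truth is not None:
            row["true_class"] = int(truth[label])
            row["correct"] = int(row["predicted_class"] == row["true_class"])
        rows.append(row)
    return pd.DataFrame(rows)


def render_score_image(score: np.ndarray, path: str | Path, title: str = "") -> Path:
    """Render one PC score image with a signed colour scale and stated range."""
    vmax = float(np.max(np.abs(score))) or 1.0
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(score, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_title(f"{title} (range ±{vmax:.3g})".strip())
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
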