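"""Hierarchical analysis: anatomical layer segmentation and the layer veto.

Ganglion cells occur only in the submucosa and muscularis propria.  This
module segments a colon-wall image into its layers and vetoes every
candidate located anywhere else — surface epithelium, mucosa, serosa or
background.  Anything resembling a ganglion cell in those layers must be
read as negative, which removes the overwhelming majority of false alarms
before any morphological scoring happens.

Segmentation is a nearest-centroid classification of smoothed stain
concentrations against the per-layer H&E palette, followed by a per-row
majority vote: colon-wall layers are laminar, so a row of tissue belongs to
a single layer.  The contract is the pixel-agreement property on synthetic
slides, not a particular operator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .config import LAYER_BY_NAME, LAYER_LEGEND, LAYER_PALETTE, PERMISSIBLE_LAYERS
from .stains import separate_stains

#: Smoothed concentrations below this (both stains) are unstained background.
_BACKGROUND_OD = 0.08


@dataclass
class LayerMap:
    """Per-pixel anatomical layer labels for one slide."""

    labels: np.ndarray  # (H, W) uint8
    legend: dict[int, str] = field(default_factory=lambda: dict(LAYER_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        bad = set(np.unique(self.labels)) - set(self.legend)
        if bad:
            raise ValueError(f"labels outside the legend: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_at(self, x: int, y: int) -> int:
        h, w = self.labels.shape
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(
                f"point ({x}, {y}) outside image bounds {w}x{h}"
            )
        return int(self.labels[int(y), int(x)])

    def layer_name_at(self, x: int, y: int) -> str:
        return self.legend[self.label_at(x, y)]

    def fraction(self, layer: str) -> float:
        """Fraction of pixels carrying the named layer label."""
        return float(np.mean(self.labels == LAYER_BY_NAME[layer]))

    # -- persistence: single-channel TIFF plus a JSON legend sidecar ------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.labels, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".legend.json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in self.legend.items()},
                       indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, path: str | Path) -> "LayerMap":
        path = Path(path)
        labels = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".legend.json")
        legend = {int(k): v for k, v in
                  json.loads(sidecar.read_text()).items()}
        return cls(labels=labels, legend=legend)


def segment_layers(image: np.ndarray, channels=None) -> LayerMap:
    """Segment a colon-wall RGB image into anatomical layers.

    Returns a full-coverage :class:`LayerMap`.  An image with no detectable
    tissue yields an all-background map and a warning rather than an error.
    ``channels`` may carry pre-computed stain channels for the same image.
    """
    if channels is None:
        channels = separate_stains(image)
    h = ndimage.gaussian_filter(channels.hematoxylin, 2.0)
    e = ndimage.gaussian_filter(channels.eosin, 2.0)

    tissue = (h > _BACKGROUND_OD) | (e > _BACKGROUND_OD)
    if not tissue.any():
        warnings.warn("no tissue detected; returning an all-background map",
                      stacklevel=2)
        return LayerMap(np.zeros(image.shape[:2], dtype=np.uint8))

    # nearest palette centroid in (hematoxylin, eosin) space, incremental
    # argmin to avoid a (H, W, n_classes) intermediate
    names = list(LAYER_PALETTE)
    h32, e32 = h.astype(np.float32), e.astype(np.float32)
    best = np.full(h.shape, np.inf, dtype=np.float32)
    labels = np.zeros(h.shape, dtype=np.uint8)
    for name in names:
        hv, ev = LAYER_PALETTE[name]
        d2 = (h32 - np.float32(hv)) ** 2 + (e32 - np.float32(ev)) ** 2
        closer = d2 < best
        best[closer] = d2[closer]
        labels[closer] = LAYER_BY_NAME[name]
    labels[~tissue] = 0

    # Laminar prior: one layer per tissue row (majority vote), then a short
    # median filter across rows to remove stray single-row flips.
    row_label = np.zeros(labels.shape[0], dtype=np.uint8)
    for i in range(labels.shape[0]):
        row = labels[i][tissue[i]]
        if row.size:
            row_label[i] = np.bincount(row, minlength=6)[1:].argmax() + 1
    occupied = row_label > 0
    if occupied.any():
        smoothed = ndimage.median_filter(row_label, size=9, mode="nearest")
        row_label[occupied] = smoothed[occupied]
    out = np.where(tissue, row_label[:, None], 0).astype(np.uint8)
    return LayerMap(out)


def layer_agreement(predicted: LayerMap, truth: LayerMap) -> float:
    """Pixel-wise agreement between two layer maps of equal shape."""
    if predicted.shape != truth.shape:
        raise ValueError("layer maps differ in shape")
    return float(np.mean(predicted.labels == truth.labels))


def is_permissible_location(
    point: Sequence[float], layers: LayerMap
) -> bool:
    """True iff the (x, y) pixel lies in submucosa or muscularis propria."""
    x, y = point
    return layers.label_at(int(x), int(y)) in PERMISSIBLE_LAYERS


def hierarchical_filter(candidates: list, layers: LayerMap) -> list:
    """Veto candidates outside the permissible layers.

    Returns exactly the input candidates whose centroid lies in submucosa
    or muscularis, in their original order, with each survivor's ``layer``
    field set to its layer name.  Idempotent.
    """
    kept = []
    for cand in candidates:
        x, y = cand.centroid
        label = layers.label_at(int(x), int(y))
        cand.layer = layers.legend[label]
        if label in PERMISSIBLE_LAYERS:
            kept.append(cand)
    return kept
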