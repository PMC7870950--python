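"""Candidate ganglion-cell detection and base scoring.

A whole slide offers on the order of 10^7 pixel positions that could host a
ganglion cell, so detection is staged: dark-nucleus seeds are picked on the
smoothed hematoxylin channel, seeds outside the permissible layers are
vetoed immediately (equivalent to, and cheaper than, filtering afterwards),
four morphology features are measured in a ~100x100 px patch around each
surviving seed, and a fixed monotone logistic map turns the features into a
base score in [0, 1].  Non-maximum suppression keeps one candidate per
soma.  The detector is classical and fully deterministic: no trained
weights, every constant is in :class:`ganglionhca.config.DetectorParams`.

Features (all clipped to [0, 1]):

* ``nucleus_area`` — fraction of the patch core covered by pale-nucleus
  texture (weak hematoxylin, very weak eosin): the large vesicular nucleus
  of a mature ganglion cell.
* ``nucleolus_prominence`` — centre-versus-surround hematoxylin contrast at
  two scales: a prominent nucleolus inside a pale nucleus, or the compact
  dark nucleus of an immature ganglion cell.
* ``cytoplasm_abundance`` — fraction of the patch annulus covered by
  strongly eosinophilic, moderately basophilic cytoplasm.
* ``stain_ratio`` — stained fraction of the patch (penalises patches
  dominated by empty lumen or background).

The base score is monotone nondecreasing in every feature.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .config import FEATURE_NAMES, DetectorParams
from .stains import StainChannels, separate_stains
from .tissue_hierarchy import LayerMap, hierarchical_filter, is_permissible_location


@dataclass
class Candidate:
    """One putative ganglion cell."""

    centroid: tuple[float, float]            # (x, y), pixel coordinates
    patch_box: tuple[int, int, int, int]     # (x0, y0, x1, y1), half-open
    base_score: float
    contextual_score: float
    layer: str | None = None
    features: dict[str, float] = field(default_factory=dict)
    slide_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_score <= 1.0:
            raise ValueError("base_score must be in [0, 1]")
        if not 0.0 <= self.contextual_score <= 1.0:
            raise ValueError("contextual_score must be in [0, 1]")
        x0, y0, x1, y1 = self.patch_box
        x, y = self.centroid
        if not (x0 <= x <= x1 and y0 <= y <= y1):
            raise ValueError("patch_box must contain the centroid")


def score_candidate(
    features: Mapping[str, float], params: DetectorParams | None = None
) -> float:
    """Map the four morphology features to a base score in [0, 1].

    A fixed logistic over a positively weighted feature sum; monotone
    nondecreasing in every feature.  Raises on NaN or missing features.
    """
    params = params or DetectorParams()
    vals = []
    for name in FEATURE_NAMES:
        if name not in features:
            raise ValueError(f"missing feature {name!r}")
        v = float(features[name])
        if not math.isfinite(v):
            raise ValueError(f"feature {name!r} is not finite: {v}")
        vals.append(v)
    na, np_, ca, sr = vals
    z = (params.w_nucleus_area * na
         + params.w_nucleolus_prominence * np_
         + params.w_cytoplasm_abundance * ca
         + params.w_stain_ratio * sr
         + params.bias)
    return float(1.0 / (1.0 + math.exp(-z)))


# --------------------------------------------------------------------------
# feature measurement
# --------------------------------------------------------------------------

def _ring_means(
    grid: np.ndarray, x: int, y: int, r_in: float, r_out: float
) -> float:
    """Mean of ``grid`` over the annulus r_in < r <= r_out around (x, y)."""
    h, w = grid.shape
    r = int(math.ceil(r_out))
    x0, x1 = max(x - r, 0), min(x + r + 1, w)
    y0, y1 = max(y - r, 0), min(y + r + 1, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    mask = (d2 > r_in**2) & (d2 <= r_out**2)
    if not mask.any():
        return 0.0
    return float(grid[y0:y1, x0:x1][mask].mean())


def extract_features(
    channels: StainChannels, x: int, y: int, patch_size: int = 100
) -> dict[str, float]:
    """Measure the four morphology features around a seed position."""
    ch, ce = channels.hematoxylin, channels.eosin
    h, w = ch.shape
    half = patch_size // 2
    x0, x1 = max(x - half, 0), min(x + half, w)
    y0, y1 = max(y - half, 0), min(y + half, h)
    pch = ch[y0:y1, x0:x1]
    pce = ce[y0:y1, x0:x1]

    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - x, yy - y)

    # pale vesicular nucleus: weak hematoxylin, very weak eosin, near centre
    pale = (pch > 0.18) & (pch < 0.45) & (pce < 0.25) & (d <= 40.0)
    nucleus_area = min(float(pale.sum()) / (0.25 * math.pi * 40.0**2), 1.0)

    # centre-vs-surround hematoxylin contrast at nucleolus and
    # immature-nucleus scales
    c_small = _ring_means(ch, x, y, -1.0, 6.0) - _ring_means(ch, x, y, 10.0, 20.0)
    c_large = _ring_means(ch, x, y, -1.0, 12.0) - _ring_means(ch, x, y, 18.0, 30.0)
    nucleolus_prominence = float(np.clip(max(c_small, c_large) / 0.8, 0.0, 1.0))

    # abundant cytoplasm: strongly eosinophilic, moderately basophilic ring
    ring = (d > 12.0) & (d <= 45.0)
    if ring.any():
        cyto = (pce > 0.55) & (pch > 0.40) & (pch < 0.70) & ring
        cytoplasm_abundance = float(
            np.clip(cyto.sum() / ring.sum() / 0.6, 0.0, 1.0)
        )
    else:
        cytoplasm_abundance = 0.0

    stain_ratio = float(np.mean((pch + pce) > 0.30)) if pch.size else 0.0

    return {
        "nucleus_area": nucleus_area,
        "nucleolus_prominence": nucleolus_prominence,
        "cytoplasm_abundance": cytoplasm_abundance,
        "stain_ratio": stain_ratio,
    }


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _clipped_box(
    x: int, y: int, size: int, width: int, height: int
) -> tuple[int, int, int, int]:
    half = size // 2
    return (max(x - half, 0), max(y - half, 0),
            min(x + half, width), min(y + half, height))


def detect_candidates(
    image: np.ndarray,
    layers: LayerMap,
    params: DetectorParams | None = None,
    channels: StainChannels | None = None,
) -> list[Candidate]:
    """Detect putative ganglion cells on one slide.

    Returns candidates sorted by base score (descending; ties broken by
    y then x ascending), already restricted to the permissible layers.
    Deterministic for a fixed input; an empty list is a valid result.
    ``channels`` may carry pre-computed stain channels for the same image.
    """
    params = params or DetectorParams()
    if channels is None:
        channels = separate_stains(image)
    height, width = channels.shape

    smoothed = ndimage.gaussian_filter(channels.hematoxylin,
                                       params.blob_sigma)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.peak_min_distance,
        threshold_abs=params.peak_threshold,
        exclude_border=False,
    )

    scored: list[Candidate] = []
    for py, px in peaks:
        x, y = int(px), int(py)
        # layer veto up front: identical outcome to filtering afterwards,
        # but skips feature extraction on the (many) vetoed seeds
        if not is_permissible_location((x, y), layers):
            continue
        feats = extract_features(channels, x, y, params.patch_size)
        score = score_candidate(feats, params)
        if score < params.min_base_score:
            continue
        scored.append(
            Candidate(
                centroid=(float(x), float(y)),
                patch_box=_clipped_box(x, y, params.patch_size,
                                       width, height),
                base_score=score,
                contextual_score=score,
                features=feats,
            )
        )

    scored.sort(key=lambda c: (-c.base_score, c.centroid[1], c.centroid[0]))

    # non-maximum suppression: one candidate per soma
    kept: list[Candidate] = []
    for cand in scored:
        cx, cy = cand.centroid
        if all(
            math.hypot(cx - k.centroid[0], cy - k.centroid[1])
            > params.nms_radius
            for k in kept
        ):
            kept.append(cand)

    return hierarchical_filter(kept, layers)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

_CSV_FIELDS = ("case_id", "slide_id", "x", "y", "x0", "y0", "x1", "y1",
               "base_score", "contextual_score", "layer")


def write_candidates_csv(
    candidates: list[Candidate], path: str | Path, case_id: str = ""
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for c in candidates:
            writer.writerow(
                [case_id, c.slide_id or "", f"{c.centroid[0]:.1f}",
                 f"{c.centroid[1]:.1f}", *c.patch_box,
                 f"{c.base_score:.6f}", f"{c.contextual_score:.6f}",
                 c.layer or ""]
            )


def read_candidates_csv(path: str | Path) -> list[Candidate]:
    out: list[Candidate] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Candidate(
                    centroid=(float(row["x"]), float(row["y"])),
                    patch_box=(int(row["x0"]), int(row["y0"]),
                               int(row["x1"]), int(row["y1"])),
                    base_score=float(row["base_score"]),
                    contextual_score=float(row["contextual_score"]),
                    layer=row["layer"] or None,
                    slide_id=row["slide_id"] or None,
                )
            )
    return out
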