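"""Shared constants and run configuration.

Everything tunable in the pipeline lives here: the anatomical layer legend,
the fixed two-stain H&E optical-density model, detector and contextual
parameters, triage constants and the decision thresholds.  The triage and
decision constants (36 images, sets of 3, up to 12 sets, score-5 rules,
0.6 doubt threshold) are the fixed operating points of the assisted
diagnostic workflow and are not meant to be changed between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

# --------------------------------------------------------------------------
# Anatomical layers
# --------------------------------------------------------------------------

#: Integer labels of the colon-wall layers, from lumen outward.
LAYER_LEGEND: dict[int, str] = {
    0: "background",
    1: "epithelium",
    2: "mucosa",
    3: "submucosa",
    4: "muscularis",
    5: "serosa",
}
LAYER_BY_NAME: dict[str, int] = {v: k for k, v in LAYER_LEGEND.items()}

#: Ganglion cells occur only in the submucosal and myenteric plexuses, i.e.
#: in the submucosa or muscularis propria; every other layer is a veto.
PERMISSIBLE_LAYERS: frozenset[int] = frozenset(
    {LAYER_BY_NAME["submucosa"], LAYER_BY_NAME["muscularis"]}
)

# --------------------------------------------------------------------------
# H&E stain model
# --------------------------------------------------------------------------

def _unit_rows(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=1, keepdims=True)

#: Optical-density unit vectors (rows: hematoxylin, eosin) in RGB space.
#: Standard H&E absorption directions; the synthetic renderer composes
#: images with exactly this matrix, so unmixing against it is exact up to
#: quantization and injected noise.
STAIN_OD_MATRIX: np.ndarray = _unit_rows(
    np.array(
        [
            [0.650, 0.704, 0.286],  # hematoxylin
            [0.072, 0.990, 0.105],  # eosin
        ]
    )
)

#: Unit vector orthogonal to both stain vectors (the residual direction).
STAIN_RESIDUAL_VECTOR: np.ndarray = (
    lambda v: v / np.linalg.norm(v)
)(np.cross(STAIN_OD_MATRIX[0], STAIN_OD_MATRIX[1]))

#: Per-layer mean stain concentrations (hematoxylin, eosin) used both by the
#: renderer and as class centroids by the layer segmenter.
LAYER_PALETTE: dict[str, tuple[float, float]] = {
    "background": (0.0, 0.0),
    "epithelium": (0.90, 0.30),
    "mucosa": (0.45, 0.50),
    "submucosa": (0.15, 0.35),
    "muscularis": (0.30, 0.85),
    "serosa": (0.20, 0.15),
}

# --------------------------------------------------------------------------
# Detector
# --------------------------------------------------------------------------

@dataclass
class DetectorParams:
    """Parameters of the classical blob + hand-crafted-feature detector."""

    #: Gaussian smoothing scale (px) applied to the hematoxylin channel
    #: before peak picking; responds to nucleoli (~5 px radius) through
    #: immature-ganglion nuclei (~15 px radius).
    blob_sigma: float = 3.0
    #: Minimum smoothed hematoxylin density at a seed peak.
    peak_threshold: float = 0.45
    #: Minimum seed separation (px) during peak picking.
    peak_min_distance: int = 15
    #: Side of the square patch analysed around each seed, px.  A mature
    #: ganglion soma spans roughly 100 px at the reference magnification.
    patch_size: int = 100
    #: Non-maximum suppression radius: one candidate per soma.
    nms_radius: float = 50.0
    #: Candidates scoring below this are not emitted at all.
    min_base_score: float = 0.2
    #: Logistic weights of the base score over the four morphology features.
    w_nucleus_area: float = 3.0
    w_nucleolus_prominence: float = 2.5
    w_cytoplasm_abundance: float = 2.5
    w_stain_ratio: float = 1.5
    bias: float = -4.2


#: Feature order used throughout scoring.
FEATURE_NAMES: tuple[str, ...] = (
    "nucleus_area",
    "nucleolus_prominence",
    "cytoplasm_abundance",
    "stain_ratio",
)

# --------------------------------------------------------------------------
# Contextual analysis
# --------------------------------------------------------------------------

@dataclass
class ContextualParams:
    """Parameters of the contextual re-scoring feedback loop."""

    #: Single-linkage clustering radius, px (a few soma diameters).
    radius_px: float = 300.0
    #: Candidates whose contextual score falls below this are pruned.
    floor_score: float = 0.05
    #: Maximum rescore-and-prune iterations before declaring convergence.
    max_iters: int = 10
    #: Bonus weights: clustering, companion (Schwann-like) texture,
    #: vessel proximity.
    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.2
    #: Annulus (px) around a candidate inspected for companion texture.
    companion_r_inner: float = 60.0
    companion_r_outer: float = 160.0
    #: Companion texture fraction that saturates the companion bonus.
    companion_saturation: float = 0.005
    #: Distance decay constant (px) of the vessel-proximity bonus.
    vessel_decay_px: float = 150.0


# --------------------------------------------------------------------------
# Triage and decision rules
# --------------------------------------------------------------------------

@dataclass
class TriageParams:
    """How scored candidates become the image sets a pathologist reviews."""

    top_k: int = 36          # images kept per case, highest scores first
    set_size: int = 3        # images per set
    max_sets: int = 12       # sets per case
    patch_margin: int = 25   # context margin (px) around the candidate box


@dataclass
class DecisionParams:
    """Classification thresholds of the triage workflow."""

    #: Pathologist score meaning "ganglion cells seen (certain)".
    certain_score: int = 5
    #: Number of certain sets required for a non-expert Positive.
    nonexpert_positive_sets: int = 2
    #: Average-AI-score boundary between Negative and Doubt (inclusive on
    #: the Doubt side).
    doubt_threshold: float = 0.6
    #: Decoy locations sampled per truth cell for cell-level specificity.
    decoys_per_cell: int = 10


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full configuration of a reproducible pipeline run.

    Round-trips losslessly through YAML; :meth:`config_hash` is embedded in
    every output manifest so results can be traced to their configuration.
    """

    seed: int = 0
    log_level: str = "INFO"
    # cohort generation
    n_cases: int = 8
    hscr_fraction: float = 0.4
    inadequate_fraction: float = 0.1
    slide_width: int = 1664
    slide_height: int = 1280
    n_mature_ganglia: int = 8
    n_immature_ganglia: int = 3
    n_mimics: int = 12
    noise_level: float = 0.05
    detector: DetectorParams = field(default_factory=DetectorParams)
    contextual: ContextualParams = field(default_factory=ContextualParams)
    triage: TriageParams = field(default_factory=TriageParams)
    decision: DecisionParams = field(default_factory=DecisionParams)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("detector", DetectorParams),
            ("contextual", ContextualParams),
            ("triage", TriageParams),
            ("decision", DecisionParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form (first 12 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def __post_init__(self) -> None:
        if not 0.0 <= self.hscr_fraction <= 1.0:
            raise ValueError("hscr_fraction must be in [0, 1]")
        if not 0.0 <= self.inadequate_fraction <= 1.0:
            raise ValueError("inadequate_fraction must be in [0, 1]")
        if self.hscr_fraction + self.inadequate_fraction > 1.0:
            raise ValueError("hscr_fraction + inadequate_fraction must be <= 1")
        if not 0.0 <= self.decision.doubt_threshold <= 1.0:
            raise ValueError("doubt_threshold must be in [0, 1]")
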