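"""Contextual analysis: neighbourhood-driven re-scoring with feedback.

A ganglion cell rarely stands alone: it appears in clusters, accompanied by
Schwann cells, close to blood vessels.  This stage measures that context
for every hierarchically filtered candidate and folds it into the score,

    contextual = clip(base * (1 + a*cluster + b*companion + g*vessel), 0, 1),

then prunes candidates whose contextual score falls below a floor and
repeats — pruning changes the cluster structure, which changes the
context — until a fixed point.  Pruning is monotone (candidates only ever
leave), so the loop provably terminates; scores of survivors depend only on
the surviving set, so re-running on the output changes nothing.

The companion and vessel detectors are simple texture/lumen heuristics
calibrated against the synthetic renderer's morphology; they are fixtures
of this artifact, not biologically validated operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from scipy.sparse import csr_matrix

from .candidate_detection import Candidate
from .config import ContextualParams, PERMISSIBLE_LAYERS
from .stains import separate_stains
from .tissue_hierarchy import LayerMap


@dataclass
class ContextFeatures:
    """Neighbourhood evidence for one candidate."""

    cluster_size: int          # candidates reachable within the radius
    companion_density: float   # Schwann-like texture fraction, [0, 1]
    vessel_proximity: float    # distance-decayed vessel presence, [0, 1]

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError(
                "cluster_size must be >= 1: a candidate is in its own cluster"
            )


def cluster_candidates(
    candidates: list[Candidate], radius_px: float
) -> list[list[Candidate]]:
    """Single-linkage grouping of candidates by centroid distance.

    Two candidates share a cluster iff a chain of pairwise centroid
    distances <= ``radius_px`` connects them.  The returned partition
    covers every candidate exactly once; clusters are ordered by their
    first member's input position, members keep input order.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    n = len(candidates)
    if n == 0:
        return []
    pts = np.array([c.centroid for c in candidates])
    adj = squareform(pdist(pts)) <= radius_px
    _, comp = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, list[Candidate]] = {}
    order: list[int] = []
    for cand, label in zip(candidates, comp):
        if label not in clusters:
            clusters[label] = []
            order.append(label)
        clusters[label].append(cand)
    return [clusters[label] for label in order]


# --------------------------------------------------------------------------
# context measurement
# --------------------------------------------------------------------------

def _vessel_lumen_centroids(
    channels, layers: LayerMap
) -> np.ndarray:
    """Centroids (x, y) of vessel-lumen-like components in permissible
    tissue: nearly unstained patches of plausible lumen size."""
    lumen = (channels.hematoxylin < 0.07) & (channels.eosin < 0.12)
    permissible = np.isin(layers.labels, list(PERMISSIBLE_LAYERS))
    lumen &= permissible
    labelled, n = ndimage.label(lumen)
    if n == 0:
        return np.empty((0, 2))
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled,
                               index=np.arange(1, n + 1))
    keep = np.flatnonzero((sizes >= 120) & (sizes <= 5000)) + 1
    if keep.size == 0:
        return np.empty((0, 2))
    cys, cxs = zip(*ndimage.center_of_mass(lumen, labelled, keep))
    return np.array([(x, y) for x, y in zip(cxs, cys)])


def compute_context_features(
    candidates: list[Candidate],
    image: np.ndarray,
    layers: LayerMap,
    params: ContextualParams | None = None,
    _channels=None,
) -> list[ContextFeatures]:
    """Measure cluster size, companion texture and vessel proximity."""
    params = params or ContextualParams()
    if not candidates:
        return []
    channels = _channels if _channels is not None else separate_stains(image)
    lumens = _vessel_lumen_centroids(channels, layers)

    clusters = cluster_candidates(candidates, params.radius_px)
    size_of: dict[int, int] = {}
    for cluster in clusters:
        for cand in cluster:
            size_of[id(cand)] = len(cluster)

    ch, ce = channels.hematoxylin, channels.eosin
    h, w = ch.shape
    out: list[ContextFeatures] = []
    for cand in candidates:
        x, y = cand.centroid
        xi, yi = int(x), int(y)
        r = int(params.companion_r_outer)
        x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
        y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - xi, yy - yi)
        annulus = (d > params.companion_r_inner) & (d <= params.companion_r_outer)
        if annulus.any():
            # Schwann-like texture: hematoxylin-dense, not eosinophilic soma
            companion = ((ch[y0:y1, x0:x1] > 0.55)
                         & (ce[y0:y1, x0:x1] < 0.55) & annulus)
            density = float(companion.sum() / annulus.sum())
        else:
            density = 0.0
        if lumens.size:
            dmin = float(np.min(np.hypot(lumens[:, 0] - x, lumens[:, 1] - y)))
            vessel = math.exp(-dmin / params.vessel_decay_px)
        else:
            vessel = 0.0
        out.append(
            ContextFeatures(
                cluster_size=size_of[id(cand)],
                companion_density=density,
                vessel_proximity=vessel,
            )
        )
    return out


def _bonus_score(
    base: float, feats: ContextFeatures, params: ContextualParams
) -> float:
    cluster_bonus = min((feats.cluster_size - 1) / 3.0, 1.0)
    companion_bonus = min(feats.companion_density / params.companion_saturation,
                          1.0)
    vessel_bonus = feats.vessel_proximity
    raw = base * (1.0 + params.alpha * cluster_bonus
                  + params.beta * companion_bonus
                  + params.gamma * vessel_bonus)
    return float(np.clip(raw, 0.0, 1.0))


def contextual_rescore(
    candidates: list[Candidate],
    image: np.ndarray,
    layers: LayerMap,
    max_iters: int | None = None,
    params: ContextualParams | None = None,
    channels=None,
) -> list[Candidate]:
    """Iteratively re-score and prune candidates to a fixed point.

    Candidates must already be hierarchically filtered.  Returns the
    surviving candidates in input order with ``contextual_score`` updated;
    a candidate in a supportive context never scores below an identical
    candidate in isolation.
    """
    params = params or ContextualParams()
    if max_iters is None:
        max_iters = params.max_iters
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    if not candidates:
        return []

    if channels is None:
        channels = separate_stains(image)
    alive = list(candidates)
    for _ in range(max_iters):
        feats = compute_context_features(
            alive, image, layers, params, _channels=channels
        )
        for cand, f in zip(alive, feats):
            cand.contextual_score = _bonus_score(cand.base_score, f, params)
        survivors = [c for c in alive
                     if c.contextual_score >= params.floor_score]
        if len(survivors) == len(alive):
            break
        alive = survivors
        if not alive:
            break
    return alive
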