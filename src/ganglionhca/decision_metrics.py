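"""Decision rules, consultation routing and cohort statistics.

The classification criteria are applied verbatim:

* Expert rule — one set scored 5 ("ganglion cells seen, certain") makes the
  case Positive (non-HSCR); otherwise Negative (HSCR).  Never Doubt.
* Non-expert rule — two or more sets scored 5 make the case Positive;
  otherwise the case is Negative if the case's average AI score is < 0.6
  and Doubt if it is >= 0.6 (boundary inclusive on the Doubt side).  Doubt
  routes the case to expert consultation.

The rules are deliberately conservative: they over-refer rather than let a
non-expert finalise a high-AI-score case as Negative.  The known failure
mode — a non-expert wrongly scoring two sets as 5 yields a Positive that
is never referred — is inherent to the rule itself and reproduced
as-is.

Cell-level metrics follow the encircling-annotation convention: a truth
cell counts as detected when at least one detection centroid falls inside
its polygon (several detections in one polygon count once).  Specificity
needs a negative unit the cell-by-cell convention leaves implicit; here
it is a
set of decoy locations sampled uniformly in ganglion-free permissible
tissue, a decoy being correctly rejected when no detection centroid falls
within its patch-sized box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .annotations import AnnotationSet
from .candidate_detection import Candidate
from .config import PERMISSIBLE_LAYERS, DecisionParams
from .tissue_hierarchy import LayerMap

POSITIVE = "Positive"
NEGATIVE = "Negative"
DOUBT = "Doubt"


@dataclass
class Classification:
    """A case label with a structured account of the rule that fired."""

    label: str
    basis: dict = field(default_factory=dict)

    @property
    def needs_consultation(self) -> bool:
        return self.label == DOUBT


def _validate_scores(set_scores: Sequence[int]) -> list[int]:
    scores = [int(s) for s in set_scores]
    for i, s in enumerate(scores):
        if not 1 <= s <= 5:
            raise ValueError(f"set score {s} at rank {i + 1} outside 1..5")
    return scores


def classify_expert(set_scores: Sequence[int],
                    params: DecisionParams | None = None) -> Classification:
    """Expert rule: a single certain set (score 5) makes the case Positive."""
    params = params or DecisionParams()
    scores = _validate_scores(set_scores)
    if not scores:
        return Classification(
            NEGATIVE,
            {"rule": "expert", "reason": "no image sets, nothing seen"},
        )
    certain = [i + 1 for i, s in enumerate(scores)
               if s == params.certain_score]
    if certain:
        return Classification(
            POSITIVE, {"rule": "expert", "certain_sets": certain}
        )
    return Classification(
        NEGATIVE, {"rule": "expert", "max_score": max(scores)}
    )


def classify_nonexpert(
    set_scores: Sequence[int],
    avg_top3_ai: float,
    params: DecisionParams | None = None,
) -> Classification:
    """Non-expert rule: two certain sets => Positive; otherwise the average
    AI score decides between Negative (< 0.6) and Doubt (>= 0.6)."""
    params = params or DecisionParams()
    scores = _validate_scores(set_scores)
    if not 0.0 <= avg_top3_ai <= 1.0:
        raise ValueError("avg_top3_ai must be in [0, 1]")
    certain = [i + 1 for i, s in enumerate(scores)
               if s == params.certain_score]
    basis: dict = {"rule": "nonexpert", "certain_sets": certain,
                   "avg_top3_ai": avg_top3_ai}
    if not scores:
        basis["reason"] = "no image sets, nothing seen"
    if len(certain) >= params.nonexpert_positive_sets:
        return Classification(POSITIVE, basis)
    if avg_top3_ai < params.doubt_threshold:
        return Classification(NEGATIVE, basis)
    return Classification(DOUBT, basis)


def resolve_consultations(
    nonexpert_labels: Mapping[str, Classification],
    expert_labels: Mapping[str, Classification],
) -> dict[str, Classification]:
    """Replace every Doubt by the expert's label; other labels pass through.

    A Doubt case without an expert label is an error (the consultation
    cannot be resolved)."""
    missing = [cid for cid, c in nonexpert_labels.items()
               if c.label == DOUBT and cid not in expert_labels]
    if missing:
        raise ValueError(
            "Doubt cases lack an expert label: " + ", ".join(sorted(missing))
        )
    out: dict[str, Classification] = {}
    for cid, c in nonexpert_labels.items():
        if c.label == DOUBT:
            expert = expert_labels[cid]
            out[cid] = Classification(
                expert.label,
                {"rule": "consultation", "nonexpert": c.basis,
                 "expert": expert.basis},
            )
        else:
            out[cid] = c
    return out


# --------------------------------------------------------------------------
# cell-level metrics
# --------------------------------------------------------------------------

def ganglion_free_regions(
    layers: LayerMap, truth: AnnotationSet, margin: float = 100.0
):
    """Permissible-layer area with a margin around every annotated object
    removed: the territory where a detection is a false alarm."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    h, w = layers.shape
    rows = np.isin(layers.labels, list(PERMISSIBLE_LAYERS)).any(axis=1)
    bands = []
    y = 0
    while y < h:
        if rows[y]:
            y0 = y
            while y < h and rows[y]:
                y += 1
            bands.append(box(0, y0, w, y))
        else:
            y += 1
    if not bands:
        return None
    region = unary_union(bands)
    blockers = [a.polygon.buffer(margin) for a in truth]
    if blockers:
        region = region.difference(unary_union(blockers))
    return None if region.is_empty else region


def _sample_in_region(region, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = region.bounds
    prepared = prep(region)
    pts: list[tuple[float, float]] = []
    # rejection sampling; region covers a large share of its bounds here
    for _ in range(200 * n):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if prepared.contains(Point(x, y)):
            pts.append((x, y))
            if len(pts) == n:
                break
    return np.array(pts)


@dataclass
class CellMetrics:
    sensitivity: float | None     # percent; None when no truth cells exist
    specificity: float | None     # percent; None when no decoys sampled
    n_truth: int
    n_detected: int
    n_decoys: int
    n_rejected: int


def cell_level_metrics(
    detections: list[Candidate],
    truth: AnnotationSet,
    negative_regions=None,
    n_decoys: int | None = None,
    decoy_box: float = 100.0,
    seed: int = 0,
    params: DecisionParams | None = None,
) -> CellMetrics:
    """Cell-by-cell sensitivity and specificity, in percent.

    Sensitivity counts a truth ganglion polygon as detected iff at least
    one detection centroid lies inside it.  Specificity is computed over
    decoy locations sampled uniformly in ``negative_regions`` (default:
    10 decoys per truth cell); a decoy is correctly rejected iff no
    detection centroid falls inside the ``decoy_box`` around it.
    """
    params = params or DecisionParams()
    cells = truth.ganglia
    pts = [Point(c.centroid) for c in detections]

    n_detected = 0
    for cell in cells:
        poly = cell.polygon
        if any(poly.covers(p) for p in pts):
            n_detected += 1
    sensitivity = (100.0 * n_detected / len(cells)) if len(cells) else None

    n_sampled = n_rejected = 0
    specificity = None
    if negative_regions is not None:
        if n_decoys is None:
            n_decoys = max(params.decoys_per_cell * len(cells), 50)
        rng = np.random.default_rng(seed)
        decoys = _sample_in_region(negative_regions, n_decoys, rng)
        n_sampled = len(decoys)
        half = decoy_box / 2.0
        centroids = np.array([c.centroid for c in detections]).reshape(-1, 2)
        for x, y in decoys:
            inside = (
                (np.abs(centroids[:, 0] - x) <= half)
                & (np.abs(centroids[:, 1] - y) <= half)
            ).any() if len(centroids) else False
            if not inside:
                n_rejected += 1
        specificity = (100.0 * n_rejected / n_sampled) if n_sampled else None

    return CellMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        n_truth=len(cells),
        n_detected=n_detected,
        n_decoys=n_sampled,
        n_rejected=n_rejected,
    )


# --------------------------------------------------------------------------
# consultation statistics
# --------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Consultation counts and rates over a cohort.

    Every rate is ``100 * count / denominator`` with the denominator
    reported explicitly alongside it.
    """

    n_cases: int
    observers: list[str]
    per_observer: dict[str, dict]      # observer -> {count, denominator, rate}
    cross_observer: dict[int, dict]    # k -> {count, denominator, pct}
    per_observer_errors: dict[str, int] = field(default_factory=dict)
    cell_metrics: CellMetrics | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_cases": self.n_cases,
            "observers": self.observers,
            "per_observer": self.per_observer,
            "cross_observer": {str(k): v
                               for k, v in self.cross_observer.items()},
            "per_observer_errors": self.per_observer_errors,
        }
        if self.cell_metrics is not None:
            d["cell_metrics"] = vars(self.cell_metrics)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "key", "count", "denominator", "value"])
            for obs, d in self.per_observer.items():
                w.writerow(["consultation_rate", obs, d["count"],
                            d["denominator"], d["rate"]])
            for k, d in self.cross_observer.items():
                w.writerow(["consulting_observers", k, d["count"],
                            d["denominator"], d["pct"]])


def consultation_statistics(
    flags: Mapping[str, Mapping[str, bool]]
) -> CohortReport:
    """Summarise needs-consultation flags: per-observer counts/rates and
    the exact-k cross-observer distribution (k = 0..n_observers).

    ``flags`` maps observer -> case_id -> flag; all observers must cover
    the same case set.  Percentages are rounded to 2 decimals.
    """
    observers = list(flags)
    if not observers:
        raise ValueError("no observers")
    case_sets = {obs: frozenset(flags[obs]) for obs in observers}
    reference = case_sets[observers[0]]
    for obs, cs in case_sets.items():
        if cs != reference:
            raise ValueError(
                f"observer {obs!r} covers a different case set than "
                f"{observers[0]!r}"
            )
    cases = sorted(reference)
    n = len(cases)

    per_observer = {
        obs: {
            "count": (count := sum(bool(flags[obs][c]) for c in cases)),
            "denominator": n,
            "rate": round(100.0 * count / n, 2) if n else 0.0,
        }
        for obs in observers
    }
    cross: dict[int, dict] = {}
    counts = [sum(bool(flags[obs][c]) for obs in observers) for c in cases]
    for k in range(len(observers) + 1):
        ck = counts.count(k)
        cross[k] = {
            "count": ck,
            "denominator": n,
            "pct": round(100.0 * ck / n, 2) if n else 0.0,
        }
    return CohortReport(
        n_cases=n,
        observers=observers,
        per_observer=per_observer,
        cross_observer=cross,
    )
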