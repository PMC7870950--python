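"""Triage: turn a case's scored candidates into ranked image sets.

All slides of a case compete in one ranking.  The 36 candidates with the
highest contextual scores are cropped (with a context margin, because a
pathologist will not judge a putative ganglion cell outside its
surroundings) and grouped, in rank order, into up to 12 sets of 3 images.
A set's score is the best of its members — a set is reviewed for *any*
ganglion cell, so its evidence is its strongest patch — and the case-level
AI score is the mean of the three highest set scores.

A trailing partial set is kept rather than dropped or padded: discarding a
candidate could hide the only ganglion cell of the case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import imageio.v3 as iio
import numpy as np

from .candidate_detection import Candidate
from .config import TriageParams


@dataclass
class ImagePatch:
    """One candidate crop shown to the pathologist."""

    case_id: str
    slide_id: str
    pixels: np.ndarray            # RGB crop: patch_box plus margin, clipped
    candidate: Candidate
    ai_score: float               # = the candidate's contextual score

    def __post_init__(self) -> None:
        if not 0.0 <= self.ai_score <= 1.0:
            raise ValueError("ai_score must be in [0, 1]")


@dataclass
class ImageSet:
    """An ordered group of (up to) 3 patches with a set-level score."""

    rank: int
    patches: list[ImagePatch]
    set_score: float


@dataclass
class CaseRecord:
    """All triage output and pathologist input for one case."""

    case_id: str
    sets: list[ImageSet]
    avg_top3_ai: float
    pathologist_scores: dict[str, list[int]] = field(default_factory=dict)
    classifications: dict[str, object] = field(default_factory=dict)


def _crop(image: np.ndarray, box: tuple[int, int, int, int],
          margin: int) -> np.ndarray:
    x0, y0, x1, y1 = box
    h, w = image.shape[:2]
    return image[max(y0 - margin, 0):min(y1 + margin, h),
                 max(x0 - margin, 0):min(x1 + margin, w)].copy()


def top_candidates(
    candidates: list[Candidate], k: int
) -> list[Candidate]:
    """The k highest-scoring candidates (stable tie-break: y, then x)."""
    ranked = sorted(
        candidates,
        key=lambda c: (-c.contextual_score, c.centroid[1], c.centroid[0]),
    )
    return ranked[:k]


def build_image_sets(
    candidates: list[Candidate],
    image_access: Callable[[str], np.ndarray] | Mapping[str, np.ndarray],
    case_id: str = "",
    params: TriageParams | None = None,
) -> list[ImageSet]:
    """Group a case's top candidates into ranked sets of patches.

    ``candidates`` may come from several slides; each must carry a
    ``slide_id`` resolvable through ``image_access``.  Returns at most
    ``max_sets`` sets ordered by rank, set scores nonincreasing.
    """
    params = params or TriageParams()
    if not candidates:
        return []
    getter = (image_access.__getitem__
              if isinstance(image_access, Mapping) else image_access)
    chosen = top_candidates(candidates, params.top_k)
    sets: list[ImageSet] = []
    for i in range(0, len(chosen), params.set_size):
        if len(sets) >= params.max_sets:
            break
        members = chosen[i:i + params.set_size]
        patches = []
        for cand in members:
            slide_id = cand.slide_id or ""
            image = np.asarray(getattr(getter(slide_id), "pixels",
                                       getter(slide_id)))
            patches.append(
                ImagePatch(
                    case_id=case_id,
                    slide_id=slide_id,
                    pixels=_crop(image, cand.patch_box, params.patch_margin),
                    candidate=cand,
                    ai_score=cand.contextual_score,
                )
            )
        sets.append(
            ImageSet(
                rank=len(sets) + 1,
                patches=patches,
                set_score=max(p.ai_score for p in patches),
            )
        )
    return sets


def case_ai_score(sets: list[ImageSet]) -> float:
    """Mean of the three highest set scores (all of them if fewer than 3;
    0 for a case with no sets)."""
    if not sets:
        return 0.0
    scores = sorted((s.set_score for s in sets), reverse=True)
    top = scores[:3]
    return float(sum(top) / len(top))


def make_case_record(case_id: str, sets: list[ImageSet]) -> CaseRecord:
    return CaseRecord(case_id=case_id, sets=sets,
                      avg_top3_ai=case_ai_score(sets))


def record_pathologist_scores(
    case: CaseRecord, observer: str, scores: list[int]
) -> CaseRecord:
    """Store one observer's per-set scores (1..5), immutably.

    Re-recording the same observer is an error (audit integrity), as is a
    score outside 1..5 or a score list whose length differs from the
    number of sets.
    """
    if observer in case.pathologist_scores:
        raise ValueError(
            f"observer {observer!r} already scored case {case.case_id!r}"
        )
    if len(scores) != len(case.sets):
        raise ValueError(
            f"expected {len(case.sets)} scores (one per set), "
            f"got {len(scores)}"
        )
    for image_set, s in zip(case.sets, scores):
        if not (isinstance(s, (int, np.integer)) and 1 <= s <= 5):
            raise ValueError(
                f"score {s!r} for set rank {image_set.rank} is outside 1..5"
            )
    case.pathologist_scores[observer] = [int(s) for s in scores]
    return case


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def export_case(
    case: CaseRecord, directory: str | Path, config_hash: str = ""
) -> Path:
    """Write a case's patches as PNGs plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "case_id": case.case_id,
        "config_hash": config_hash,
        "avg_top3_ai": round(case.avg_top3_ai, 6),
        "sets": [],
    }
    for image_set in case.sets:
        entry = {"rank": image_set.rank,
                 "set_score": round(image_set.set_score, 6),
                 "patches": []}
        for j, patch in enumerate(image_set.patches):
            name = f"set{image_set.rank:02d}_img{j + 1}.png"
            iio.imwrite(directory / name, patch.pixels)
            x, y = patch.candidate.centroid
            entry["patches"].append(
                {"file": name, "slide_id": patch.slide_id,
                 "x": x, "y": y,
                 "ai_score": round(patch.ai_score, 6),
                 "layer": patch.candidate.layer}
            )
        manifest["sets"].append(entry)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def presented_area_fraction(
    cases: list[CaseRecord], tissue_pixels: int
) -> float:
    """Total presented patch area over total tissue area, as a fraction."""
    patch_area = sum(
        p.pixels.shape[0] * p.pixels.shape[1]
        for case in cases for s in case.sets for p in s.patches
    )
    if tissue_pixels <= 0:
        raise ValueError("tissue_pixels must be positive")
    return patch_area / tissue_pixels
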