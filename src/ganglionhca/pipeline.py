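"""End-to-end orchestration: simulate, analyse, triage and evaluate.

Chains the stages — layer segmentation, candidate detection, contextual
re-scoring, triage — over cohorts on disk, with full provenance (config
hash, seed, package version) in every manifest.  The run directory layout:

    run/
      config.yaml             resolved configuration of the run
      cohort/manifest.csv     case_id, label, per-case file paths
      cohort/case_XXX/        slide.tif, layers.tif(+legend), annotations.xml
      cases/case_XXX/         candidates.csv, sets/ (PNG patches + manifest)
      classifications.jsonl   per observer x case: rule fired and inputs
      report.json / report.csv
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidate_detection import Candidate, detect_candidates, write_candidates_csv
from .config import RunConfig
from .contextual_analysis import contextual_rescore
from .decision_metrics import (
    DOUBT,
    Classification,
    classify_expert,
    classify_nonexpert,
    consultation_statistics,
    resolve_consultations,
)
from .synthetic_histology import (
    GroundTruthBundle,
    LabeledCase,
    SlideSpec,
    generate_cohort,
    read_bundle,
    write_bundle,
)
from .tissue_hierarchy import segment_layers
from .triage import (
    CaseRecord,
    build_image_sets,
    export_case,
    make_case_record,
    record_pathologist_scores,
)

log = logging.getLogger("ganglionhca")


def spec_from_config(config: RunConfig, seed: int = 0) -> SlideSpec:
    return SlideSpec(
        width_px=config.slide_width,
        height_px=config.slide_height,
        n_mature_ganglia=config.n_mature_ganglia,
        n_immature_ganglia=config.n_immature_ganglia,
        n_mimics=config.n_mimics,
        noise_level=config.noise_level,
        seed=seed,
    )


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate the configured cohort on disk; returns the manifest path."""
    out_dir = Path(out_dir)
    cohort_dir = out_dir / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    cases = generate_cohort(
        n_cases=config.n_cases,
        hscr_fraction=config.hscr_fraction,
        inadequate_fraction=config.inadequate_fraction,
        seed=config.seed,
        base_spec=spec_from_config(config),
    )
    manifest = cohort_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "path", "config_hash"])
        for case in cases:
            case_dir = cohort_dir / case.case_id
            write_bundle(case.bundle, case_dir)
            writer.writerow([case.case_id, case.label, case.case_id,
                             config.config_hash()])
            log.info("wrote %s (%s)", case.case_id, case.label)
    return manifest


def load_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    path = Path(cohort_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing cohort manifest: {path}")
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# per-case analysis
# --------------------------------------------------------------------------

@dataclass
class CaseAnalysis:
    """Everything the pipeline computed for one case."""

    record: CaseRecord
    candidates: list[Candidate]
    layers_predicted: object
    bundle: GroundTruthBundle


def analyze_bundle(
    bundle: GroundTruthBundle, config: RunConfig, case_id: str,
    slide_id: str = "slide_0",
) -> CaseAnalysis:
    """Segment, detect, contextually re-score and triage one case."""
    from .stains import separate_stains

    channels = separate_stains(bundle.image)
    layers = segment_layers(bundle.image, channels=channels)
    candidates = detect_candidates(bundle.image.pixels, layers,
                                   config.detector, channels=channels)
    for c in candidates:
        c.slide_id = slide_id
    candidates = contextual_rescore(candidates, bundle.image.pixels, layers,
                                    params=config.contextual,
                                    channels=channels)
    sets = build_image_sets(candidates, {slide_id: bundle.image.pixels},
                            case_id=case_id, params=config.triage)
    record = make_case_record(case_id, sets)
    log.info("%s: %d candidates, %d sets, avg_top3_ai=%.3f",
             case_id, len(candidates), len(sets), record.avg_top3_ai)
    return CaseAnalysis(record=record, candidates=candidates,
                        layers_predicted=layers, bundle=bundle)


def run_case(
    config: RunConfig, run_dir: str | Path, case_id: str
) -> CaseAnalysis:
    """Analyse one simulated case and export its image sets."""
    run_dir = Path(run_dir)
    manifest = load_manifest(run_dir / "cohort")
    rows = manifest[manifest.case_id == case_id]
    if rows.empty:
        raise ValueError(f"unknown case id {case_id!r}")
    bundle = read_bundle(run_dir / "cohort" / rows.iloc[0]["path"])
    analysis = analyze_bundle(bundle, config, case_id)
    case_dir = run_dir / "cases" / case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    write_candidates_csv(analysis.candidates, case_dir / "candidates.csv",
                         case_id=case_id)
    export_case(analysis.record, case_dir / "sets",
                config_hash=config.config_hash())
    provenance = {
        "case_id": case_id,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "avg_top3_ai": round(analysis.record.avg_top3_ai, 6),
        "n_candidates": len(analysis.candidates),
        "n_sets": len(analysis.record.sets),
    }
    (case_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    return analysis


# --------------------------------------------------------------------------
# observer scores and evaluation
# --------------------------------------------------------------------------

def simulate_observer_scores(
    analysis: CaseAnalysis, certain: int = 5, otherwise: int = 2
) -> list[int]:
    """A deterministic oracle observer: scores a set 5 when one of its
    patches centres on a true annotated ganglion cell, ``otherwise`` if
    not.  Useful for end-to-end runs without human score tables."""
    truth = analysis.bundle.annotations.ganglia
    scores = []
    for image_set in analysis.record.sets:
        hit = any(
            cell.contains_point(*patch.candidate.centroid)
            for patch in image_set.patches for cell in truth
        )
        scores.append(certain if hit else otherwise)
    return scores


def read_observer_scores(path: str | Path) -> dict[str, dict[str, list[int]]]:
    """Read a long-format CSV (observer, case_id, set_rank, score) into
    observer -> case_id -> ordered score list."""
    df = pd.read_csv(path)
    required = {"observer", "case_id", "set_rank", "score"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"observer score file {path} lacks columns "
            f"{sorted(required - set(df.columns))}"
        )
    out: dict[str, dict[str, list[int]]] = {}
    for (obs, cid), grp in df.groupby(["observer", "case_id"], sort=True):
        ordered = grp.sort_values("set_rank")["score"].astype(int).tolist()
        out.setdefault(str(obs), {})[str(cid)] = ordered
    return out


def evaluate_cohort(
    config: RunConfig,
    records: dict[str, CaseRecord],
    scores: dict[str, dict[str, list[int]]],
    expert_observer: str | None = None,
    audit_path: str | Path | None = None,
):
    """Classify every case for every observer and summarise consultations.

    ``expert_observer``, when given, is classified under the expert rule
    and used to resolve the non-experts' Doubt cases; the remaining
    observers follow the non-expert rule.
    """
    audit: list[dict] = []
    nonexpert_obs = [o for o in scores if o != expert_observer]
    flags: dict[str, dict[str, bool]] = {}
    nonexpert_labels: dict[str, dict[str, Classification]] = {}
    expert_labels: dict[str, Classification] = {}

    if expert_observer is not None:
        for cid, record in records.items():
            s = scores[expert_observer].get(cid, [])
            record_pathologist_scores(record, expert_observer, s)
            cls = classify_expert(s, config.decision)
            expert_labels[cid] = cls
            audit.append({"case_id": cid, "observer": expert_observer,
                          "label": cls.label, "basis": cls.basis})

    for obs in nonexpert_obs:
        flags[obs] = {}
        nonexpert_labels[obs] = {}
        for cid, record in records.items():
            s = scores[obs].get(cid, [])
            record_pathologist_scores(record, obs, s)
            cls = classify_nonexpert(s, record.avg_top3_ai, config.decision)
            nonexpert_labels[obs][cid] = cls
            flags[obs][cid] = cls.needs_consultation
            audit.append({"case_id": cid, "observer": obs,
                          "label": cls.label, "basis": cls.basis})

    final: dict[str, dict[str, Classification]] = {}
    if expert_observer is not None:
        for obs in nonexpert_obs:
            final[obs] = resolve_consultations(nonexpert_labels[obs],
                                               expert_labels)
    else:
        for obs in nonexpert_obs:
            if any(c.label == DOUBT for c in nonexpert_labels[obs].values()):
                log.warning(
                    "observer %s has Doubt cases but no expert observer "
                    "was designated; labels left unresolved", obs)
            final[obs] = nonexpert_labels[obs]

    report = consultation_statistics(flags) if flags else None
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            for entry in audit:
                fh.write(json.dumps(entry, sort_keys=True, default=str)
                         + "\n")
    return report, final, expert_labels


def run_evaluate(
    config: RunConfig,
    run_dir: str | Path,
    scores_path: str | Path,
    expert_observer: str | None = None,
):
    """Analyse every cohort case, apply observer scores, write the report."""
    run_dir = Path(run_dir)
    manifest = load_manifest(run_dir / "cohort")
    scores = read_observer_scores(scores_path)
    records: dict[str, CaseRecord] = {}
    analyses: dict[str, CaseAnalysis] = {}
    for case_id in manifest.case_id:
        analysis = run_case(config, run_dir, case_id)
        records[case_id] = analysis.record
        analyses[case_id] = analysis
    report, final, expert_labels = evaluate_cohort(
        config, records, scores, expert_observer=expert_observer,
        audit_path=run_dir / "classifications.jsonl",
    )

    truth = dict(zip(manifest.case_id, manifest.label))
    errors: dict[str, int] = {}
    for obs, labels in final.items():
        n_err = sum(
            1 for cid, cls in labels.items()
            if (cls.label == "Positive") != (truth[cid] == "non-HSCR")
        )
        errors[obs] = n_err
    if report is not None:
        report.per_observer_errors = errors
        report.to_json(run_dir / "report.json")
        report.to_csv(run_dir / "report.csv")
    return report, final, analyses
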