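"""Decision rules, consultation routing and cohort statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganglionhca.annotations import Annotation, AnnotationSet
from ganglionhca.decision_metrics import (
    DOUBT,
    NEGATIVE,
    POSITIVE,
    Classification,
    cell_level_metrics,
    classify_expert,
    classify_nonexpert,
    consultation_statistics,
    resolve_consultations,
)

from .conftest import make_candidate


class TestExpertRule:
    def test_single_certain_set_is_positive(self):
        assert classify_expert([1, 1, 5]).label == POSITIVE

    def test_all_scores_below_five_is_negative(self):
        assert classify_expert([4, 4, 4]).label == NEGATIVE

    def test_no_sets_means_nothing_seen_hence_negative(self):
        cls = classify_expert([])
        assert cls.label == NEGATIVE
        assert "no image sets" in cls.basis["reason"]

    def test_exhaustive_short_lists_positive_iff_any_five(self):
        for n in (1, 2, 3):
            for scores in itertools.product(range(1, 6), repeat=n):
                got = classify_expert(list(scores)).label
                assert got == (POSITIVE if 5 in scores else NEGATIVE)

    def test_invalid_score_is_rejected(self):
        with pytest.raises(ValueError, match="outside 1..5"):
            classify_expert([3, 6])


class TestNonExpertRule:
    def test_two_certain_sets_are_positive_regardless_of_ai(self):
        assert classify_nonexpert([5, 5, 1, 1], 0.2).label == POSITIVE

    def test_one_five_with_low_ai_average_is_negative(self):
        assert classify_nonexpert([5, 4, 1], 0.55).label == NEGATIVE

    def test_boundary_average_is_doubt_inclusive(self):
        assert classify_nonexpert([5, 4, 1], 0.60).label == DOUBT

    def test_doubt_requires_consultation(self):
        assert classify_nonexpert([1, 1], 0.9).needs_consultation
        assert not classify_nonexpert([5, 5], 0.9).needs_consultation

    def test_no_sets_low_ai_is_negative(self):
        assert classify_nonexpert([], 0.0).label == NEGATIVE

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=5), max_size=12),
        st.sampled_from([0.0, 0.3, 0.59, 0.599, 0.6, 0.601, 0.9, 1.0]),
    )
    def test_rule_totality_and_branch_agreement(self, scores, avg):
        """Every (score list, average) maps to exactly one label, equal to
        a literal restatement of the triage criteria."""
        got = classify_nonexpert(scores, avg).label
        if scores.count(5) >= 2:
            expected = POSITIVE
        elif avg < 0.6:
            expected = NEGATIVE
        else:
            expected = DOUBT
        assert got == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=5), max_size=12),
           st.floats(min_value=0.6, max_value=1.0))
    def test_high_ai_cases_are_never_finalised_negative_by_a_nonexpert(
        self, scores, avg
    ):
        """Safety: with avg >= 0.6 the non-expert outcome is Positive or
        Doubt (consultation), never a silent Negative."""
        assert classify_nonexpert(scores, avg).label != NEGATIVE

    def test_average_outside_unit_interval_is_rejected(self):
        with pytest.raises(ValueError):
            classify_nonexpert([1], 1.5)


class TestResolveConsultations:
    def test_doubt_takes_the_expert_label(self):
        final = resolve_consultations(
            {"a": Classification(DOUBT)},
            {"a": Classification(POSITIVE)},
        )
        assert final["a"].label == POSITIVE

    def test_non_doubt_labels_pass_through(self):
        final = resolve_consultations(
            {"a": Classification(NEGATIVE), "b": Classification(POSITIVE)},
            {"a": Classification(POSITIVE), "b": Classification(NEGATIVE)},
        )
        assert final["a"].label == NEGATIVE
        assert final["b"].label == POSITIVE

    def test_cohort_without_doubt_is_unchanged(self):
        labels = {f"c{i}": Classification(NEGATIVE) for i in range(5)}
        assert resolve_consultations(labels, {}) == labels

    def test_doubt_without_expert_label_lists_the_cases(self):
        with pytest.raises(ValueError, match="c1"):
            resolve_consultations({"c1": Classification(DOUBT)}, {})


def square(cx: float, cy: float, half: float = 50.0,
           label: str = "mature_ganglion") -> Annotation:
    return Annotation(label, np.array(
        [(cx - half, cy - half), (cx + half, cy - half),
         (cx + half, cy + half), (cx - half, cy + half)]
    ))


def ray_casting_contains(coords: np.ndarray, x: float, y: float) -> bool:
    """Independent point-in-polygon oracle (even-odd rule)."""
    inside = False
    n = len(coords)
    for i in range(n):
        x1, y1 = coords[i]
        x2, y2 = coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xt = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xt:
                inside = not inside
    return inside


class TestCellLevelMetrics:
    def test_matched_fraction_is_reported_as_a_percentage(self):
        truth = AnnotationSet(
            [square(200 * i + 100.0, 100.0) for i in range(100)]
        )
        detections = [
            make_candidate(200 * i + 100.0, 100.0) for i in range(96)
        ]
        m = cell_level_metrics(detections, truth)
        assert m.sensitivity == pytest.approx(96.0)
        assert m.n_truth == 100 and m.n_detected == 96

    def test_no_detections_reject_every_decoy(self):
        from shapely.geometry import box

        m = cell_level_metrics(
            [], AnnotationSet([square(100, 100)]),
            negative_regions=box(300, 0, 2000, 400), n_decoys=50,
        )
        assert m.specificity == pytest.approx(100.0)
        assert m.n_decoys == 50

    def test_zero_truth_cells_give_undefined_sensitivity(self):
        m = cell_level_metrics([make_candidate(10, 10)], AnnotationSet())
        assert m.sensitivity is None

    def test_multiple_detections_in_one_cell_count_once(self):
        truth = AnnotationSet([square(100, 100)])
        detections = [make_candidate(90, 100), make_candidate(110, 100)]
        m = cell_level_metrics(detections, truth)
        assert m.n_detected == 1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_sensitivity_matches_ray_casting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = AnnotationSet([
            square(float(x), float(y), half=float(rng.uniform(20, 60)))
            for x, y in rng.uniform(100, 900, size=(6, 2))
        ])
        detections = [
            make_candidate(float(x), float(y))
            for x, y in rng.uniform(0, 1000, size=(30, 2))
        ]
        m = cell_level_metrics(detections, truth)
        expected = sum(
            any(ray_casting_contains(ann.coords, *d.centroid)
                for d in detections)
            for ann in truth
        )
        assert m.n_detected == expected


def flags_from_counts(n_cases: int, per_k: dict[int, int],
                      observers=("p2", "p3", "p4", "p5")):
    """Build a flag table in which exactly per_k[k] cases are flagged by
    exactly k observers."""
    flags = {obs: {} for obs in observers}
    case = 0
    for k, count in per_k.items():
        for _ in range(count):
            cid = f"case_{case:03d}"
            for j, obs in enumerate(observers):
                flags[obs][cid] = j < k
            case += 1
    while case < n_cases:
        cid = f"case_{case:03d}"
        for obs in observers:
            flags[obs][cid] = False
        case += 1
    return flags


class TestConsultationStatistics:
    def test_exact_k_distribution_percentages(self):
        flags = flags_from_counts(48, {4: 9, 2: 9, 1: 6})
        report = consultation_statistics(flags)
        assert report.cross_observer[4]["pct"] == 18.75
        assert report.cross_observer[2]["pct"] == 18.75
        assert report.cross_observer[1]["pct"] == 12.5
        assert report.cross_observer[4]["denominator"] == 48

    def test_zero_flags_give_zero_rates(self):
        flags = flags_from_counts(10, {})
        report = consultation_statistics(flags)
        for obs in flags:
            assert report.per_observer[obs]["rate"] == 0.0
        assert report.cross_observer[0]["count"] == 10

    def test_differing_case_sets_are_rejected(self):
        flags = {"a": {"c1": True}, "b": {"c2": True}}
        with pytest.raises(ValueError, match="different case set"):
            consultation_statistics(flags)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n_obs, n_cases = int(rng.integers(1, 6)), int(rng.integers(1, 30))
        mat = rng.random((n_obs, n_cases)) < 0.3
        flags = {
            f"o{i}": {f"c{j}": bool(mat[i, j]) for j in range(n_cases)}
            for i in range(n_obs)
        }
        report = consultation_statistics(flags)
        for i in range(n_obs):
            assert report.per_observer[f"o{i}"]["count"] == int(
                mat[i].sum()
            )
        col_sums = mat.sum(axis=0)
        for k in range(n_obs + 1):
            assert report.cross_observer[k]["count"] == int(
                (col_sums == k).sum()
            )
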