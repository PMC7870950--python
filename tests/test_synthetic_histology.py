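"""Generator contracts: determinism, placement soundness, annotation I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganglionhca.annotations import (
    Annotation,
    AnnotationParseError,
    AnnotationSet,
    read_annotations,
    write_annotations,
)
from ganglionhca.config import LAYER_LEGEND, PERMISSIBLE_LAYERS
from ganglionhca.synthetic_histology import (
    SlideSpec,
    generate_cohort,
    generate_slide,
    read_bundle,
    write_bundle,
)

from .conftest import tiny_spec


class TestSlideSpec:
    def test_band_fractions_must_be_nonnegative_and_sum_below_one(self):
        with pytest.raises(ValueError):
            SlideSpec(layer_band_fractions=(0.3, 0.3, 0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            SlideSpec(layer_band_fractions=(-0.1, 0.3, 0.3, 0.3, 0.1))

    def test_counts_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            SlideSpec(n_mature_ganglia=-1)


class TestGenerateSlide:
    def test_same_spec_and_seed_reproduces_the_bundle_exactly(self):
        a = generate_slide(tiny_spec(seed=11))
        b = generate_slide(tiny_spec(seed=11))
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.layers.labels, b.layers.labels)
        assert a.annotations == b.annotations

    def test_zero_ganglia_spec_yields_zero_ganglion_polygons(self):
        bundle = generate_slide(
            tiny_spec(n_mature_ganglia=0, n_immature_ganglia=0, seed=5)
        )
        assert len(bundle.annotations.ganglia) == 0
        # mimics are still there to challenge the hierarchical filter
        assert len(bundle.annotations.by_class("mimic")) == 5

    def test_requested_ganglion_count_is_honoured_with_valid_placement(self):
        bundle = generate_slide(SlideSpec(n_mature_ganglia=20, seed=7))
        mature = bundle.annotations.by_class("mature_ganglion")
        assert len(mature) == 20
        for ann in mature:
            x, y = ann.centroid
            assert bundle.layers.label_at(int(x), int(y)) in PERMISSIBLE_LAYERS

    def test_ganglion_polygons_lie_entirely_within_permissible_bands(
        self, default_bundle
    ):
        for ann in default_bundle.annotations.ganglia:
            labels = {
                default_bundle.layers.label_at(int(x), int(y))
                for x, y in ann.coords
            }
            assert labels <= PERMISSIBLE_LAYERS

    def test_mimics_are_placed_only_in_non_permissible_layers(
        self, default_bundle
    ):
        mimics = default_bundle.annotations.by_class("mimic")
        assert len(mimics) > 0
        for ann in mimics:
            x, y = ann.centroid
            label = default_bundle.layers.label_at(int(x), int(y))
            assert label not in PERMISSIBLE_LAYERS
            assert LAYER_LEGEND[label] in {"epithelium", "mucosa", "serosa"}

    def test_image_and_layer_map_share_dimensions(self, default_bundle):
        assert (default_bundle.image.pixels.shape[:2]
                == default_bundle.layers.shape)

    def test_bands_too_thin_for_a_soma_raise_instead_of_truncating(self):
        with pytest.raises(ValueError, match="too thin"):
            generate_slide(
                SlideSpec(
                    width_px=600,
                    height_px=400,
                    layer_band_fractions=(0.1, 0.4, 0.1, 0.1, 0.1),
                    n_mature_ganglia=2,
                )
            )


class TestGenerateCohort:
    def test_half_hscr_cohort_has_exactly_half_zero_ganglion_cases(self):
        cases = generate_cohort(10, hscr_fraction=0.5, seed=4,
                                base_spec=tiny_spec())
        empty = [c for c in cases if len(c.bundle.annotations.ganglia) == 0]
        assert len(empty) == 5
        assert all(c.label == "HSCR" for c in empty)
        for c in cases:
            if c.label == "non-HSCR":
                assert len(c.bundle.annotations.ganglia) >= 1

    def test_inadequate_cases_have_no_submucosa_and_no_ganglia(self):
        cases = generate_cohort(6, hscr_fraction=0.0,
                                inadequate_fraction=0.5, seed=9,
                                base_spec=tiny_spec())
        inadequate = [c for c in cases if c.label == "inadequate"]
        assert len(inadequate) == 3
        for c in inadequate:
            assert c.bundle.layers.fraction("submucosa") == 0.0
            assert c.bundle.layers.fraction("muscularis") == 0.0
            assert len(c.bundle.annotations.ganglia) == 0

    def test_cohort_labels_are_reproducible_under_the_same_seed(self):
        kw = dict(hscr_fraction=0.4, inadequate_fraction=0.2, seed=21,
                  base_spec=tiny_spec())
        first = [c.label for c in generate_cohort(10, **kw)]
        second = [c.label for c in generate_cohort(10, **kw)]
        assert first == second

    def test_zero_cases_is_an_empty_cohort_not_an_error(self):
        assert generate_cohort(0, hscr_fraction=0.5, seed=0) == []

    def test_fraction_sum_above_one_is_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(4, hscr_fraction=0.8, inadequate_fraction=0.4,
                            seed=0)


class TestAnnotationIO:
    def test_empty_set_round_trips_through_valid_xml(self, tmp_path):
        path = tmp_path / "empty.xml"
        write_annotations(AnnotationSet(), path)
        assert read_annotations(path) == AnnotationSet()

    def test_square_polygon_round_trips_exactly(self, tmp_path):
        square = Annotation(
            "mimic",
            np.array([(0, 0), (100, 0), (100, 100), (0, 100)], dtype=float),
        )
        path = tmp_path / "square.xml"
        write_annotations(AnnotationSet([square]), path)
        back = read_annotations(path)
        assert len(back) == 1
        assert np.array_equal(back.annotations[0].coords, square.coords)
        assert back.annotations[0].label == "mimic"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_polygon_sets_round_trip(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        anns = []
        for _ in range(rng.integers(1, 8)):
            cx, cy = rng.uniform(50, 950, size=2)
            r = rng.uniform(5, 40)
            theta = np.linspace(0, 2 * np.pi, int(rng.integers(3, 30)),
                                endpoint=False)
            coords = np.stack(
                [cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1
            )
            label = ["mimic", "vessel", "mature_ganglion"][
                int(rng.integers(3))
            ]
            anns.append(Annotation(label, coords))
        path = tmp_path_factory.mktemp("xml") / "anns.xml"
        write_annotations(AnnotationSet(anns), path)
        assert read_annotations(path) == AnnotationSet(anns)

    def test_slide_annotations_round_trip(self, default_bundle, tmp_path):
        path = tmp_path / "slide.xml"
        write_annotations(default_bundle.annotations, path)
        assert read_annotations(path) == default_bundle.annotations

    def test_malformed_xml_names_the_offending_element(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<ASAP_Annotations><Annotations>"
            '<Annotation Name="Annotation 7" PartOfGroup="mimic">'
            "<Coordinates><Coordinate Order='0' X='oops' Y='1'/>"
            "</Coordinates></Annotation></Annotations></ASAP_Annotations>"
        )
        with pytest.raises(AnnotationParseError, match="Annotation 7"):
            read_annotations(path)

    def test_missing_coordinates_element_is_reported(self, tmp_path):
        path = tmp_path / "bad2.xml"
        path.write_text(
            "<ASAP_Annotations><Annotations>"
            '<Annotation Name="A" PartOfGroup="mimic"/>'
            "</Annotations></ASAP_Annotations>"
        )
        with pytest.raises(AnnotationParseError, match="Coordinates"):
            read_annotations(path)


class TestBundleIO:
    def test_bundle_round_trips_through_disk(self, noiseless_bundle,
                                             tmp_path):
        write_bundle(noiseless_bundle, tmp_path / "case")
        back = read_bundle(tmp_path / "case")
        assert np.array_equal(back.image.pixels,
                              noiseless_bundle.image.pixels)
        assert np.array_equal(back.layers.labels,
                              noiseless_bundle.layers.labels)
        assert back.annotations == noiseless_bundle.annotations

    def test_missing_slide_file_error_names_the_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="slide.tif"):
            read_bundle(tmp_path / "nowhere")
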