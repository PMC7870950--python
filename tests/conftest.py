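"""Shared fixtures: small seeded synthetic slides and their analyses."""

from __future__ import annotations

import numpy as np
import pytest

from ganglionhca.candidate_detection import Candidate, detect_candidates
from ganglionhca.contextual_analysis import contextual_rescore
from ganglionhca.synthetic_histology import SlideSpec, generate_slide
from ganglionhca.tissue_hierarchy import segment_layers


def tiny_spec(**overrides) -> SlideSpec:
    """A small, quick slide that still holds every anatomical structure."""
    kwargs = dict(
        width_px=768,
        height_px=640,
        n_mature_ganglia=4,
        n_immature_ganglia=1,
        n_mimics=5,
        cluster_size_mean=2.0,
        seed=0,
    )
    kwargs.update(overrides)
    return SlideSpec(**kwargs)


def make_candidate(
    x: float, y: float, score: float = 0.5, box: int = 100,
    slide_id: str | None = None,
) -> Candidate:
    half = box // 2
    return Candidate(
        centroid=(x, y),
        patch_box=(int(x) - half, int(y) - half,
                   int(x) + half, int(y) + half),
        base_score=score,
        contextual_score=score,
        slide_id=slide_id,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default-difficulty slide (8 mature + 3 immature ganglia)."""
    return generate_slide(SlideSpec(seed=1))


@pytest.fixture(scope="session")
def default_layers(default_bundle):
    return segment_layers(default_bundle.image)


@pytest.fixture(scope="session")
def default_candidates(default_bundle, default_layers):
    return detect_candidates(default_bundle.image.pixels, default_layers)


@pytest.fixture(scope="session")
def default_rescored(default_bundle, default_layers, default_candidates):
    import copy

    cands = copy.deepcopy(default_candidates)
    return contextual_rescore(cands, default_bundle.image.pixels,
                              default_layers)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_slide(tiny_spec(noise_level=0.0, seed=3))
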