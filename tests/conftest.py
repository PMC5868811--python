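"""Shared synthetic-section fixtures.

Section generation and segmentation are the expensive steps, so the standard
study sections are built once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sarcoquant import (
    SegmentationParams,
    SyntheticSpec,
    build_compartments,
    generate_section,
    quantify_all,
    segment_section,
)

settings.register_profile("ci", derandomize=True, max_examples=40)
settings.load_profile("ci")

NOISE_FREE = {"gaussian_sigma_au": 0, "poisson_gain_au": 0}


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free section, complete rims, no distractors: exact oracles."""
    spec = SyntheticSpec(
        image_shape=(1536, 1536),
        seed=21,
        distractors=(),
        noise=dict(NOISE_FREE),
        gap_fraction_dist={"name": "constant", "value": 0.0},
    )
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def clean_segmented(clean_section):
    _, section, truth = clean_section
    return segment_section(section), section, truth


@pytest.fixture(scope="session")
def clean_quantified(clean_segmented):
    result, section, truth = clean_segmented
    masks = build_compartments(result.labels, section.pixel_size_um)
    table = quantify_all(section, result.label_map, masks)
    return table, masks, result, section, truth


@pytest.fixture(scope="session")
def noisy_section():
    """Default photon + read noise, default (rare) gaps, no distractors."""
    spec = SyntheticSpec(image_shape=(1536, 1536), seed=22, distractors=())
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def noisy_segmented(noisy_section):
    _, section, truth = noisy_section
    return segment_section(section), section, truth


@pytest.fixture(scope="session")
def gap_section():
    """Noise-free section whose fibres carry gaps spanning the 20% rule."""
    spec = SyntheticSpec(
        image_shape=(1536, 1536),
        seed=11,
        distractors=(),
        noise=dict(NOISE_FREE),
        gap_fraction_dist={"name": "uniform", "low": 0.0, "high": 0.35},
    )
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def gap_segmented(gap_section):
    _, section, truth = gap_section
    return segment_section(section), section, truth


@pytest.fixture(scope="session")
def distractor_section():
    """Default conditions including all five distractor kinds."""
    spec = SyntheticSpec(image_shape=(1536, 1536), seed=3)
    section, truth = generate_section(spec)
    return spec, section, truth


@pytest.fixture(scope="session")
def distractor_segmented(distractor_section):
    _, section, truth = distractor_section
    return segment_section(section), section, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
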