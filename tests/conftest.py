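"""Shared fixtures: small phantoms for unit tests, the default-size study
(run once per session) for the end-to-end suites."""

from __future__ import annotations

import numpy as np
import pytest

from svzmap.phantom import PhantomSpec, ground_truth, iter_sections, study_config
from svzmap.pipeline import analyze_sections


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 512 px, 6-section phantom: fast, 2 probes per vertical wall."""
    return PhantomSpec(image_shape=(512, 512), n_sections=6, seed=0)


@pytest.fixture(scope="session")
def small_section(small_spec):
    from svzmap.phantom import generate_section

    return generate_section(small_spec, 2)


@pytest.fixture(scope="session")
def default_study():
    """Full default-size study (43 sections, 1024 px), analyzed once.

    Returns (spec, config, result, truth); shared by the end-to-end and
    acceptance suites.
    """
    spec = PhantomSpec(seed=0)
    config = study_config(spec)
    result = analyze_sections(iter_sections(spec), config)
    truth = ground_truth(spec, config.probe_width_px)
    return spec, config, result, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
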