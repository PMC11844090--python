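"""Shared fixtures: rendered synthetic cohorts analysed once per session."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from gliamorph import pipeline, synthetic as syn
from gliamorph.config import AnalysisConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """18-case noise-free human-like cohort (~330 cells) with ground truth."""
    spec = syn.default_human_cohort(seed=11, n_control=9, n_stage13=5, n_stage4=4)
    spec = replace(spec, noise=syn.NoiseModel(background=0.0, read_noise_sd=0.0))
    return syn.render_cohort(spec)


@pytest.fixture(scope="session")
def noise_free_analysis(noise_free_cohort):
    """Pipeline output on the noise-free cohort, truth-matched."""
    cfg = AnalysisConfig()
    cells, tissue, matched = pipeline.analyze_cohort(
        noise_free_cohort, cfg, match_truth=True)
    return {"cells": cells, "tissue": tissue, "matched": matched, "cfg": cfg}


@pytest.fixture(scope="session")
def noisy_cohort():
    """12-case cohort with the default noise model (direction-of-effect runs)."""
    spec = syn.default_human_cohort(seed=5, n_control=6, n_stage13=3, n_stage4=3)
    return syn.render_cohort(spec)


@pytest.fixture(scope="session")
def noisy_analysis(noisy_cohort):
    cfg = AnalysisConfig()
    cells, tissue = pipeline.analyze_cohort(noisy_cohort, cfg)
    return {"cells": cells, "tissue": tissue, "cfg": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
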