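"""Shared fixtures: expensive simulated objects built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from habitatomics.habitats import select_k_and_segment
from habitatomics.pipeline import PipelineConfig, run_pipeline
from habitatomics.synthetic import (
    CohortSpec,
    generate_clinical,
    generate_tumor_volume,
)

#: cohort sizes used by the slower end-to-end fixtures; chosen so the
#: full suite runs comfortably on one CPU
PIPELINE_N = 14
PIPELINE_SEED = 7
SEGMENTATION_N = 20


@pytest.fixture(scope="session")
def two_habitat_segmentations():
    """Default-spec tumors for 20 patients, each segmented over K = 2..10.

    Returns (volumes, label maps); used for habitat-recovery and
    label-ordering checks.
    """
    spec = CohortSpec(n_patients=SEGMENTATION_N, seed=20260921)
    ss = np.random.SeedSequence(spec.seed)
    rng_clin, rng_vol = (np.random.default_rng(c) for c in ss.spawn(2))
    clinical = generate_clinical(spec, rng_clin)
    volumes, habmaps = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (_, row) in enumerate(clinical.iterrows()):
            vol = generate_tumor_volume(spec, row, rng_vol)
            habmaps.append(
                select_k_and_segment(vol.image.astype(float), vol.mask, seed=100 + i)
            )
            volumes.append(vol)
    return volumes, habmaps


def _run(tmp_path_factory, name: str, **overrides):
    cfg = PipelineConfig(
        out_dir=str(tmp_path_factory.mktemp(name)),
        n_patients=PIPELINE_N,
        seed=PIPELINE_SEED,
        **overrides,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(cfg)
    return cfg, manifest


@pytest.fixture(scope="session")
def pipeline_run_a(tmp_path_factory):
    return _run(tmp_path_factory, "run_a")


@pytest.fixture(scope="session")
def pipeline_run_b(tmp_path_factory):
    """Second run with an identical configuration (different directory)."""
    return _run(tmp_path_factory, "run_b")


@pytest.fixture(scope="session")
def pipeline_run_sim_only(tmp_path_factory):
    """Same config with all downstream stages toggled off."""
    return _run(tmp_path_factory, "run_sim", stages=("simulate",))
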