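"""Shared fixtures: tiny BOLD runs built in memory and one full default-study
analysis shared (session-scoped) by the map-level acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest

from traitconn.config import StudyConfig, validate_config
from traitconn.datatypes import BoldRun, PlantedEffect, SeedSpec


def make_run(data: np.ndarray, tr: float = 2.0, voxel: float = 4.0,
             motion: np.ndarray | None = None,
             brain: np.ndarray | None = None) -> BoldRun:
    """Wrap a 4D array into a BoldRun with simple masks and geometry."""
    shape = data.shape[:3]
    t = data.shape[3]
    affine = np.diag([voxel] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    if brain is None:
        brain = np.ones(shape, dtype=bool)
    wm = np.zeros(shape)
    wm[0] = 0.9
    csf = np.zeros(shape)
    csf[-1] = 0.9
    if motion is None:
        motion = np.zeros((t, 6))
    return BoldRun(data=np.asarray(data, dtype=float), tr_seconds=tr, affine=affine,
                   motion=motion, brain_mask=brain, wm_prob=wm, csf_prob=csf,
                   subject_id="sub-test", run_index=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_study_config(rng_seed: int = 77) -> StudyConfig:
    """A small but complete study: 12 subjects, one run each, two seeds,
    one planted association and one invariant-positive connection."""
    cfg = StudyConfig(
        n_subjects=12,
        runs_per_subject={1: 0.7, 2: 0.3},
        grid_shape=(14, 16, 14),
        voxel_size_mm=4.0,
        n_volumes=80,
        seeds=[SeedSpec("s1", (0.0, 14.0, 4.0), 8.0),
               SeedSpec("s2", (0.0, -16.0, 8.0), 8.0)],
        effects=[
            PlantedEffect("s1", "assoc_n", (-14.0, -6.0, -6.0), 6.0,
                          0.0, {"neuroticism": 0.007}, "variable"),
            PlantedEffect("s2", "base_pos", (14.0, 6.0, -8.0), 6.0,
                          0.5, {}, "invariant_pos"),
        ],
        rng_seed=rng_seed,
    )
    errs = validate_config(cfg)
    assert not errs, errs
    return cfg


@pytest.fixture(scope="session")
def default_study_results():
    """One full default-study analysis (39 subjects, 1-5 runs each), shared by
    every test that inspects the map-level results."""
    from traitconn.benchmarks import run_default_study

    return run_default_study(rng_seed=2026, n_perm=1000)
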