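"""Shared fixtures.

Small configurations keep unit tests fast; the session-scoped
``default_cohort`` fixture runs the full-scale ten-subject study once and
is shared by the recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from v2lamina import pipeline as pipe
from v2lamina import synthetic as syn
from v2lamina.synthetic import PatchConfig, default_truth

SMALL_GRIDS = {a: (24, 16) for a in ("V1", "V2", "V3ab", "V4")}


def small_cohort_config(seed=0, n_subjects=10, n_runs=4, truth=None, **analysis_kw):
    """Scaled-down cohort: 24x16 columns per area, 4 runs, 60-voxel tails."""
    analysis = pipe.AnalysisConfig(n_tail=30, **analysis_kw)
    return pipe.CohortConfig(
        n_subjects=n_subjects,
        runs_per_subject=(n_runs,) * n_subjects,
        patch=PatchConfig(area_grids=dict(SMALL_GRIDS)),
        truth=truth if truth is not None else default_truth(),
        analysis=analysis,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_patch():
    return syn.make_cortical_patch(PatchConfig(area_grids=dict(SMALL_GRIDS)))


@pytest.fixture(scope="session")
def flat_patch():
    return syn.make_cortical_patch(
        PatchConfig(area_grids=dict(SMALL_GRIDS), curvature_amplitude=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale ten-subject cohort at the study's default conditions.

    Six subjects with ten runs and four with four runs per experiment;
    60 x 50 columns per area; 200-voxel selection tails.  Shared by the
    stripe, laminar and connectivity recovery tests.
    """
    return pipe.run_cohort(pipe.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_null_subject():
    """One small simulated subject with no planted couplings (null connectivity)."""
    truth = default_truth()
    truth.shared_variability = []
    cfg = small_cohort_config(seed=404, n_subjects=3, truth=truth)
    patch = syn.make_cortical_patch(cfg.patch)
    data, planted = pipe.simulate_cohort_subject(cfg, patch, 0)
    return cfg, patch, data, planted
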