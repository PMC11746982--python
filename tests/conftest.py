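"""Shared fixtures: study conditions at the desk-scale grid resolution.

Expensive end-to-end runs (phantom pipelines, the 19-study cohort) are
session-scoped so every test that needs them shares one computation.  The
desk-scale grids keep the full 614 mm field of view of the clinical
128^3 / 4.8 mm SPECT grid at half resolution (64^3 / 9.6 mm).
"""

from __future__ import annotations

import pytest

import tabfx
from tabfx.grids import GridSpec
from tabfx.pipeline import (
    ExperimentConfig,
    default_ct_grid,
    default_spect_grid,
    run_cohort_experiment,
    run_phantom_experiment,
)

DESK_DOWNSAMPLE = 2


@pytest.fixture(scope="session")
def desk_grids():
    return default_spect_grid(DESK_DOWNSAMPLE), default_ct_grid(DESK_DOWNSAMPLE)


@pytest.fixture(scope="session")
def qc_report(desk_grids):
    spect, ct = desk_grids
    cfg = ExperimentConfig(experiment="qc_phantom", spect_grid=spect, ct_grid=ct)
    return run_phantom_experiment(cfg)


@pytest.fixture(scope="session")
def mpi_report(desk_grids):
    spect, ct = desk_grids
    cfg = ExperimentConfig(experiment="mpi_phantom", spect_grid=spect, ct_grid=ct)
    return run_phantom_experiment(cfg)


@pytest.fixture(scope="session")
def cohort_report():
    """19-study synthetic cohort, both arms reconstructed per study."""
    cfg = ExperimentConfig(
        experiment="cohort",
        seed=42,
        n_studies=19,
        spect_grid=GridSpec.centered((64, 64, 32), (9.6, 9.6, 9.6)),
        ct_grid=default_ct_grid(DESK_DOWNSAMPLE),
    )
    return run_cohort_experiment(cfg)


@pytest.fixture()
def small_phantom(desk_grids):
    """Default phantom + table volumes on the desk-scale grids."""
    spect, ctg = desk_grids
    ct, act, truth = tabfx.generate_jaszczak(
        tabfx.PhantomSpec(), tabfx.TableModel(), ctg, spect
    )
    return ct, act, truth
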