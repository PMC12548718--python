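"""Shared fixtures: a small grid with embedded ground truth, and a cached
multi-subject study run through the full task pipeline."""

import numpy as np
import pytest

from preself import glm, simcore
from preself.types import AcquisitionGrid


@pytest.fixture(scope="session")
def small_grid():
    return AcquisitionGrid(dims=(16, 12, 8), voxel_size=2.5, tr=1.0)


@pytest.fixture(scope="session")
def small_truth(small_grid):
    return simcore.make_ground_truth(small_grid, seed=7)


@pytest.fixture(scope="session")
def small_masks(small_grid):
    return simcore.default_masks(small_grid)


@pytest.fixture(scope="session")
def hrf():
    return glm.canonical_hrf(1.0)


def simulate_subject(truth, grid, hrf, seed, trials_per_run=18, n_runs=2,
                     noise_sd=1.0):
    """One subject through schedule -> choices -> run -> residuals -> betas."""
    cfg = simcore.ScheduleConfig(trials_per_run=trials_per_run, n_runs=n_runs)
    schedule = simcore.make_task_schedule(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    amplitudes = rng.standard_normal(trials_per_run * n_runs)
    choices = simcore.simulate_choices(truth, amplitudes, seed=seed + 2)
    series, motion = simcore.simulate_task_run(
        schedule, choices, truth, grid, noise_sd=noise_sd, seed=seed + 3,
        amplitudes=amplitudes)
    nuis = glm.NuisanceSet(run_lengths=series.run_lengths, motion=motion)
    design = glm.build_design(schedule, nuis, hrf, conditions=["choice", "shape"])
    residuals = glm.residualize(series, design)
    betas = glm.pretrial_rest_betas(residuals, schedule, choices, hrf,
                                    subject=f"seed-{seed}")
    return {"schedule": schedule, "choices": choices, "series": series,
            "motion": motion, "residuals": residuals, "betas": betas,
            "amplitudes": amplitudes}


@pytest.fixture(scope="session")
def small_study(small_truth, small_grid, hrf):
    """Six subjects through the full task pipeline on the small grid."""
    return [simulate_subject(small_truth, small_grid, hrf, seed=1000 + 97 * s)
            for s in range(6)]
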