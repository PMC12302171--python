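"""Shared fixtures: a calibrated default cohort and its factorial results.

The full 10-patient trial (calibration + 80 factorial cells) is computed
once per session; most integration and acceptance tests read from it.
"""

from __future__ import annotations

import pytest

from afloop.config import RunConfig
from afloop.pipeline import _cohort_seed, calibrate_cohort
from afloop.protocol import run_factorial
from afloop.virtual_cohort import generate_cohort

MASTER_SEED = 1


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def trial(run_config):
    """Calibrated default cohort plus the full factorial results table."""
    cohort = generate_cohort(
        run_config.n_patients, _cohort_seed(run_config.master_seed), run_config.cohort
    )
    calibration = calibrate_cohort(
        cohort, run_config.calibration, dt=run_config.dt_s
    )
    results = run_factorial(cohort, run_config)
    return {
        "config": run_config,
        "cohort": cohort,
        "calibration": calibration,
        "results": results,
    }


@pytest.fixture(scope="session")
def results_wide(trial):
    """Per-patient wide tables of LVSV / LVEF / EDV by scenario key."""
    res = trial["results"]
    return {
        col: res.pivot(index="patient_id", columns="scenario_key", values=col)
        for col in ("lvsv", "lvef", "edv", "esv")
    }
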