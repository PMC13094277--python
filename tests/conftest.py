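"""Shared fixtures: small synthetic studies and quick MCMC configurations.

Fits are session-scoped so that several tests can interrogate one posterior.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from stormssm.mcmc import McmcConfig
from stormssm.occupancy import OBS_COVARIATES, TransferPrior, fit_ssm
from stormssm.simulate import ScenarioConfig, simulate_study
from stormssm.telemetry_io import (
    CovariateTable,
    DetectionRecord,
    StudyWindow,
    standardize,
)

UTC = timezone.utc


def make_window(start="2023-08-01", hours=24) -> StudyWindow:
    s = pd.Timestamp(start, tz="UTC").to_pydatetime()
    return StudyWindow(start=s, end=s + timedelta(hours=hours))


def make_record(hour_offset: float, receiver="R1", transmitter="S1",
                window: StudyWindow | None = None) -> DetectionRecord:
    start = window.start if window else datetime(2023, 8, 1, tzinfo=UTC)
    return DetectionRecord(
        timestamp=start + timedelta(hours=hour_offset),
        receiver_id=receiver,
        transmitter_id=transmitter,
    )


def random_covariates(window: StudyWindow, rng: np.random.Generator) -> CovariateTable:
    """A covariate table with independent noise columns (for oracle tests)."""
    cols = ("wind", "waves", "sst", "baro", "sal", "turb", "noise", "tilt", "sharks")
    raw = pd.DataFrame(
        {c: rng.normal(10.0, 3.0, window.n_hours) for c in cols}, index=window.hours
    )
    raw.index.name = "hour_start"
    std = pd.DataFrame(index=raw.index)
    records = {}
    for c in cols:
        if window.n_hours < 2:  # degenerate single-hour oracle instances
            from stormssm.telemetry_io import StandardizationRecord

            records[c] = StandardizationRecord(mean=10.0, sd=3.0)
            std[c] = records[c].apply(raw[c].to_numpy())
        else:
            std[c], records[c] = standardize(raw[c].to_numpy(), c)
    return CovariateTable(window=window, raw=raw, standardized=std, records=records)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(
        n_receivers=10, n_sync_tags=5, n_animals=5, window_hours=200,
        storm_start_hour=90, seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def quick_mcmc() -> McmcConfig:
    return McmcConfig(n_chains=2, n_iterations=1200, burn_in=500, thin=2, seed=7)


@pytest.fixture(scope="session")
def truth_transfer(small_config) -> TransferPrior:
    tr = small_config.obs_truth
    return TransferPrior({x: (tr.slope(x), 0.2) for x in OBS_COVARIATES})


@pytest.fixture(scope="session")
def small_ssm_fit(small_study, truth_transfer, quick_mcmc):
    return fit_ssm(
        small_study.animal_matrix, small_study.covariates, truth_transfer,
        variant="full", mcmc_config=quick_mcmc, decode_draws=20,
    )


@pytest.fixture(scope="session")
def small_reduced_fit(small_study, quick_mcmc):
    return fit_ssm(
        small_study.animal_matrix, small_study.covariates, None,
        variant="reduced", mcmc_config=quick_mcmc, decode_draws=20,
    )
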