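"""Shared fixtures: small cohorts for unit tests, and two session-scoped
full pipeline runs (a deterioration cohort and a zero-effect null cohort)
reused across the end-to-end and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from respwatch.workflow import config_from_dict, run_pipeline  # noqa: E402

SIGNAL_SEED = 20210927
NULL_SEED = 1361


def null_config_dict(seed: int = NULL_SEED) -> dict:
    """Zero-signal cohort: no deterioration of means or of RR variability."""
    return {
        "cohort": {
            "n_admissions": 200,
            "event_fraction": 0.25,
            "stay_median_hours": 36.0,
            "stay_log_sd": 0.25,
            "effect_sizes": {"hr": 0.0, "rr": 0.0, "spo2": 0.0, "sbp": 0.0},
            "rr_variability_shrink": 1.0,
        },
        "seed": seed,
    }


def _slim(artifacts: dict) -> dict:
    # raw per-beat series dominate memory; evaluation tests don't need them
    artifacts["n_records"] = len(artifacts.pop("records"))
    return artifacts


@pytest.fixture(scope="session")
def signal_artifacts() -> dict:
    """Full pipeline on the default deterioration cohort (150 admissions,
    ~50 events, 12 h ramp)."""
    cfg = config_from_dict({"seed": SIGNAL_SEED})
    return _slim(run_pipeline(cfg))


@pytest.fixture(scope="session")
def null_artifacts() -> dict:
    """Full pipeline on a cohort with every programmed effect set to zero."""
    cfg = config_from_dict(null_config_dict())
    return _slim(run_pipeline(cfg))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
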