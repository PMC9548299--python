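"""Shared plumbing for the numbered analysis drivers: configuration, result
paths, and the deterministic cohort regeneration that lets each script run
standalone without storing the multi-gigabyte beat-level series on disk."""

from __future__ import annotations

import dataclasses
from pathlib import Path

from respwatch.cohort import generate_cohort
from respwatch.workflow import RunConfig, load_config, stage_seed

HERE = Path(__file__).resolve().parent
ROOT = HERE.parent
CONFIG_PATH = HERE / "config.yaml"
RESULTS = ROOT / "results"


def load_run_config() -> RunConfig:
    return load_config(CONFIG_PATH)


def results_dir(sub: str = "") -> Path:
    d = RESULTS / sub if sub else RESULTS
    d.mkdir(parents=True, exist_ok=True)
    return d


def regenerate_cohort(config: RunConfig):
    """The cohort is a pure function of config + seed; regenerating it is
    cheap (seconds) and avoids persisting per-beat series between scripts."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, 0))
    return generate_cohort(cohort_cfg)
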