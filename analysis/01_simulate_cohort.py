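"""Simulate the synthetic ICU cohort.

Generates the study cohort — admissions with continuous vitals and
beat-to-beat RR intervals, a third of them deteriorating over the 12 h
before an emergent intubation, plus sparse ventilator-flowsheet charting
and DNI exclusions — and writes the admission-level tables under
results/cohort/.  The per-beat series are not persisted (they are pure
functions of the seed and are regenerated by later scripts); pass
--full-series to write them too.
"""

import sys

import numpy as np

from common import load_run_config, regenerate_cohort, results_dir
from respwatch import io as rio
from respwatch.workflow import config_hash


def main() -> None:
    full = "--full-series" in sys.argv
    cfg = load_run_config()
    records = regenerate_cohort(cfg)
    out = results_dir("cohort")
    meta = f"config_hash={config_hash(cfg)} seed={cfg.seed}"
    rio.write_cohort(records, out, meta, full_series=full)

    events = [r for r in records if r.event_time is not None]
    durations = np.array([r.duration for r in records]) / 60.0
    print(f"cohort: {len(records)} admissions -> {out}")
    print(f"  events: {len(events)}, DNI: {sum(r.dni for r in records)}")
    print(f"  stay hours: median {np.median(durations):.1f}, "
          f"IQR {np.percentile(durations, 25):.1f}-{np.percentile(durations, 75):.1f}")
    lead = np.array([r.event_time for r in events]) / 60.0
    print(f"  pre-event observation: median {np.median(lead):.1f} h "
          f"(all >= {lead.min():.1f} h)")
    n_fs = sum(len(r.flowsheet) for r in records)
    print(f"  flowsheet entries: {n_fs} across "
          f"{sum(bool(r.flowsheet) for r in records)} ventilated admissions")


if __name__ == "__main__":
    main()
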