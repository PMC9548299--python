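"""Delimited-table input/output for every pipeline stage.

All tables are UTF-8 CSV with a mandatory header row; missing values are
empty fields.  Schemas:

* ``admissions.csv`` — admission_id, duration_min, event_time_min, dni
* ``vitals.csv`` — admission_id, t_min, hr, rr, spo2, sbp
* ``rr_intervals.csv`` — admission_id, beat_time_min, rr_ms (one row per
  beat; the first beat of an admission has an empty rr_ms)
* ``flowsheet.csv`` — admission_id, t_min, vent_rr
* ``truth_epochs.csv`` / ``epochs.csv`` — admission_id, start_min, end_min
* ``censor.csv`` — admission_id, t_min, censored
* ``features.csv`` — admission_id, window_end_min, one column per feature
  (+ one ``*_imputed`` flag per feature once imputed)
* ``risk.csv`` — admission_id, window_end_min, relative_risk, censored

Writers accept an optional metadata line (config hash, seed) emitted as a
leading ``#`` comment; readers skip ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AdmissionRecord, RRIntervalSeries, VitalsSeries
from .vent_epochs import FlowsheetEntry, VentilationEpoch

__all__ = [
    "write_csv",
    "read_csv",
    "write_cohort",
    "read_cohort",
    "epochs_to_frame",
    "frame_to_epochs",
]


def write_csv(df: pd.DataFrame, path: Path | str, meta: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def read_csv(path: Path | str, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, comment="#", **kwargs)


def write_cohort(
    records: Sequence[AdmissionRecord],
    outdir: Path | str,
    meta: str | None = None,
    full_series: bool = True,
) -> None:
    """Write a cohort as the delimited tables above.

    ``full_series=False`` skips the (large) vitals and RR-interval tables,
    keeping only the admission-level tables; useful when downstream stages
    regenerate the series deterministically from the config seed.
    """
    outdir = Path(outdir)
    adm = pd.DataFrame(
        {
            "admission_id": [r.admission_id for r in records],
            "duration_min": [r.duration for r in records],
            "event_time_min": [r.event_time for r in records],
            "dni": [int(r.dni) for r in records],
        }
    )
    write_csv(adm, outdir / "admissions.csv", meta)

    fs_rows = [
        {"admission_id": r.admission_id, "t_min": e.time, "vent_rr": e.value}
        for r in records
        for e in r.flowsheet
    ]
    write_csv(
        pd.DataFrame(fs_rows, columns=["admission_id", "t_min", "vent_rr"]),
        outdir / "flowsheet.csv",
        meta,
    )
    truth = epochs_to_frame({r.admission_id: r.truth_vent_epochs for r in records})
    write_csv(truth, outdir / "truth_epochs.csv", meta)

    if full_series:
        vit = pd.concat(
            [
                pd.DataFrame(
                    {
                        "admission_id": r.admission_id,
                        "t_min": r.vitals.timestamps,
                        "hr": r.vitals.hr,
                        "rr": r.vitals.rr,
                        "spo2": r.vitals.spo2,
                        "sbp": r.vitals.sbp,
                    }
                )
                for r in records
            ],
            ignore_index=True,
        ) if records else pd.DataFrame(
            columns=["admission_id", "t_min", "hr", "rr", "spo2", "sbp"]
        )
        write_csv(vit, outdir / "vitals.csv", meta)
        rr = pd.concat(
            [
                pd.DataFrame(
                    {
                        "admission_id": r.admission_id,
                        "beat_time_min": r.rr_intervals.beat_times,
                        "rr_ms": np.concatenate([[np.nan], r.rr_intervals.intervals]),
                    }
                )
                for r in records
            ],
            ignore_index=True,
        ) if records else pd.DataFrame(columns=["admission_id", "beat_time_min", "rr_ms"])
        write_csv(rr, outdir / "rr_intervals.csv", meta)


def read_cohort(indir: Path | str) -> list[AdmissionRecord]:
    """Rebuild admission records from the cohort tables (series required)."""
    indir = Path(indir)
    adm = read_csv(indir / "admissions.csv")
    vit = read_csv(indir / "vitals.csv")
    rr = read_csv(indir / "rr_intervals.csv")
    fs = read_csv(indir / "flowsheet.csv")
    truth_path = indir / "truth_epochs.csv"
    truth = read_csv(truth_path) if truth_path.exists() else None

    records = []
    for row in adm.itertuples(index=False):
        a = row.admission_id
        v = vit[vit["admission_id"] == a]
        vitals = VitalsSeries(
            timestamps=v["t_min"].to_numpy(float),
            hr=v["hr"].to_numpy(float),
            rr=v["rr"].to_numpy(float),
            spo2=v["spo2"].to_numpy(float),
            sbp=v["sbp"].to_numpy(float),
        )
        r = rr[rr["admission_id"] == a]
        rri = RRIntervalSeries(
            beat_times=r["beat_time_min"].to_numpy(float),
            intervals=r["rr_ms"].to_numpy(float)[1:],
        )
        f = fs[fs["admission_id"] == a]
        flow = [FlowsheetEntry(t, v_) for t, v_ in zip(f["t_min"], f["vent_rr"])]
        tv: list[VentilationEpoch] = []
        if truth is not None:
            t = truth[truth["admission_id"] == a]
            tv = [VentilationEpoch(s, e) for s, e in zip(t["start_min"], t["end_min"])]
        ev = row.event_time_min
        records.append(
            AdmissionRecord(
                admission_id=a,
                duration=float(row.duration_min),
                event_time=None if pd.isna(ev) else float(ev),
                dni=bool(row.dni),
                vitals=vitals,
                rr_intervals=rri,
                flowsheet=flow,
                truth_vent_epochs=tv,
            )
        )
    return records


def epochs_to_frame(epochs: Mapping[str, Iterable[VentilationEpoch]]) -> pd.DataFrame:
    rows = [
        {"admission_id": a, "start_min": e.start, "end_min": e.end}
        for a, eps in epochs.items()
        for e in eps
    ]
    return pd.DataFrame(rows, columns=["admission_id", "start_min", "end_min"])


def frame_to_epochs(df: pd.DataFrame) -> dict[str, list[VentilationEpoch]]:
    out: dict[str, list[VentilationEpoch]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.admission_id, []).append(
            VentilationEpoch(float(row.start_min), float(row.end_min))
        )
    return out
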