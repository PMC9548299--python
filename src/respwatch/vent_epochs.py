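"""Reconstruction of mechanical-ventilation epochs from flowsheet data.

Respiratory therapists chart the ventilator respiratory rate only every few
hours, so the start and end of mechanical ventilation must be inferred from
sparse timestamped entries.  A run of entries whose consecutive gaps do not
exceed ``split_gap`` (default 16 h) forms one ventilation epoch spanning the
first to the last entry of the run; an isolated entry opens a 1 h epoch.
Known emergent-intubation times are then reconciled with the reconstructed
epochs so that every verified event starts an epoch exactly at the event
time, with extubation placed at the last charted entry preceding it.

Epochs are the censoring unit: feature windows that fall inside a
ventilation epoch (closed on both ends), or belong to a patient under a
do-not-intubate order, are excluded from modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FlowsheetEntry",
    "VentilationEpoch",
    "EpochRules",
    "build_epochs",
    "split_at_intubation",
    "censor_mask",
]


@dataclass(frozen=True)
class FlowsheetEntry:
    """One ventilator-respiratory-rate charting event.

    time
        Minutes from admission.
    value
        Ventilator respiratory rate in breaths/min.
    """

    time: float
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"flowsheet entry time must be >= 0, got {self.time}")
        if self.value < 0:
            raise ValueError(f"ventilator respiratory rate must be >= 0, got {self.value}")


@dataclass(frozen=True)
class VentilationEpoch:
    """A reconstructed interval of mechanical ventilation, minutes from admission."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"epoch start must precede end, got [{self.start}, {self.end}]")

    def contains(self, t: float) -> bool:
        # closed on both ends: a window stamped exactly at extubation is censored
        return self.start <= t <= self.end


@dataclass(frozen=True)
class EpochRules:
    """Thresholds of the epoch-building rule.

    split_gap_hours
        Consecutive entries farther apart than this belong to different
        epochs (default 16 h).
    isolated_duration_hours
        Length assigned to an epoch seeded by a single isolated entry
        (default 1 h).
    """

    split_gap_hours: float = 16.0
    isolated_duration_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.split_gap_hours <= 0:
            raise ValueError("split_gap_hours must be > 0")
        if self.isolated_duration_hours <= 0:
            raise ValueError("isolated_duration_hours must be > 0")

    @property
    def split_gap_min(self) -> float:
        return self.split_gap_hours * 60.0

    @property
    def isolated_duration_min(self) -> float:
        return self.isolated_duration_hours * 60.0


def _entry_times(entries: Iterable[FlowsheetEntry | float]) -> np.ndarray:
    times = np.asarray(
        [e.time if isinstance(e, FlowsheetEntry) else float(e) for e in entries],
        dtype=float,
    )
    if times.size and times.min() < 0:
        raise ValueError("flowsheet entry times must be >= 0")
    return np.unique(times)  # sorted; duplicate charting timestamps collapse


def build_epochs(
    entries: Sequence[FlowsheetEntry | float],
    rules: EpochRules = EpochRules(),
) -> list[VentilationEpoch]:
    """Group flowsheet entries into ventilation epochs.

    Entries are sorted, then split wherever the gap between consecutive
    entries is strictly larger than ``rules.split_gap_hours``.  Each group
    yields an epoch from its first to its last entry; a singleton group
    yields ``[t, t + isolated_duration]``.

    Parameters
    ----------
    entries
        Flowsheet entries (or bare times in minutes); sorted internally.
    rules
        Split-gap and isolated-entry thresholds.

    Returns
    -------
    Disjoint, sorted ventilation epochs.  Empty input gives an empty list.
    """
    times = _entry_times(entries)
    if times.size == 0:
        return []
    # boundaries where the gap exceeds the split threshold (strict >)
    gaps = np.diff(times)
    cut = np.flatnonzero(gaps > rules.split_gap_min)
    groups = np.split(times, cut + 1)
    epochs: list[VentilationEpoch] = []
    for g in groups:
        if g.size == 1:
            epochs.append(VentilationEpoch(g[0], g[0] + rules.isolated_duration_min))
        else:
            epochs.append(VentilationEpoch(g[0], g[-1]))
    return _merge_overlaps(epochs)


def _merge_overlaps(epochs: Iterable[VentilationEpoch]) -> list[VentilationEpoch]:
    """Union of possibly-overlapping epochs; ties broken toward longer censoring."""
    eps = sorted(epochs, key=lambda e: (e.start, e.end))
    merged: list[VentilationEpoch] = []
    for e in eps:
        if merged and e.start <= merged[-1].end:
            last = merged.pop()
            merged.append(VentilationEpoch(last.start, max(last.end, e.end)))
        else:
            merged.append(e)
    return merged


def split_at_intubation(
    epochs: Sequence[VentilationEpoch],
    entries: Sequence[FlowsheetEntry | float],
    event_times: Sequence[float],
    rules: EpochRules = EpochRules(),
    admission_end: float | None = None,
) -> list[VentilationEpoch]:
    """Reconcile reconstructed epochs with verified emergent-intubation times.

    Every verified event must begin a ventilation epoch at exactly the event
    time.  When an event falls strictly inside a reconstructed epoch, the
    epoch is split: the earlier part ends at the last flowsheet entry before
    the event (the inferred extubation), the later part starts at the event.
    When an event falls in no epoch, a new epoch is opened from the event to
    the next flowsheet entry, or for the isolated duration if none follows;
    epochs that come to overlap are merged (longer censoring wins).

    Parameters
    ----------
    epochs
        Output of :func:`build_epochs` for the same entries.
    entries
        The flowsheet entries the epochs were built from.
    event_times
        Verified emergent-intubation times, minutes from admission, sorted.
    admission_end
        Optional admission duration; events beyond it raise ``ValueError``.
    """
    times = _entry_times(entries)
    out = list(epochs)
    for t in sorted(float(t) for t in event_times):
        if t < 0:
            raise ValueError(f"event time must be >= 0, got {t}")
        if admission_end is not None and t > admission_end:
            raise ValueError(f"event time {t} is after admission end {admission_end}")
        host = next((e for e in out if e.start < t <= e.end), None)
        if host is not None:
            out.remove(host)
            prev = times[(times >= host.start) & (times < t)]
            if prev.size and prev[-1] > host.start:
                out.append(VentilationEpoch(host.start, prev[-1]))
            # (when only the opening entry precedes the event the earlier
            # part collapses to a point and is dropped)
            if t < host.end:
                tail_end = host.end
            else:  # event at the epoch's last entry: re-intubation there
                nxt = times[times > t]
                tail_end = float(nxt[0]) if nxt.size else t + rules.isolated_duration_min
            out.append(VentilationEpoch(t, tail_end))
        elif any(e.start == t for e in out):
            continue  # epoch already starts at the event
        else:
            nxt = times[times > t]
            end = float(nxt[0]) if nxt.size else t + rules.isolated_duration_min
            out.append(VentilationEpoch(t, end))
    return _merge_overlaps(out)


def censor_mask(
    epoch_times: Sequence[float],
    vent_epochs: Sequence[VentilationEpoch],
    dni: bool = False,
) -> np.ndarray:
    """Boolean mask over feature-epoch timestamps: True where censored.

    A timestamp is censored when it lies inside any ventilation epoch
    (closed ``[start, end]``) or when the admission is under a DNI order.
    """
    times = np.asarray(epoch_times, dtype=float)
    if dni:
        return np.ones(times.shape, dtype=bool)
    mask = np.zeros(times.shape, dtype=bool)
    for e in vent_epochs:
        mask |= (times >= e.start) & (times <= e.end)
    return mask
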