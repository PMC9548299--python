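"""Synthetic ICU cohort generator with programmable pre-intubation deterioration.

No patient-level data from the validation study are deposited, so every
downstream stage is exercised on simulated admissions that carry the
statistical structure the analysis assumes:

* control admissions with stationary AR(1) vital signs around fixed
  baselines and white beat-to-beat RR-interval variability;
* event admissions whose channel means ramp linearly over the final
  ``ramp_hours`` before emergent intubation (rising heart and respiratory
  rate, falling SpO2 and blood pressure) while RR-interval variability
  shrinks multiplicatively — the slowly progressive, multi-hour
  deterioration the risk models are designed to detect;
* sparse respiratory-therapist flowsheet documentation of the ventilator
  respiratory rate (gaps of one to a few hours) inside true ventilation
  epochs, from which the censoring epochs must be reconstructed;
* DNI admissions to exclude, and optional ventilated controls.

Ground truth (event times, true ventilation epochs, programmed effect
sizes) is retained on each record so tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import logging

import numpy as np
from scipy.signal import lfilter

from .vent_epochs import FlowsheetEntry, VentilationEpoch

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "VitalsSeries",
    "RRIntervalSeries",
    "AdmissionRecord",
    "DeteriorationRamp",
    "generate_cohort",
    "simulate_vitals",
    "simulate_rr_intervals",
    "simulate_flowsheet",
]

CHANNELS = ("hr", "rr", "spo2", "sbp")

RR_FLOOR_MS = 200.0  # physiological floor; sampled intervals are clipped here


@dataclass(frozen=True)
class DeteriorationRamp:
    """Linear pre-event deterioration: channel means shift from 0 to
    ``effect`` between ``event_time - ramp_hours`` and ``event_time`` and
    hold thereafter."""

    event_time_min: float
    ramp_hours: float

    def fraction(self, t_min: np.ndarray) -> np.ndarray:
        """Ramp fraction in [0, 1] at times ``t_min``."""
        ramp_min = self.ramp_hours * 60.0
        f = (np.asarray(t_min, dtype=float) - (self.event_time_min - ramp_min)) / ramp_min
        return np.clip(f, 0.0, 1.0)


@dataclass(frozen=True)
class VitalsSeries:
    """Per-minute vital signs: heart rate (bpm), respiratory rate
    (breaths/min), SpO2 (%), systolic blood pressure (mmHg)."""

    timestamps: np.ndarray
    hr: np.ndarray
    rr: np.ndarray
    spo2: np.ndarray
    sbp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("vitals timestamps must be strictly increasing")
        for name in CHANNELS:
            v = getattr(self, name)
            if len(v) != t.size:
                raise ValueError(f"channel {name} length mismatch")
        s = np.asarray(self.spo2, dtype=float)
        if np.any((s[np.isfinite(s)] < 0) | (s[np.isfinite(s)] > 100)):
            raise ValueError("SpO2 must lie in [0, 100]")
        for name in ("hr", "rr", "sbp"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RRIntervalSeries:
    """Beat times (minutes from admission) and the RR interval (ms)
    preceding each beat after the first."""

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        x = np.asarray(self.intervals, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if x.size != max(t.size - 1, 0):
            raise ValueError("need one interval per beat after the first")
        if np.any(x <= 0):
            raise ValueError("RR intervals must be > 0")
        if x.size and not np.allclose(np.diff(t) * 60000.0, x, atol=0.51):
            raise ValueError("intervals inconsistent with beat times")


@dataclass(frozen=True)
class AdmissionRecord:
    """One simulated ICU admission with ground truth attached."""

    admission_id: str
    duration: float  # minutes
    event_time: float | None
    dni: bool
    vitals: VitalsSeries
    rr_intervals: RRIntervalSeries
    flowsheet: list[FlowsheetEntry]
    truth_vent_epochs: list[VentilationEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_time is not None and not (0 < self.event_time <= self.duration):
            raise ValueError("event_time must lie in (0, duration]")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe a desk-scale cohort with enough events (~50) for
    event-aligned averaging: 150 admissions, a third of them ending in
    emergent intubation after a 12 h linear deterioration, 5% DNI,
    lognormal stays with median ~48 h (clipped at 30 h so every event
    admission has a >=24 h pre-event observation window), flowsheet
    charting every 1-6 h during ventilation.
    """

    n_admissions: int = 150
    event_fraction: float = 1 / 3
    dni_fraction: float = 0.05
    stay_median_hours: float = 48.0
    stay_log_sd: float = 0.35
    stay_min_hours: float = 30.0
    ramp_hours: float = 12.0
    baselines: dict = field(
        default_factory=lambda: {"hr": 85.0, "rr": 18.0, "spo2": 97.0, "sbp": 120.0}
    )
    effect_sizes: dict = field(
        default_factory=lambda: {"hr": 15.0, "rr": 10.0, "spo2": -6.0, "sbp": -15.0}
    )
    rr_variability_shrink: float = 0.4
    mean_rr_ms: float = 800.0
    sd_rr_ms: float = 50.0
    ar_coefficient: float = 0.9
    noise_sd: dict = field(
        default_factory=lambda: {"hr": 3.0, "rr": 2.0, "spo2": 1.0, "sbp": 6.0}
    )
    doc_interval_hours: tuple[float, float] = (1.0, 6.0)
    missing_rate: float = 0.02
    control_vent_fraction: float = 0.0
    allow_multiple_events: bool = False
    second_event_prob: float = 0.15
    post_event_vent_hours: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_admissions < 0:
            raise ValueError("n_admissions must be >= 0")
        for name in ("event_fraction", "dni_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.event_fraction + self.dni_fraction > 1:
            raise ValueError("event_fraction + dni_fraction must be <= 1")
        if self.ramp_hours <= 0:
            raise ValueError("ramp_hours must be > 0")
        if not 0 < self.rr_variability_shrink <= 1:
            raise ValueError("rr_variability_shrink must lie in (0, 1]")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be > 0")
        if self.sd_rr_ms < 0:
            raise ValueError("sd_rr_ms must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.doc_interval_hours
        if not 0 < lo <= hi:
            raise ValueError("doc_interval_hours must satisfy 0 < lo <= hi")
        if set(self.baselines) != set(CHANNELS) or set(self.effect_sizes) != set(
            CHANNELS
        ) or set(self.noise_sd) != set(CHANNELS):
            raise ValueError(f"baselines/effect_sizes/noise_sd must cover {CHANNELS}")


def _ar1(n: int, ar: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` and lag-1
    autocorrelation ``ar``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - ar**2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = lfilter([1.0], [1.0, -ar], e)
    x += rng.normal(0.0, sd) * ar ** np.arange(1, n + 1)  # stationary start
    return x


def simulate_vitals(
    duration: float,
    baselines: dict,
    deterioration: DeteriorationRamp | None,
    effect_sizes: dict | None,
    ar: float,
    noise_sd: dict,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> VitalsSeries:
    """AR(1) vital signs at one sample per minute, with optional linear
    pre-event deterioration of the channel means.

    ``noise_sd`` is the stationary (marginal) SD per channel; the AR(1)
    innovation SD is scaled so the lag-1 autocorrelation equals ``ar``.
    SpO2 is clipped to [0, 100], other channels at 0.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if any(v < 0 for v in noise_sd.values()):
        raise ValueError("noise_sd values must be >= 0")
    t = np.arange(0.0, duration + 1e-9, 1.0)
    chans: dict[str, np.ndarray] = {}
    for c in CHANNELS:
        x = baselines[c] + _ar1(t.size, ar, noise_sd[c], rng)
        if deterioration is not None and effect_sizes is not None:
            x = x + effect_sizes[c] * deterioration.fraction(t)
        if missing_rate > 0:
            drop = rng.random(t.size) < missing_rate
            x = np.where(drop, np.nan, x)
        chans[c] = x
    chans["spo2"] = np.clip(chans["spo2"], 0.0, 100.0)
    for c in ("hr", "rr", "sbp"):
        chans[c] = np.clip(chans[c], 0.0, None)
    return VitalsSeries(timestamps=t, **chans)


def simulate_rr_intervals(
    duration: float,
    mean_rr: float,
    sd_rr: float,
    deterioration: DeteriorationRamp | None,
    shrink: float,
    rng: np.random.Generator,
) -> RRIntervalSeries:
    """Beat-to-beat RR intervals with optionally shrinking variability.

    Intervals are drawn independently from a normal distribution whose SD
    ramps multiplicatively from ``sd_rr`` down to ``sd_rr * shrink`` over
    the deterioration ramp; beat times accumulate from the sampled
    intervals.  Intervals are clipped at a 200 ms physiological floor
    (clips are logged).
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    if sd_rr < 0:
        raise ValueError("sd_rr must be >= 0")
    dur_ms = duration * 60000.0
    times_ms: list[np.ndarray] = [np.array([0.0])]
    intervals: list[np.ndarray] = []
    t = 0.0
    n_clipped = 0
    chunk = 20000
    while t < dur_ms:
        # project beat times ahead to evaluate the time-varying SD
        proj = t + np.arange(1, chunk + 1) * mean_rr
        sd = np.full(chunk, sd_rr)
        if deterioration is not None:
            frac = deterioration.fraction(proj / 60000.0)
            sd = sd_rr * (1.0 - (1.0 - shrink) * frac)
        x = rng.normal(mean_rr, sd) if sd_rr > 0 else np.full(chunk, mean_rr)
        clipped = x < RR_FLOOR_MS
        n_clipped += int(clipped.sum())
        x = np.maximum(x, RR_FLOOR_MS)
        tt = t + np.cumsum(x)
        keep = tt <= dur_ms
        intervals.append(x[keep])
        times_ms.append(tt[keep])
        if not keep.all():
            break
        t = tt[-1]
    if n_clipped:
        logger.info("simulate_rr_intervals: clipped %d intervals at %.0f ms", n_clipped, RR_FLOOR_MS)
    beat_times = np.concatenate(times_ms) / 60000.0
    x = np.concatenate(intervals) if intervals else np.empty(0)
    return RRIntervalSeries(beat_times=beat_times, intervals=x)


def simulate_flowsheet(
    truth_epochs: Sequence[VentilationEpoch],
    doc_interval_hours: tuple[float, float],
    rng: np.random.Generator,
    vent_rr: float = 14.0,
) -> list[FlowsheetEntry]:
    """Sparse ventilator-respiratory-rate charting inside true epochs.

    Entries are placed at each epoch's boundaries with intermediate gaps
    drawn uniformly from ``doc_interval_hours`` (the final gap is whatever
    remains, never longer than the maximum).  Raises ``ValueError`` on
    overlapping epochs.
    """
    eps = sorted(truth_epochs, key=lambda e: e.start)
    for a, b in zip(eps, eps[1:]):
        if b.start <= a.end:
            raise ValueError("truth ventilation epochs must be disjoint")
    lo, hi = (h * 60.0 for h in doc_interval_hours)
    entries: list[FlowsheetEntry] = []
    for e in eps:
        t = e.start
        entries.append(FlowsheetEntry(t, vent_rr))
        while True:
            t = t + rng.uniform(lo, hi)
            if t >= e.end:
                break
            entries.append(FlowsheetEntry(t, vent_rr))
        if entries[-1].time < e.end:
            entries.append(FlowsheetEntry(e.end, vent_rr))
    return entries


def _simulate_admission(
    admission_id: str,
    config: CohortConfig,
    kind: str,
    rng: np.random.Generator,
) -> AdmissionRecord:
    """One admission of kind 'control', 'event' or 'dni'."""
    dur_h = np.exp(rng.normal(np.log(config.stay_median_hours), config.stay_log_sd))
    dur_h = max(dur_h, config.stay_min_hours)
    duration = dur_h * 60.0

    event_time: float | None = None
    truth_epochs: list[VentilationEpoch] = []
    if kind == "event":
        # uniform in [24 h, duration - 1 h] so a pre-event day is observed
        # and the post-event ventilation epoch is non-degenerate
        event_time = float(rng.uniform(24 * 60.0, duration - 60.0))
        vent_end = min(event_time + config.post_event_vent_hours * 60.0, duration)
        truth_epochs.append(VentilationEpoch(event_time, vent_end))
        if (
            config.allow_multiple_events
            and duration - vent_end > (config.ramp_hours + 6.0) * 60.0
            and rng.random() < config.second_event_prob
        ):
            # a later, second respiratory-failure event after extubation
            second = float(rng.uniform(vent_end + config.ramp_hours * 60.0, duration - 60.0))
            truth_epochs.append(
                VentilationEpoch(second, min(second + config.post_event_vent_hours * 60.0, duration))
            )
    elif kind == "control" and rng.random() < config.control_vent_fraction:
        # a planned (non-emergent) ventilation episode to censor
        vdur = rng.uniform(6 * 60.0, 24 * 60.0)
        vstart = rng.uniform(0.0, max(duration - vdur, 1.0))
        truth_epochs.append(VentilationEpoch(vstart, min(vstart + vdur, duration)))

    ramp = (
        DeteriorationRamp(event_time, config.ramp_hours) if event_time is not None else None
    )
    vitals = simulate_vitals(
        duration,
        config.baselines,
        ramp,
        config.effect_sizes if ramp is not None else None,
        config.ar_coefficient,
        config.noise_sd,
        rng,
        config.missing_rate,
    )
    rr = simulate_rr_intervals(
        duration,
        config.mean_rr_ms,
        config.sd_rr_ms,
        ramp,
        config.rr_variability_shrink,
        rng,
    )
    flowsheet = simulate_flowsheet(truth_epochs, config.doc_interval_hours, rng)
    return AdmissionRecord(
        admission_id=admission_id,
        duration=duration,
        event_time=event_time,
        dni=(kind == "dni"),
        vitals=vitals,
        rr_intervals=rr,
        flowsheet=flowsheet,
        truth_vent_epochs=truth_epochs,
    )


def generate_cohort(config: CohortConfig) -> list[AdmissionRecord]:
    """Generate the synthetic cohort: deterministic for a fixed config seed.

    Exactly ``round(n * event_fraction)`` admissions carry an emergent
    intubation with deterioration over the final ``ramp_hours``;
    ``round(n * dni_fraction)`` are flagged DNI; the rest are controls.
    """
    n = config.n_admissions
    if n == 0:
        return []
    n_event = int(round(n * config.event_fraction))
    n_dni = int(round(n * config.dni_fraction))
    if n_event + n_dni > n:
        n_dni = n - n_event
    kinds = ["event"] * n_event + ["dni"] * n_dni + ["control"] * (n - n_event - n_dni)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n + 1)
    assign_rng = np.random.default_rng(children[0])
    order = assign_rng.permutation(n)
    kinds = [kinds[i] for i in order]
    records = []
    width = max(4, len(str(n)))
    for i, (kind, child) in enumerate(zip(kinds, children[1:])):
        rng = np.random.default_rng(child)
        records.append(_simulate_admission(f"adm{i:0{width}d}", config, kind, rng))
    return records
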