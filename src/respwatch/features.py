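"""Cardiorespiratory predictors computed in overlapping 30-minute windows.

Predictors follow the continuous-monitoring risk-model family for emergent
intubation: per-window means and standard deviations of the four vital
signs (heart rate, respiratory rate, SpO2, systolic blood pressure),
zero-lag Pearson cross-correlations between each vital-sign pair, and three
measures of cardiac dynamics computed from beat-to-beat RR intervals —

* SDNN, the sample standard deviation of RR intervals;
* COSEn, the coefficient of sample entropy,
  ``SampEn(m, r) + ln(2 r) - ln(mean RR)`` with r and RR in ms, an entropy
  rate that is comparable across records of different lengths;
* the slope of log RR-interval fluctuation variance versus log box size from
  detrended fluctuation analysis (so iid intervals give a slope near 1,
  twice the conventional scaling exponent alpha of 0.5).

Windows are 30 min wide with 50% overlap, i.e. one feature vector every
15 min, stamped at the window end.  Windows with too few vital-sign samples
or too few beats yield missing values; missing features are later imputed
with medians from the development split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureParams",
    "CHANNELS",
    "CHANNEL_PAIRS",
    "FEATURE_NAMES",
    "iter_windows",
    "window_vitals_stats",
    "window_cross_correlations",
    "sample_entropy",
    "cosen",
    "dfa_variance_slope",
    "sdnn",
    "impute_missing",
    "feature_medians",
    "compute_admission_features",
]

CHANNELS: tuple[str, ...] = ("hr", "rr", "spo2", "sbp")
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("hr", "rr"),
    ("hr", "spo2"),
    ("hr", "sbp"),
    ("rr", "spo2"),
    ("rr", "sbp"),
    ("spo2", "sbp"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{c}_{s}" for c in CHANNELS for s in ("mean", "sd")]
    + [f"xcorr_{a}_{b}" for a, b in CHANNEL_PAIRS]
    + ["sdnn", "cosen", "dfa_slope"]
)


@dataclass(frozen=True)
class FeatureParams:
    """Windowing and cardiac-dynamics parameters.

    window_width_min / step_min
        30-minute windows with 50% overlap by default.
    sampen_m, sampen_r_ms
        Sample-entropy template length and tolerance (ms).
    dfa_scales
        Box sizes in beats for the detrended-fluctuation variance slope.
    dfa_use_squared
        Regress log F^2(n) on log n (default) rather than log F(n); the
        default makes the iid-noise reference slope 1.0.
    min_samples_per_window / min_beats_per_window
        Below these counts a window's vitals / cardiac features are missing.
    """

    window_width_min: float = 30.0
    step_min: float = 15.0
    sampen_m: int = 1
    sampen_r_ms: float = 30.0
    dfa_scales: tuple[int, ...] = (4, 8, 16, 32, 64)
    dfa_use_squared: bool = True
    min_samples_per_window: int = 10
    min_beats_per_window: int = 100

    def __post_init__(self) -> None:
        if self.window_width_min <= 0 or self.step_min <= 0:
            raise ValueError("window_width_min and step_min must be > 0")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r_ms <= 0:
            raise ValueError("sampen_r_ms must be > 0")
        scales = tuple(self.dfa_scales)
        if any(s < 4 for s in scales) or any(
            b <= a for a, b in zip(scales, scales[1:])
        ):
            raise ValueError("dfa_scales must be increasing and each >= 4")


def iter_windows(
    t_start: float, t_end: float, params: FeatureParams = FeatureParams()
) -> list[tuple[float, float]]:
    """Sliding windows ``[e - width, e]`` for ends on the step grid.

    Ends run ``t_start + width, t_start + width + step, ...`` up to and
    including ``t_end``.  A span shorter than one window yields an empty
    list.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    w, s = params.window_width_min, params.step_min
    ends = np.arange(t_start + w, t_end + 1e-9, s)
    return [(float(e - w), float(e)) for e in ends]


# ---------------------------------------------------------------------------
# vital-sign window statistics


def window_vitals_stats(
    values: np.ndarray, min_samples: int = 10
) -> tuple[float, float]:
    """Sample mean and SD (ddof=1) of the non-missing samples in a window.

    Returns ``(nan, nan)`` when fewer than ``min_samples`` samples are
    present: missingness is data, not an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < max(min_samples, 2):
        return np.nan, np.nan
    return float(np.mean(x)), float(np.std(x, ddof=1))


def window_cross_correlations(
    a: np.ndarray, b: np.ndarray, min_samples: int = 10
) -> float:
    """Zero-lag Pearson correlation over pairwise-complete samples.

    Missing (nan) when the pairwise-complete overlap is below
    ``min_samples`` or either channel is constant over the overlap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_samples:
        return np.nan
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against rounding slightly outside [-1, 1]
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# sample entropy / COSEn

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _sampen_counts_m1(x: np.ndarray, r: float) -> tuple[int, int]:
        # m = 1 fast path: visit only first-component matches in sorted order
        n = x.shape[0]
        order = np.argsort(x)  # B domain: all n length-1 templates
        xs = x[order]
        b_count = 0
        a_count = 0
        for p in range(n - 1):
            q = p + 1
            while q < n and xs[q] - xs[p] <= r:
                b_count += 1
                i = order[p]
                j = order[q]
                # A domain: starts 0..n-2 so the (m+1)-template exists
                if i < n - 1 and j < n - 1 and abs(x[i + 1] - x[j + 1]) <= r:
                    a_count += 1
                q += 1
        return a_count, b_count

    @njit(cache=True)
    def _sampen_counts_generic(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        n = x.shape[0]
        nb = n - m + 1  # starts of length-m templates
        na = n - m  # starts of length-(m+1) templates
        b_count = 0
        a_count = 0
        for i in range(nb):
            for j in range(i + 1, nb):
                match = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        match = False
                        break
                if match:
                    b_count += 1
                    if j < na and abs(x[i + m] - x[j + m]) <= r:
                        a_count += 1
        return a_count, b_count

    def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        if m == 1:
            return _sampen_counts_m1(x, r)
        return _sampen_counts_generic(x, m, r)

except ImportError:  # pragma: no cover

    def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        n = x.shape[0]
        nb = n - m + 1
        na = n - m
        b_count = 0
        a_count = 0
        for i in range(nb - 1):
            js = np.arange(i + 1, nb)
            row = np.ones(js.size, dtype=bool)
            for k in range(m):
                row &= np.abs(x[i + k] - x[js + k]) <= r
            b_count += int(row.sum())
            if i < na:
                js_a = js[row & (js < na)]
                a_count += int(np.sum(np.abs(x[i + m] - x[js_a + m]) <= r))
        return a_count, b_count


def sample_entropy(intervals: Sequence[float], m: int = 1, r: float = 30.0) -> float:
    """Sample entropy ``-ln(A/B)`` of a series, Chebyshev distance.

    ``A`` counts non-self template pairs of length ``m + 1`` matching within
    tolerance ``r``; ``B`` the same for length ``m``.  Each count runs over
    all valid template start positions for its own length, so the shorter
    templates at the end of the record enter ``B`` only.  Missing (nan) when
    either count is zero or the series is shorter than ``m + 2``.
    """
    x = np.ascontiguousarray(intervals, dtype=float)
    if x.size < m + 2:
        logger.debug("sample_entropy: series length %d < m+2=%d", x.size, m + 2)
        return np.nan
    if r <= 0:
        raise ValueError("tolerance r must be > 0")
    a_count, b_count = _sampen_counts(x, m, float(r))
    if a_count == 0 or b_count == 0:
        logger.debug("sample_entropy: no template matches (A=%d, B=%d)", a_count, b_count)
        return np.nan
    return float(-np.log(a_count / b_count))


def cosen(intervals: Sequence[float], m: int = 1, r: float = 30.0) -> float:
    """Coefficient of sample entropy: ``SampEn(m, r) + ln(2 r) - ln(mean RR)``.

    ``r`` and the RR intervals are in ms.  Propagates a missing SampEn.
    """
    x = np.asarray(intervals, dtype=float)
    mu = float(np.mean(x)) if x.size else np.nan
    if not np.isfinite(mu) or mu <= 0:
        raise ValueError("mean RR interval must be positive")
    se = sample_entropy(x, m=m, r=r)
    if not np.isfinite(se):
        return np.nan
    return float(se + np.log(2.0 * r) - np.log(mu))


# ---------------------------------------------------------------------------
# detrended fluctuation analysis


def dfa_variance_slope(
    intervals: Sequence[float],
    scales: Sequence[int] = (4, 8, 16, 32, 64),
    use_squared: bool = True,
) -> float:
    """Slope of log fluctuation variance versus log box size.

    The mean-subtracted series is integrated, partitioned into
    non-overlapping boxes of ``n`` beats from both ends of the record, each
    box linearly detrended, and ``F^2(n)`` taken as the mean squared
    residual.  The returned value is the least-squares slope of
    ``log F^2(n)`` on ``log n`` over ``scales`` (``log F(n)`` when
    ``use_squared`` is False, halving the reference values).  Iid intervals
    give a slope near 1.0; integrated (strongly trending) input well above
    that.  Missing (nan) when any ``F(n)`` is zero or the record is shorter
    than twice the largest box.
    """
    x = np.asarray(intervals, dtype=float)
    scales = tuple(int(s) for s in scales)
    if x.size < 2 * max(scales):
        logger.debug("dfa_variance_slope: %d beats < 2*max scale", x.size)
        return np.nan
    y = np.cumsum(x - x.mean())
    f2 = np.empty(len(scales))
    for idx, n in enumerate(scales):
        nbox = y.size // n
        t = np.arange(n, dtype=float)
        design = np.column_stack([np.ones(n), t])
        sq_sum = 0.0
        for seg in (y[: nbox * n], y[y.size - nbox * n :]):
            boxes = seg.reshape(nbox, n)
            coef, *_ = np.linalg.lstsq(design, boxes.T, rcond=None)
            resid = boxes.T - design @ coef
            sq_sum += float(np.mean(resid**2))
        f2[idx] = sq_sum / 2.0
    if np.any(f2 <= 0):
        logger.debug("dfa_variance_slope: zero fluctuation at some scale")
        return np.nan
    logf = np.log(f2) if use_squared else 0.5 * np.log(f2)
    slope = np.polyfit(np.log(scales), logf, 1)[0]
    return float(slope)


def sdnn(intervals: Sequence[float], min_beats: int = 2) -> float:
    """Sample SD (ddof=1) of the RR intervals in a window, in ms."""
    x = np.asarray(intervals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < max(min_beats, 2):
        return np.nan
    return float(np.std(x, ddof=1))


# ---------------------------------------------------------------------------
# assembly and imputation


def compute_admission_features(
    admission,
    params: FeatureParams = FeatureParams(),
    censor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature vectors for one admission, one row per uncensored window end.

    Parameters
    ----------
    admission
        An object with ``admission_id``, ``duration``, ``vitals``
        (timestamps + one array per channel) and ``rr_intervals``
        (beat_times, intervals) attributes, e.g.
        :class:`respwatch.cohort.AdmissionRecord`.
    censor
        Optional boolean mask aligned to the window-end grid of
        ``iter_windows(0, duration, params)``; censored windows produce no
        rows.
    """
    windows = iter_windows(0.0, admission.duration, params)
    if censor is not None and len(censor) != len(windows):
        raise ValueError("censor mask length does not match window grid")
    vit = admission.vitals
    rri = admission.rr_intervals
    beat_t = rri.beat_times[1:]  # interval i ends at beat i+1
    rows = []
    for w_idx, (w0, w1) in enumerate(windows):
        if censor is not None and censor[w_idx]:
            continue
        row: dict[str, float] = {
            "admission_id": admission.admission_id,
            "window_end_min": w1,
        }
        sel = slice(
            np.searchsorted(vit.timestamps, w0, side="left"),
            np.searchsorted(vit.timestamps, w1, side="right"),
        )
        chan = {c: getattr(vit, c)[sel] for c in CHANNELS}
        for c in CHANNELS:
            mean, sd = window_vitals_stats(chan[c], params.min_samples_per_window)
            row[f"{c}_mean"] = mean
            row[f"{c}_sd"] = sd
        for a, b in CHANNEL_PAIRS:
            row[f"xcorr_{a}_{b}"] = window_cross_correlations(
                chan[a], chan[b], params.min_samples_per_window
            )
        bsel = slice(
            np.searchsorted(beat_t, w0, side="left"),
            np.searchsorted(beat_t, w1, side="right"),
        )
        beats = rri.intervals[bsel]
        if beats.size >= params.min_beats_per_window:
            row["sdnn"] = sdnn(beats)
            row["cosen"] = cosen(beats, m=params.sampen_m, r=params.sampen_r_ms)
            row["dfa_slope"] = dfa_variance_slope(
                beats, params.dfa_scales, params.dfa_use_squared
            )
        else:
            row["sdnn"] = row["cosen"] = row["dfa_slope"] = np.nan
        rows.append(row)
    cols = ["admission_id", "window_end_min", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)


def feature_medians(features: pd.DataFrame) -> pd.Series:
    """Per-feature medians of a development feature table (imputation reference)."""
    return features[list(FEATURE_NAMES)].median(skipna=True)


def impute_missing(features: pd.DataFrame, medians: pd.Series | dict) -> pd.DataFrame:
    """Replace missing feature values with development-split medians.

    Adds one ``<feature>_imputed`` flag column per feature; raises
    ``KeyError`` when the medians table names an unknown feature or lacks a
    feature present in the table.
    """
    med = pd.Series(medians, dtype=float)
    unknown = set(med.index) - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown feature name(s) in medians table: {sorted(unknown)}")
    present = [c for c in FEATURE_NAMES if c in features.columns]
    lacking = set(present) - set(med.index)
    if lacking:
        raise KeyError(f"no median available for feature(s): {sorted(lacking)}")
    out = features.copy()
    for c in present:
        flag = out[c].isna()
        out[f"{c}_imputed"] = flag
        out[c] = out[c].fillna(med[c])
    return out
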