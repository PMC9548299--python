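"""Evaluation suite for the relative-risk series.

Four analyses, each operating on every-15-min relative-risk estimates with
censoring applied:

* **Event-aligned trajectories** — risk series of event admissions aligned
  on the intubation time (time zero), averaged per 15-min offset with a
  normal-approximation 95% ribbon.
* **Signed-rank lag tests** — at every offset, a one-sided Wilcoxon
  signed-rank test of the null that risk equals the same patient's risk
  12 h earlier; exact null distribution (rank-sum enumeration via dynamic
  programming, tie-aware) for up to 25 pairs, normal approximation with
  tie correction beyond.
* **Discrimination** — AUC as a function of the event-window width
  (labels positive within 4–24 h before intubation), with percentile 95%
  CIs from 200 bootstrap resamples drawn over hospital admissions so
  within-patient correlation is preserved.
* **Calibration** — deciles of predicted relative risk against observed
  relative risk (fraction of measurements within 12 h of an event,
  divided by the development mean event probability); perfect calibration
  lies on the identity line.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "align_to_event",
    "mean_trajectory_ci",
    "signed_rank_lag_test",
    "signed_rank_exact_p",
    "roc_auc",
    "auc_vs_window",
    "calibration_deciles",
]

GRID_MIN = 15.0  # risk estimates live on a 15-min grid


def align_to_event(
    risk: pd.DataFrame,
    event_times: Mapping[str, float | None],
    max_offset_hours: float = 48.0,
) -> pd.DataFrame:
    """Align risk series on the event time (time zero).

    Parameters
    ----------
    risk
        Rows ``(admission_id, window_end_min, relative_risk, censored)``.
    event_times
        Event time in minutes per admission; admissions without an event
        are excluded (logged).

    Returns
    -------
    A matrix with one row per event admission and one column per 15-min
    offset from ``-max_offset_hours`` to 0; cells hold the uncensored
    relative risk snapped to the nearest grid offset, NaN where
    unmonitored or censored.
    """
    offsets = np.arange(-max_offset_hours * 60.0, 0.0 + GRID_MIN / 2, GRID_MIN)
    rows: dict[str, np.ndarray] = {}
    skipped = 0
    for adm, grp in risk.groupby("admission_id", sort=True):
        t_event = event_times.get(adm)
        if t_event is None or (isinstance(t_event, float) and np.isnan(t_event)):
            skipped += 1
            continue
        row = np.full(offsets.size, np.nan)
        g = grp[~grp["censored"].astype(bool)]
        tau = g["window_end_min"].to_numpy(dtype=float) - float(t_event)
        tau = np.round(tau / GRID_MIN) * GRID_MIN
        ok = (tau <= 0) & (tau >= offsets[0])
        idx = ((tau[ok] - offsets[0]) / GRID_MIN).astype(int)
        row[idx] = g["relative_risk"].to_numpy(dtype=float)[ok]
        rows[adm] = row
    if skipped:
        logger.info("align_to_event: excluded %d admissions without event", skipped)
    return pd.DataFrame.from_dict(rows, orient="index", columns=offsets)


def mean_trajectory_ci(aligned: pd.DataFrame) -> pd.DataFrame:
    """Per-offset mean relative risk with a 95% normal-approximation CI.

    ``ci = mean ± 1.96 · SD/√n``; offsets with no data are omitted, and
    offsets with a single admission report the value with an absent CI.
    """
    recs = []
    for off in aligned.columns:
        col = aligned[off].to_numpy(dtype=float)
        vals = col[np.isfinite(col)]
        n = vals.size
        if n == 0:
            continue
        mean = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
        else:
            lo = hi = np.nan
        recs.append({"offset_min": float(off), "n": n, "mean": mean,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(recs, columns=["offset_min", "n", "mean", "ci_low", "ci_high"])


# ---------------------------------------------------------------------------
# Wilcoxon signed rank against a lagged self-comparison


def signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Exact one-sided (greater) signed-rank p-value.

    Conditions on the observed |difference| midranks and enumerates the
    sign-flip null by dynamic programming over the doubled (hence integer)
    ranks, so tied magnitudes are handled exactly.  Zero differences must
    already be removed.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks, possibly half-integers
    r2 = np.rint(ranks * 2).astype(int)
    w_obs = int(np.rint(r2[d > 0].sum()))
    total = int(r2.sum())
    # dp[s] = number of sign assignments with doubled positive-rank sum s
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in r2:
        dp[r:] = dp[r:] + dp[:-r]  # new array on the rhs: safe despite overlap
    n_ge = dp[w_obs:].sum()
    return float(n_ge / 2.0**n)


def _signed_rank_p(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """One-sided signed-rank p; exact for small n, else normal with tie
    correction and continuity correction."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n <= exact_max_n:
        return signed_rank_exact_p(d)
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def signed_rank_lag_test(
    aligned: pd.DataFrame,
    lag_hours: float = 12.0,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-offset one-sided test that risk exceeds the same patient's risk
    ``lag_hours`` earlier.

    Pairs are admissions with values at both the offset and the lagged
    offset; zero differences are dropped (Wilcoxon convention).  Offsets
    with fewer than ``min_pairs`` pairs are reported untested (NaN p).
    """
    lag_min = lag_hours * 60.0
    offsets = np.asarray(aligned.columns, dtype=float)
    recs = []
    for off in offsets:
        lagged = off - lag_min
        if lagged < offsets[0] - 1e-9:
            recs.append({"offset_min": off, "n_pairs": 0, "p": np.nan})
            continue
        j = int(np.argmin(np.abs(offsets - lagged)))
        a = aligned[aligned.columns[int(np.argmin(np.abs(offsets - off)))]].to_numpy(float)
        b = aligned[aligned.columns[j]].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        d = a[ok] - b[ok]
        d = d[d != 0]
        if d.size < min_pairs:
            recs.append({"offset_min": off, "n_pairs": int(d.size), "p": np.nan})
            continue
        recs.append({"offset_min": off, "n_pairs": int(d.size), "p": _signed_rank_p(d)})
    return pd.DataFrame(recs, columns=["offset_min", "n_pairs", "p"])


# ---------------------------------------------------------------------------
# discrimination


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC / C-statistic: probability that a random event epoch outscores a
    random control epoch, ties counted half (Mann–Whitney form)."""
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auc_vs_window(
    risk: pd.DataFrame,
    event_times: Mapping[str, float | None],
    windows_hours: Sequence[float] = tuple(range(4, 25, 2)),
    n_boot: int = 200,
    seed: int = 0,
    max_redraws: int = 1000,
) -> pd.DataFrame:
    """AUC versus event-window width with admission-level bootstrap CIs.

    For each window ``w`` every uncensored epoch is labelled positive when
    it falls within ``w`` hours before its admission's event; control
    epochs are those of never-intubated admissions and of event admissions
    far from the event.  Percentile 95% CIs come from ``n_boot`` bootstrap
    resamples drawn over hospital admissions with replacement (all epochs
    of a sampled admission enter together); single-class replicates are
    redrawn and counted.
    """
    g = risk[~risk["censored"].astype(bool)].reset_index(drop=True)
    if g.empty:
        raise ValueError("no uncensored epochs")
    adm_ids = np.array(sorted(g["admission_id"].unique()))
    rows_of = {a: np.flatnonzero((g["admission_id"] == a).to_numpy()) for a in adm_ids}
    scores = g["relative_risk"].to_numpy(dtype=float)
    ends = g["window_end_min"].to_numpy(dtype=float)
    ev = np.array(
        [np.nan if event_times.get(a) is None else float(event_times[a]) for a in g["admission_id"]],
        dtype=float,
    )

    def labels_for(w_hours: float, idx: np.ndarray) -> np.ndarray:
        delta = ev[idx] - ends[idx]
        return ((delta > 0) & (delta <= w_hours * 60.0)).astype(int)

    all_idx = np.arange(len(g))
    recs = []
    ss = np.random.SeedSequence([seed, len(adm_ids)])
    for w, child in zip(windows_hours, ss.spawn(len(list(windows_hours)))):
        y = labels_for(w, all_idx)
        point = roc_auc(scores, y)
        rng = np.random.default_rng(child)
        boots = []
        redraws = 0
        while len(boots) < n_boot and redraws < max_redraws + n_boot:
            sample = rng.choice(adm_ids, size=adm_ids.size, replace=True)
            idx = np.concatenate([rows_of[a] for a in sample])
            yb = labels_for(w, idx)
            if yb.min() == yb.max():
                redraws += 1
                continue
            boots.append(roc_auc(scores[idx], yb))
        if redraws:
            logger.info("auc_vs_window(w=%s): redrew %d single-class replicates", w, redraws)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        recs.append(
            {
                "window_hours": float(w),
                "auc": point,
                "ci_low": float(min(lo, point)),
                "ci_high": float(max(hi, point)),
                "n_event_epochs": int(y.sum()),
                "n_epochs": int(y.size),
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# calibration


def calibration_deciles(
    risk: pd.DataFrame,
    event_times: Mapping[str, float | None],
    train_mean_p: float,
    horizon_hours: float = 12.0,
) -> pd.DataFrame:
    """Observed versus predicted relative risk by decile of prediction.

    Uncensored measurements are ranked by predicted relative risk (ties
    broken by a stable sort on admission id and time so the partition is
    reproducible) and cut into 10 equal-count groups.  Per decile the
    predicted value is the mean relative risk; the observed value is the
    fraction of measurements within ``horizon_hours`` of an emergent
    intubation divided by ``train_mean_p``.
    """
    g = risk[~risk["censored"].astype(bool)]
    if len(g) < 10:
        raise ValueError("need at least 10 uncensored measurements")
    g = g.sort_values(
        ["relative_risk", "admission_id", "window_end_min"], kind="mergesort"
    ).reset_index(drop=True)
    ev = np.array(
        [np.nan if event_times.get(a) is None else float(event_times[a]) for a in g["admission_id"]],
        dtype=float,
    )
    delta = ev - g["window_end_min"].to_numpy(dtype=float)
    observed = ((delta > 0) & (delta <= horizon_hours * 60.0)).astype(float)
    pred = g["relative_risk"].to_numpy(dtype=float)
    splits = np.array_split(np.arange(len(g)), 10)
    recs = []
    for d, idx in enumerate(splits, start=1):
        recs.append(
            {
                "decile": d,
                "n": int(idx.size),
                "predicted_rr": float(pred[idx].mean()),
                "observed_rr": float(observed[idx].mean() / train_mean_p),
                "observed_fraction": float(observed[idx].mean()),
            }
        )
    return pd.DataFrame(recs)
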