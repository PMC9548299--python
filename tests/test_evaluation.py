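"""Evaluation suite against exact oracles: all-pairs AUC concordance,
full sign-flip enumeration for the signed-rank test, and simulation checks
for alignment, bootstrap and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from respwatch.evaluation import (
    align_to_event,
    auc_vs_window,
    calibration_deciles,
    mean_trajectory_ci,
    roc_auc,
    signed_rank_exact_p,
    signed_rank_lag_test,
)

# ---------------------------------------------------------------------------
# oracles


def auc_bruteforce(scores, labels):
    """All-pairs concordance count, ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    c = 0.0
    for p in pos:
        for n in neg:
            c += 1.0 if p > n else (0.5 if p == n else 0.0)
    return c / (len(pos) * len(neg))


def signed_rank_enumeration_p(diffs):
    """Exact one-sided p by full 2^n enumeration of sign flips."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


def risk_frame(series: dict, censored: dict | None = None) -> pd.DataFrame:
    rows = []
    for adm, vals in series.items():
        for t, v in vals:
            c = False
            if censored and adm in censored:
                c = t in censored[adm]
            rows.append(
                {"admission_id": adm, "window_end_min": t, "relative_risk": v,
                 "censored": c}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


class TestAlignToEvent:
    def test_risk_before_event_lands_in_negative_offset_column(self):
        risk = risk_frame({"a": [(985.0, 2.0)]})
        m = align_to_event(risk, {"a": 1000.0}, max_offset_hours=2.0)
        assert m.loc["a", -15.0] == 2.0

    def test_unmonitored_leading_columns_absent(self):
        risk = risk_frame({"a": [(t, 1.0) for t in np.arange(30.0, 200.0, 15.0)]})
        m = align_to_event(risk, {"a": 1900.0}, max_offset_hours=48.0)
        row = m.loc["a"]
        assert row[np.asarray(m.columns) < -1900.0].isna().all()
        assert row.notna().sum() == len(np.arange(30.0, 200.0, 15.0))

    def test_admission_without_event_excluded(self):
        risk = risk_frame({"a": [(30.0, 1.0)], "b": [(30.0, 1.0)]})
        m = align_to_event(risk, {"a": 100.0, "b": None})
        assert list(m.index) == ["a"]

    def test_censored_cells_absent(self):
        risk = risk_frame({"a": [(970.0, 2.0), (985.0, 3.0)]},
                          censored={"a": {985.0}})
        m = align_to_event(risk, {"a": 1000.0}, max_offset_hours=1.0)
        assert np.isnan(m.loc["a", -15.0])
        assert m.loc["a", -30.0] == 2.0

    def test_post_event_values_excluded(self):
        risk = risk_frame({"a": [(1030.0, 9.0), (1000.0, 5.0)]})
        m = align_to_event(risk, {"a": 1000.0}, max_offset_hours=1.0)
        assert m.loc["a", 0.0] == 5.0
        assert m.loc["a"].notna().sum() == 1


class TestMeanTrajectory:
    def test_single_admission_reports_n1_without_ci(self):
        risk = risk_frame({"a": [(985.0, 2.0)]})
        m = align_to_event(risk, {"a": 1000.0}, max_offset_hours=0.5)
        out = mean_trajectory_ci(m)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n"] == 1 and row["mean"] == 2.0
        assert np.isnan(row["ci_low"])

    def test_identical_rows_have_zero_width_ci(self):
        risk = risk_frame({a: [(985.0, 2.0)] for a in "abcd"})
        m = align_to_event(risk, {a: 1000.0 for a in "abcd"}, max_offset_hours=0.5)
        out = mean_trajectory_ci(m)
        row = out.iloc[0]
        assert row["ci_low"] == row["ci_high"] == row["mean"] == 2.0


class TestSignedRank:
    def test_all_zero_differences_untested(self):
        # same value at offset and lag: pairs vanish, p reported missing
        vals = {a: [(700.0, 1.0), (1420.0, 1.0)] for a in "abcdefgh"}
        m = align_to_event(risk_frame(vals), {a: 1440.0 for a in vals},
                          max_offset_hours=13.0)
        out = signed_rank_lag_test(m, lag_hours=12.0)
        tested = out[out["p"].notna()]
        assert tested.empty

    def test_six_positive_pairs_exact_p(self):
        assert signed_rank_exact_p(np.ones(6)) == pytest.approx(2.0**-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_equals_full_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 13))
        d = np.round(r.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = d[d != 0]
        if d.size == 0:
            return
        assert signed_rank_exact_p(d) == pytest.approx(
            signed_rank_enumeration_p(d), abs=1e-12
        )

    def test_exact_branch_matches_scipy_without_ties(self, rng):
        d = rng.normal(0.5, 1.0, 15)
        want = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert signed_rank_exact_p(d) == pytest.approx(want, abs=1e-12)

    def test_large_n_normal_approximation_close_to_exact(self, rng):
        d = rng.normal(0.2, 1.0, 24)
        exact = signed_rank_exact_p(d)
        from respwatch.evaluation import _signed_rank_p

        approx = _signed_rank_p(d, exact_max_n=0)
        assert approx == pytest.approx(exact, abs=0.01)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([1.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("n", [30, 200])
    def test_equals_bruteforce_concordance(self, n):
        r = np.random.default_rng(n)
        scores = np.round(r.normal(size=n), 1)  # ties likely
        labels = r.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            auc_bruteforce(scores, labels), abs=1e-12
        )


class TestAucVsWindow:
    def _toy_risk(self, rng, signal=True):
        rows = {}
        events = {}
        for i in range(30):
            adm = f"a{i:02d}"
            has_event = i < 12
            dur = 3000.0
            events[adm] = dur - 60.0 if has_event else None
            vals = []
            for t in np.arange(30.0, dur, 15.0):
                x = rng.normal(1.0, 0.3)
                if signal and has_event and events[adm] - t < 240.0:
                    x += 2.0
                vals.append((t, max(x, 0.01)))
            rows[adm] = vals
        return risk_frame(rows), events

    def test_fixed_seed_reproduces_ci_bounds(self, rng):
        risk, events = self._toy_risk(rng)
        a = auc_vs_window(risk, events, windows_hours=(4, 12), n_boot=50, seed=3)
        b = auc_vs_window(risk, events, windows_hours=(4, 12), n_boot=50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_narrow_window_labels_nest_in_wide(self, rng):
        risk, events = self._toy_risk(rng)
        out = auc_vs_window(risk, events, windows_hours=(4, 24), n_boot=10, seed=0)
        assert out["n_event_epochs"].iloc[0] <= out["n_event_epochs"].iloc[1]
        assert out["n_epochs"].iloc[0] == out["n_epochs"].iloc[1]

    def test_signal_concentrated_near_event_detected_at_narrow_window(self, rng):
        risk, events = self._toy_risk(rng, signal=True)
        out = auc_vs_window(risk, events, windows_hours=(4, 24), n_boot=20, seed=0)
        assert out["auc"].iloc[0] > 0.9
        assert out["auc"].iloc[0] > out["auc"].iloc[1]

    def test_ci_brackets_point_estimate(self, rng):
        risk, events = self._toy_risk(rng)
        out = auc_vs_window(risk, events, windows_hours=(4,), n_boot=100, seed=1)
        row = out.iloc[0]
        assert row["ci_low"] <= row["auc"] <= row["ci_high"]

    def test_bootstrap_ci_covers_true_auc(self):
        # scaled-down coverage simulation: iid admissions with one epoch
        # each, known population AUC from the generating mixture
        hits = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(100 + rep)
            rows, events = {}, {}
            for i in range(120):
                adm = f"a{i:03d}"
                has_event = i < 40
                events[adm] = 1030.0 if has_event else None
                mu = 1.5 if has_event else 1.0
                rows[adm] = [(1000.0, r.normal(mu, 0.5))]
            risk = risk_frame(rows)
            out = auc_vs_window(risk, events, windows_hours=(4,), n_boot=100,
                                seed=rep)
            # population AUC for N(1.5,.5) vs N(1,.5): Phi(0.5/(0.5*sqrt2))
            true_auc = stats.norm.cdf(0.5 / (0.5 * np.sqrt(2)))
            if out["ci_low"].iloc[0] <= true_auc <= out["ci_high"].iloc[0]:
                hits += 1
        assert hits >= reps * 0.7


class TestCalibration:
    def test_fewer_than_ten_measurements_rejected(self):
        risk = risk_frame({"a": [(30.0, 1.0)]})
        with pytest.raises(ValueError):
            calibration_deciles(risk, {"a": None}, train_mean_p=0.1)

    def test_constant_predictions_split_into_equal_deciles(self):
        rows = {f"a{i}": [(30.0, 1.0)] for i in range(20)}
        events = {f"a{i}": (90.0 if i < 10 else None) for i in range(20)}
        out = calibration_deciles(risk_frame(rows), events, train_mean_p=0.5)
        assert len(out) == 10
        assert (out["n"] == 2).all()
        # stable (admission id) ordering puts the 10 event admissions first
        np.testing.assert_allclose(out["predicted_rr"], 1.0)

    def test_decile_without_pre_event_measurements_observes_zero(self):
        rows = {f"a{i}": [(30.0, float(i))] for i in range(10)}
        events = {f"a{i}": None for i in range(10)}
        events["a9"] = 90.0
        out = calibration_deciles(risk_frame(rows), events, train_mean_p=0.5)
        assert out["observed_rr"].iloc[0] == 0.0
        assert out["observed_rr"].iloc[-1] == pytest.approx(2.0)

    def test_weighted_decile_mean_equals_overall_observed_risk(self, rng):
        rows, events = {}, {}
        for i in range(200):
            adm = f"a{i:03d}"
            events[adm] = 200.0 if rng.random() < 0.3 else None
            rows[adm] = [(t, float(rng.normal(1, 0.2))) for t in (30.0, 45.0)]
        risk = risk_frame(rows)
        out = calibration_deciles(risk, events, train_mean_p=0.25)
        overall = np.average(out["observed_rr"], weights=out["n"])
        ev = risk["admission_id"].map(events)
        delta = ev - risk["window_end_min"]
        want = ((delta > 0) & (delta <= 720.0)).mean() / 0.25
        assert overall == pytest.approx(want, abs=1e-12)

    def test_generating_model_calibrates_on_identity_line(self):
        # predictions equal the true event probability: every decile's
        # observed frequency should sit inside its binomial band
        r = np.random.default_rng(12)
        n = 20000
        p = stats.norm.cdf(r.normal(-1.2, 0.8, n))
        label = r.random(n) < p
        rows, events = {}, {}
        for i in range(n):
            adm = f"a{i:05d}"
            rows[adm] = [(30.0, p[i] / p.mean())]
            events[adm] = 60.0 if label[i] else None
        out = calibration_deciles(risk_frame(rows), events, train_mean_p=float(p.mean()))
        for row in out.itertuples(index=False):
            band = 2.81 * np.sqrt(row.predicted_rr * p.mean() / row.n) / p.mean()
            assert abs(row.observed_rr - row.predicted_rr) <= band + 1e-12
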