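"""Compose the run report.

Collects the evaluation tables into results/report.txt: cohort summary,
events-with-data versus lead time, per-model trajectory extremes, the
AUC-versus-window curve, and the calibration deciles.  Pass --plots to
also write per-model PNG figures (requires matplotlib).
"""

import sys

import numpy as np

from common import load_run_config, regenerate_cohort, results_dir
from respwatch import io as rio


def main() -> None:
    cfg = load_run_config()
    records = regenerate_cohort(cfg)
    out = results_dir()
    lines = ["respwatch analysis report", ""]
    events = [r for r in records if r.event_time is not None]
    lines.append(f"admissions: {len(records)} (events {len(events)}, "
                 f"dni {sum(r.dni for r in records)})")

    # events with pre-event observation of at least h hours (lead-time table)
    lead_h = np.array([r.event_time for r in events]) / 60.0
    lines.append("")
    lines.append("lead time (h) : events observed at least that long before intubation")
    for h in (0, 4, 8, 12, 16, 20, 24):
        lines.append(f"  {h:2d} : {(lead_h >= h).sum()}")

    for name in cfg.models:
        tr = rio.read_csv(out / f"trajectory_{name}.csv")
        auc = rio.read_csv(out / f"auc_curve_{name}.csv")
        cal = rio.read_csv(out / f"calibration_{name}.csv")
        lines.append("")
        lines.append(f"model {name}")
        far = tr[tr.offset_min == -1440.0]["mean"]
        near = tr[tr.offset_min >= -120.0]["mean"].mean()
        if len(far):
            lines.append(f"  mean relative risk: {float(far.iloc[0]):.2f} at -24 h, "
                         f"{near:.2f} in the final 2 h")
        for row in auc.itertuples(index=False):
            lines.append(f"  AUC({row.window_hours:>4.0f} h) = {row.auc:.3f} "
                         f"[{row.ci_low:.3f}, {row.ci_high:.3f}]")
        lines.append("  calibration (predicted -> observed relative risk by decile):")
        lines.append("    " + ", ".join(
            f"{r.predicted_rr:.2f}->{r.observed_rr:.2f}"
            for r in cal.itertuples(index=False)))

    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text, encoding="utf-8")
    print(text)

    if "--plots" in sys.argv:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name in cfg.models:
            tr = rio.read_csv(out / f"trajectory_{name}.csv")
            auc = rio.read_csv(out / f"auc_curve_{name}.csv")
            cal = rio.read_csv(out / f"calibration_{name}.csv")
            fig, axes = plt.subplots(1, 3, figsize=(14, 4))
            axes[0].fill_between(tr.offset_min / 60, tr.ci_low, tr.ci_high, color="0.85")
            axes[0].plot(tr.offset_min / 60, tr["mean"], "k")
            sig = tr[tr["p"] < 0.05]
            axes[0].plot(sig.offset_min / 60, sig["mean"], "wo", mec="k", ms=4)
            axes[0].set(xlabel="hours before intubation", ylabel="mean relative risk")
            axes[1].errorbar(auc.window_hours, auc.auc,
                             yerr=[auc.auc - auc.ci_low, auc.ci_high - auc.auc],
                             fmt="o-", capsize=3)
            axes[1].set(xlabel="event window (h)", ylabel="AUC")
            axes[2].plot(cal.predicted_rr, cal.observed_rr, "o-")
            lim = float(max(cal.predicted_rr.max(), cal.observed_rr.max()) * 1.05)
            axes[2].plot([0, lim], [0, lim], "k--", lw=1)
            axes[2].set(xlabel="predicted relative risk", ylabel="observed relative risk")
            fig.suptitle(name)
            fig.tight_layout()
            fig.savefig(out / f"figures_{name}.png", dpi=120)
            plt.close(fig)
        print(f"figures written to {out}")


if __name__ == "__main__":
    main()
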