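"""Fit the three logistic risk models and emit relative-risk series.

Reads results/features.csv, imputes missing values with the development
medians, fits the three-model family on the development admissions
(linear basis / 24 h horizon; splines / 4 h; splines / 6 h) and writes
each model (results/model_*.json) together with its every-15-min
relative-risk series on the validation admissions (results/risk_*.csv).
"""

from common import load_run_config, regenerate_cohort, results_dir
from respwatch import io as rio
from respwatch.features import feature_medians, impute_missing
from respwatch.risk_models import predict_relative_risk
from respwatch.workflow import (
    config_hash,
    fit_models,
    split_dev_val,
    stage_seed,
)


def main() -> None:
    cfg = load_run_config()
    records = regenerate_cohort(cfg)
    out = results_dir()
    features = rio.read_csv(out / "features.csv")
    event_times = {r.admission_id: r.event_time for r in records}

    dev_ids, val_ids = split_dev_val(records, cfg.dev_fraction, stage_seed(cfg.seed, 1))
    dev_raw = features[features["admission_id"].isin(dev_ids)].reset_index(drop=True)
    val_raw = features[features["admission_id"].isin(val_ids)].reset_index(drop=True)
    medians = feature_medians(dev_raw)
    dev_feat = impute_missing(dev_raw, medians)
    val_feat = impute_missing(val_raw, medians)

    models = fit_models(dev_feat, event_times, cfg.models, cfg.politano_stepwise)
    meta = f"config_hash={config_hash(cfg)} seed={cfg.seed}"
    print(f"development: {len(dev_ids)} admissions ({len(dev_feat)} epochs); "
          f"validation: {len(val_ids)} ({len(val_feat)} epochs)")
    for name, model in models.items():
        (out / f"model_{name}.json").write_text(model.to_json(), encoding="utf-8")
        risk = predict_relative_risk(model, val_feat, cap=cfg.relative_risk_cap)
        rio.write_csv(risk, out / f"risk_{name}.csv", meta)
        print(f"  {name}: basis={model.spec.basis}, horizon={model.spec.horizon_hours:g} h, "
              f"train mean event probability={model.train_mean_p:.4f}")


if __name__ == "__main__":
    main()
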