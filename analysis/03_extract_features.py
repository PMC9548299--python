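"""Extract the windowed cardiorespiratory predictors.

Regenerates the cohort deterministically, applies the censor mask implied
by results/epochs.csv (ventilated periods and DNI admissions), and computes
the 30-min/50%-overlap feature vectors: per-channel means and SDs,
pairwise cross-correlations, SDNN, COSEn and the DFA variance slope.
Writes results/features.csv plus the development-split imputation medians
(results/medians.csv).
"""

import time

from common import load_run_config, regenerate_cohort, results_dir
from respwatch import io as rio
from respwatch.features import FEATURE_NAMES, feature_medians
from respwatch.workflow import (
    config_hash,
    extract_features,
    split_dev_val,
    stage_seed,
)


def main() -> None:
    cfg = load_run_config()
    records = regenerate_cohort(cfg)
    out = results_dir()
    epochs = rio.frame_to_epochs(rio.read_csv(out / "epochs.csv"))

    t0 = time.time()
    features = extract_features(records, epochs, cfg.features)
    meta = f"config_hash={config_hash(cfg)} seed={cfg.seed}"
    rio.write_csv(features, out / "features.csv", meta)

    dev_ids, _ = split_dev_val(records, cfg.dev_fraction, stage_seed(cfg.seed, 1))
    medians = feature_medians(features[features["admission_id"].isin(dev_ids)])
    rio.write_csv(
        medians.rename_axis("feature").reset_index(name="median"),
        out / "medians.csv", meta,
    )

    total_windows = sum(
        int((r.duration - cfg.features.window_width_min) // cfg.features.step_min) + 1
        for r in records
    )
    print(f"features: {len(features)} uncensored epochs "
          f"({total_windows} on the grid; "
          f"{1 - len(features)/total_windows:.1%} censored) in {time.time()-t0:.0f} s")
    miss = features[list(FEATURE_NAMES)].isna().mean()
    print(f"  missingness: max {miss.max():.2%} ({miss.idxmax()}); "
          f"imputation medians from {len(dev_ids)} development admissions")


if __name__ == "__main__":
    main()
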