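"""Train the CRF sleep-wake classifier and sweep the decision threshold.

A 70/30 participant split keeps test nights fully independent; the CRF emits
per-window P(sleep) marginals, thresholded at tau to produce labels.
"""

import numpy as np

from patchsleep import ModelSpec, RunConfig, SimulationConfig, SplitSpec
from patchsleep.evaluate import confusion_metrics, f1_maximizing_threshold, split_cohort, threshold_sweep
from patchsleep.features import base_feature_names, build_feature_table, difference_features, feature_columns
from patchsleep.models import apply_threshold, predict_sleep_probability, train_classifier
from patchsleep.pipeline import process_cohort

cfg = RunConfig(
    simulation=SimulationConfig(n_participants=10, nights_per_participant=1,
                                night_duration=240.0, seed=7),
    split=SplitSpec(seed=8),
)
nights = process_cohort(cfg)
table = difference_features(build_feature_table(nights), base_feature_names())
cols = feature_columns(table)

train_ids, test_ids = split_cohort(sorted(table["participant"].unique()), cfg.split)
model = train_classifier(ModelSpec(kind="crf", seed=9),
                         table[table["participant"].isin(train_ids)], cols)
preds = predict_sleep_probability(model, table[table["participant"].isin(test_ids)])
p, y = preds["p_sleep"].to_numpy(), preds["label"].to_numpy()

tau = f1_maximizing_threshold(p, y, list(cfg.tau_grid))
m = confusion_metrics(apply_threshold(p, tau), y, p)
print(f"test participants: {test_ids}; {len(preds)} windows")
print(f"AUC {m.auc:.3f} | at tau*={tau:.2f}: sensitivity {m.sensitivity:.3f}, "
      f"specificity {m.specificity:.3f}, F1 {m.f1:.3f}")
# sensitivity = fraction of sleep windows caught; specificity = fraction of
# wake windows caught. Raising tau trades sensitivity for specificity:
sweep = threshold_sweep(p, y, [0.25, 0.5, 0.75])
print(sweep.round(3).to_string(index=False))
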