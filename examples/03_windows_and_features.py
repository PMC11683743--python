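"""Assemble 5-minute windows and build per-window feature vectors.

A window spans ten 30-s PSG epochs (wake iff >= 5 are wake), keeps the first
ACC block of each minute and the first valid ECG block, and is valid with
>= 3 ACC blocks plus an ECG block. Valid windows of usable nights (>= 1 h of
overlap) become feature rows.
"""

from patchsleep import FilterSpec, SimulationConfig
from patchsleep.features import base_feature_names, build_feature_table, difference_features
from patchsleep.simulate import iter_cohort_sessions
from patchsleep.windows import assemble_windows

config = SimulationConfig(n_participants=3, nights_per_participant=1,
                          night_duration=120.0, seed=11)
spec = FilterSpec()

nights = [(g, assemble_windows(s, spec)) for g, s in iter_cohort_sessions(config)]
for _, night in nights:
    n_valid = len(night.valid_windows)
    print(f"{night.participant}: {len(night.windows)} windows, {n_valid} valid, "
          f"usable={night.usable} ({night.usable_overlap:.0f} min overlap)")

table = build_feature_table(nights)
table = difference_features(table, base_feature_names())
print(f"\nfeature table: {len(table)} rows x {len(base_feature_names()) * 6} "
      "model columns (15 base features, each with 5 lag differences)")
print(table[["participant", "window_index", "label",
             "total_step_count", "mean_hr", "hr_z"]].head(6).to_string(index=False))
# label 1 = sleep; hr_z is the heart rate standardized against each
# participant's own mean and SD, so between-person HR offsets drop out.
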