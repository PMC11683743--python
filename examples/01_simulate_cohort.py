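"""Simulate a small synthetic cohort and write it to disk.

Each participant-night gets duty-cycled ACC/ECG streams (14 s recorded per
20-s interval) and a PSG hypnogram scored in 30-s epochs, as CSV files plus
a cohort manifest.
"""

import tempfile
from pathlib import Path

from patchsleep import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_participants=4, nights_per_participant=1, night_duration=60.0, seed=7
)
out = Path(tempfile.mkdtemp()) / "cohort"
manifest = simulate_cohort(config, out)

print(f"cohort written to {out}")
print(f"participants: {len(manifest.participants)} "
      f"({sum(1 for _, g in manifest.participants if g == 'SMI')} tagged SMI)")
for entry in manifest.sessions[:2]:
    night_dir = out / entry["path"]
    acc_lines = sum(1 for _ in open(night_dir / "acc.csv")) - 1
    print(f"  {entry['participant']} night {entry['night']}: "
          f"{acc_lines} ACC samples in {night_dir.name}/acc.csv")
# Every 20-s interval contributes one 14-s block; a 60-min night therefore
# holds 180 blocks per stream, and the manifest ties files to participants.
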