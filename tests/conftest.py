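import numpy as np
import pandas as pd
import pytest

from patchsleep.config import FilterSpec, SimulationConfig
from patchsleep.pipeline import process_cohort
from patchsleep.config import RunConfig
from patchsleep.session import EcgBlock


@pytest.fixture(scope="session")
def filter_spec() -> FilterSpec:
    return FilterSpec()


def make_r_peak_train(
    rr_s: float,
    rate: float = 256.0,
    duration: float = 14.0,
    amplitude: float = 1.0,
    sigma: float = 0.012,
    noise_sd: float = 0.0,
    first_peak: float = 0.4,
    seed: int = 0,
) -> tuple[EcgBlock, np.ndarray]:
    """Synthetic ECG block built directly from its ground-truth peak times."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    peaks = np.arange(first_peak, duration, rr_s)
    x = np.zeros(n)
    for tp in peaks:
        x += amplitude * np.exp(-0.5 * ((t - tp) / sigma) ** 2)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return EcgBlock(0.0, rate, x), peaks


def make_synthetic_table(
    n_participants: int = 8,
    windows_per_night: int = 48,
    n_noise: int = 3,
    effect: float = 3.0,
    sleep_fraction: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with one informative feature and pure-noise decoys.

    Labels form per-night bouts (a sticky two-state chain) so the sequence
    models see realistic runs rather than i.i.d. labels.
    """
    rng = np.random.default_rng(seed)
    stay = 0.9
    rows = []
    for p in range(n_participants):
        state = 1
        for w in range(windows_per_night):
            flip_to_sleep = sleep_fraction * (1 - stay) / (1 - sleep_fraction + 1e-9)
            if state == 1:
                state = 1 if rng.random() < stay else 0
            else:
                state = 0 if rng.random() < 1 - min(flip_to_sleep, 0.5) else 1
            row = {
                "participant": f"S{p:02d}",
                "group": "HV",
                "night": 0,
                "window_index": w,
                "label": state,
                "informative": effect * state + rng.normal(),
            }
            for j in range(n_noise):
                row[f"noise_{j}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Processed nights for a small simulated cohort (shared, read-only)."""
    cfg = RunConfig(
        simulation=SimulationConfig(
            n_participants=8, nights_per_participant=1, night_duration=180.0, seed=11
        )
    )
    return process_cohort(cfg)
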