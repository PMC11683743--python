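"""Configuration objects for simulation, preprocessing, modeling and evaluation.

All tunable parameters of the pipeline live in small validated dataclasses so
that a run is fully described by one :class:`RunConfig` plus a master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

STAGES = ("W", "N1", "N2", "N3", "R")
SLEEP_STAGES = frozenset({"N1", "N2", "N3", "R"})

EPOCH_S = 30
WINDOW_S = 300
EPOCHS_PER_WINDOW = WINDOW_S // EPOCH_S
BLOCK_PERIOD_S = 20.0
BLOCK_DURATION_S = 14.0


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


def _check_row_stochastic(matrix: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigurationError(f"{name} must be a square matrix, got shape {m.shape}")
    if (m < 0).any():
        raise ConfigurationError(f"{name} has negative entries")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError(f"{name} rows must sum to 1 (±1e-9)")
    return m


# Stage-transition matrix over (W, N1, N2, N3, R) at 30-s epoch resolution.
# Hand-tuned so that a night started in wake yields ~84% sleep-labeled 5-min
# windows, with a wake bout structure giving a non-trivial SOL and WASO.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        #  W      N1     N2     N3     R
        [0.920, 0.080, 0.000, 0.000, 0.000],  # W
        [0.060, 0.450, 0.440, 0.000, 0.050],  # N1
        [0.012, 0.015, 0.880, 0.063, 0.030],  # N2
        [0.005, 0.000, 0.085, 0.900, 0.010],  # N3
        [0.015, 0.030, 0.055, 0.000, 0.900],  # R
    ]
)

DEFAULT_CONTACT_MATRIX = np.array(
    [
        # good   bad
        [0.970, 0.030],  # good
        [0.090, 0.910],  # bad
    ]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe the emulated study regime: 60 participants (35 with a
    serious mental illness diagnosis), up to 8-h lab nights, a patch sampling
    14 s of ACC and ECG in every 20-s interval, state-dependent heart rate and
    movement, and a contact-quality process that makes roughly a quarter of
    ECG blocks unusable.
    """

    n_participants: int = 60
    nights_per_participant: int = 2
    smi_fraction: float = 35 / 60
    epoch_duration: int = EPOCH_S
    night_duration: float = 480.0  # minutes
    stage_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    hr_mean_by_state: Mapping[str, float] = field(
        default_factory=lambda: {"wake": 72.0, "sleep": 58.0}
    )
    hr_sd: float = 3.0  # bpm, between-block variation
    rr_jitter: float = 0.02  # fractional R-R jitter within a block
    movement_burst_rate_by_state: Mapping[str, float] = field(
        default_factory=lambda: {"wake": 3.0, "sleep": 0.15}
    )  # bursts / minute
    burst_duration: float = 2.0  # seconds
    burst_amplitude: float = 0.25  # g
    step_cadence: float = 1.8  # Hz
    posture_shift_rate: float = 2.0  # events / hour
    acc_sampling_rate: float = 32.0  # Hz
    ecg_sampling_rate: float = 256.0  # Hz
    acc_noise_sd: float = 0.02  # g
    ecg_noise_sd: float = 0.03  # mV, good skin contact
    ecg_bad_contact_noise_sd: float = 0.60  # mV, degraded contact
    r_peak_amplitude: float = 1.0  # mV
    r_peak_width: float = 0.012  # s, Gaussian sigma
    contact_dropout_transition: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTACT_MATRIX.copy()
    )
    acc_dropout_rate: float = 0.02  # per-block loss probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 1 <= self.nights_per_participant <= 4:
            raise ConfigurationError("nights_per_participant must be in 1..4")
        if not 0.0 <= self.smi_fraction <= 1.0:
            raise ConfigurationError("smi_fraction must be a proportion")
        m = _check_row_stochastic(self.stage_transition_matrix, "stage_transition_matrix")
        if m.shape[0] != len(STAGES):
            raise ConfigurationError(
                f"stage_transition_matrix must be {len(STAGES)}x{len(STAGES)}"
            )
        object.__setattr__(self, "stage_transition_matrix", m)
        c = _check_row_stochastic(self.contact_dropout_transition, "contact_dropout_transition")
        if c.shape[0] != 2:
            raise ConfigurationError("contact_dropout_transition must be 2x2")
        object.__setattr__(self, "contact_dropout_transition", c)
        night_s = self.night_duration * 60.0
        if abs(night_s / self.epoch_duration - round(night_s / self.epoch_duration)) > 1e-9:
            raise ConfigurationError("night_duration must be a multiple of epoch_duration")
        for state, hr in self.hr_mean_by_state.items():
            if not 30.0 < hr < 200.0:
                raise ConfigurationError(
                    f"hr_mean_by_state[{state!r}]={hr} outside plausible (30, 200) bpm"
                )
        for name in (
            "hr_sd",
            "acc_noise_sd",
            "ecg_noise_sd",
            "step_cadence",
            "posture_shift_rate",
            "acc_sampling_rate",
            "ecg_sampling_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for state, rate in self.movement_burst_rate_by_state.items():
            if rate < 0:
                raise ConfigurationError(f"movement burst rate for {state!r} negative")
        if not 0.0 <= self.acc_dropout_rate < 1.0:
            raise ConfigurationError("acc_dropout_rate must be in [0, 1)")

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_duration * 60.0 / self.epoch_duration))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_transition_matrix"] = self.stage_transition_matrix.tolist()
        d["contact_dropout_transition"] = self.contact_dropout_transition.tolist()
        d["hr_mean_by_state"] = dict(self.hr_mean_by_state)
        d["movement_burst_rate_by_state"] = dict(self.movement_burst_rate_by_state)
        return d


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-limiting filter specification.

    Defaults follow common wearable practice: a 0.5–40 Hz ECG band with a
    60 Hz mains notch; the ACC step band and the gravity low-pass cutoff are
    separate class attributes used by the ACC feature extractor.
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 40.0
    notch_hz: float = 60.0
    notch_q: float = 30.0

    # ACC-side cutoffs (Hz)
    step_band: tuple[float, float] = (0.5, 5.0)
    gravity_lowpass_hz: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ConfigurationError("need 0 < highpass_hz < lowpass_hz")
        if self.notch_q <= 0:
            raise ConfigurationError("notch_q must be positive")

    def validate_for_rate(self, rate: float) -> None:
        nyquist = rate / 2.0
        if self.lowpass_hz >= nyquist:
            raise ConfigurationError(
                f"lowpass_hz={self.lowpass_hz} must be below Nyquist ({nyquist} Hz)"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Classifier back-end choice with hyperparameters and decision threshold."""

    kind: str = "crf"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gbm", "crf", "lstm"):
            raise ConfigurationError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class SplitSpec:
    """Participant-level train/test partition."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    models: Sequence[ModelSpec] = field(
        default_factory=lambda: (ModelSpec(kind="crf"),)
    )
    split: SplitSpec = field(default_factory=SplitSpec)
    tau_grid: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
    )
    run_selection: bool = False
    extended_catalog: bool = False
    onset_rule: str = "first"  # or "two_consecutive"
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.tau_grid:
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError(f"tau={t} outside [0, 1]")
        if list(self.tau_grid) != sorted(self.tau_grid):
            raise ConfigurationError("tau_grid must be sorted")
        if self.onset_rule not in ("first", "two_consecutive"):
            raise ConfigurationError(f"unknown onset_rule {self.onset_rule!r}")

    def config_hash(self) -> str:
        payload = {
            "simulation": self.simulation.to_dict(),
            "filters": dataclasses.asdict(self.filters),
            "models": [dataclasses.asdict(m) for m in self.models],
            "split": dataclasses.asdict(self.split),
            "tau_grid": list(self.tau_grid),
            "run_selection": self.run_selection,
            "extended_catalog": self.extended_catalog,
            "onset_rule": self.onset_rule,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
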