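"""In-memory containers for one participant-night of patch + PSG data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BLOCK_DURATION_S, EPOCH_S, STAGES


@dataclass(frozen=True)
class Hypnogram:
    """Scored sleep stages at fixed 30-s epochs, starting at t=0."""

    stages: tuple[str, ...]
    epoch_duration: int = EPOCH_S

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage codes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_duration

    def stage_at(self, t: float) -> str:
        """Stage of the epoch containing time ``t`` (seconds from start)."""
        idx = int(t // self.epoch_duration)
        if not 0 <= idx < len(self.stages):
            raise IndexError(f"t={t} outside hypnogram")
        return self.stages[idx]


@dataclass(frozen=True)
class AccBlock:
    """One 14-s tri-axial acceleration block (columns x, y, z in g)."""

    start_time: float
    sampling_rate: float
    samples: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("ACC samples must have shape (n, 3)")
        if not np.isfinite(s).all():
            raise ValueError("ACC samples must be finite")
        expected = self.duration * self.sampling_rate
        if abs(s.shape[0] - expected) > 1:
            raise ValueError(
                f"ACC block has {s.shape[0]} samples, expected {expected:.0f}±1"
            )
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return BLOCK_DURATION_S


@dataclass(frozen=True)
class EcgBlock:
    """One 14-s single-lead ECG block (voltage in mV)."""

    start_time: float
    sampling_rate: float
    samples: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float).ravel()
        if not np.isfinite(s).all():
            raise ValueError("ECG samples must be finite")
        expected = self.duration * self.sampling_rate
        if abs(s.shape[0] - expected) > 1:
            raise ValueError(
                f"ECG block has {s.shape[0]} samples, expected {expected:.0f}±1"
            )
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return BLOCK_DURATION_S


@dataclass
class SessionRecording:
    """One participant-night: duty-cycled sensor blocks plus the hypnogram."""

    participant: str
    night: int
    hypnogram: Hypnogram
    acc_blocks: list[AccBlock] = field(default_factory=list)
    ecg_blocks: list[EcgBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        for blocks in (self.acc_blocks, self.ecg_blocks):
            starts = [b.start_time for b in blocks]
            if starts != sorted(starts):
                raise ValueError("blocks must be ordered by start time")
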