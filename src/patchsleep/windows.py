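"""5-minute window assembly from PSG epochs and duty-cycled sensor blocks.

A window spans ten 30-s PSG epochs and is labeled wake when at least five of
them are wake, sleep otherwise. Within a window the first ACC block of each
minute is kept (up to five) and the first *valid* ECG block is kept (at most
one). A window is valid when it holds at least three ACC blocks and an ECG
block; a night is usable when at least one hour of valid, overlapping ACC,
ECG and PSG data exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import EPOCHS_PER_WINDOW, FilterSpec, WINDOW_S
from .preprocess import (
    AccBlockFeatures,
    DEFAULT_QUALITY_THRESHOLD,
    EcgBlockFeatures,
    acc_block_features,
    process_ecg_block,
)
from .session import AccBlock, EcgBlock, SessionRecording

logger = logging.getLogger(__name__)

MIN_ACC_BLOCKS = 3
MAX_ACC_BLOCKS = 5
USABLE_OVERLAP_MIN = 60.0

SLEEP, WAKE = "sleep", "wake"
_STAGE_TO_BINARY = {"W": WAKE, "N1": SLEEP, "N2": SLEEP, "N3": SLEEP, "R": SLEEP}


def binarize_stage(stage: str) -> str:
    """Collapse a 5-stage PSG code to sleep/wake (N1, N2, N3, R are sleep)."""
    try:
        return _STAGE_TO_BINARY[stage]
    except KeyError:
        raise ValueError(f"unknown PSG stage code {stage!r}") from None


def label_window(epoch_states: list[str]) -> tuple[str, int]:
    """Majority label of one window: wake iff >= 5 of its 10 epochs are wake."""
    if len(epoch_states) != EPOCHS_PER_WINDOW:
        raise ValueError(
            f"a window needs exactly {EPOCHS_PER_WINDOW} epoch states, got {len(epoch_states)}"
        )
    bad = set(epoch_states) - {SLEEP, WAKE}
    if bad:
        raise ValueError(f"unknown binary states: {sorted(bad)}")
    wake_count = sum(1 for s in epoch_states if s == WAKE)
    return (WAKE if wake_count >= 5 else SLEEP), wake_count


def subsample_acc(blocks: list[AccBlock], window_start: float) -> list[AccBlock]:
    """Keep the earliest ACC block starting in each minute of the window."""
    kept: dict[int, AccBlock] = {}
    for block in blocks:
        offset = block.start_time - window_start
        minute = int(offset // 60.0)
        if not 0 <= minute < 5:
            continue
        if minute not in kept or block.start_time < kept[minute].start_time:
            kept[minute] = block
    return [kept[m] for m in sorted(kept)]


def subsample_ecg(
    blocks: list[EcgBlock],
    spec: FilterSpec,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> EcgBlockFeatures | None:
    """First valid ECG block of the window (quality gate + plausible HR).

    Blocks are evaluated in time order and evaluation stops at the first one
    passing validity; ``None`` when no block passes.
    """
    for block in blocks:
        feats = process_ecg_block(block, spec, quality_threshold)
        if feats.valid:
            return feats
    return None


@dataclass(frozen=True)
class Window:
    """One 5-minute analysis unit."""

    index: int
    start_time: float
    acc_blocks: tuple[AccBlockFeatures, ...]
    ecg_block: EcgBlockFeatures | None
    psg_label: str
    wake_epoch_count: int

    def __post_init__(self) -> None:
        if len(self.acc_blocks) > MAX_ACC_BLOCKS:
            raise ValueError("a window holds at most 5 ACC blocks")

    @property
    def valid(self) -> bool:
        return len(self.acc_blocks) >= MIN_ACC_BLOCKS and self.ecg_block is not None

    @property
    def duration(self) -> float:
        return WINDOW_S


@dataclass(frozen=True)
class NightRecord:
    """All windows of one participant-night plus the usability verdict."""

    participant: str
    night: int
    windows: tuple[Window, ...]

    @property
    def usable_overlap(self) -> float:
        """Minutes with valid, overlapping ACC, ECG and PSG data."""
        return 5.0 * sum(1 for w in self.windows if w.valid)

    @property
    def usable(self) -> bool:
        return night_usability(self)

    @property
    def valid_windows(self) -> tuple[Window, ...]:
        return tuple(w for w in self.windows if w.valid)


def night_usability(night: NightRecord) -> bool:
    """At least one hour of valid overlapping data (inclusive at 60 min)."""
    return night.usable_overlap >= USABLE_OVERLAP_MIN


def assemble_windows(
    session: SessionRecording,
    spec: FilterSpec,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> NightRecord:
    """Tile the night into 5-minute windows and populate them from the streams.

    Windows are anchored at PSG epoch 0 and assigned sensor blocks by
    start-time containment in [start, start+300). A trailing partial window
    (fewer than 10 epochs) is dropped.
    """
    hyp = session.hypnogram
    n_windows = len(hyp) // EPOCHS_PER_WINDOW
    sensor_end = max(
        [b.start_time + b.duration for b in session.acc_blocks + session.ecg_blocks],
        default=0.0,
    )
    if hyp.duration_s < sensor_end:
        logger.info(
            "hypnogram (%.0f s) shorter than sensor streams (%.0f s); truncating to overlap",
            hyp.duration_s,
            sensor_end,
        )

    binary = [binarize_stage(s) for s in hyp.stages]
    acc_by_window: dict[int, list[AccBlock]] = {}
    for block in session.acc_blocks:
        w = int(block.start_time // WINDOW_S)
        acc_by_window.setdefault(w, []).append(block)
    ecg_by_window: dict[int, list[EcgBlock]] = {}
    for block in session.ecg_blocks:
        w = int(block.start_time // WINDOW_S)
        ecg_by_window.setdefault(w, []).append(block)

    windows = []
    for i in range(n_windows):
        start = i * float(WINDOW_S)
        states = binary[i * EPOCHS_PER_WINDOW : (i + 1) * EPOCHS_PER_WINDOW]
        label, wake_count = label_window(states)
        kept_acc = subsample_acc(acc_by_window.get(i, []), start)
        acc_feats = tuple(acc_block_features(b, spec) for b in kept_acc)
        ecg_feats = subsample_ecg(ecg_by_window.get(i, []), spec, quality_threshold)
        windows.append(
            Window(
                index=i,
                start_time=start,
                acc_blocks=acc_feats,
                ecg_block=ecg_feats,
                psg_label=label,
                wake_epoch_count=wake_count,
            )
        )
    return NightRecord(session.participant, session.night, tuple(windows))
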