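"""Per-window feature vectors.

Block-level ACC features are aggregated to window level as mean, sample SD
and range; step counts are summed; the window's heart rate is carried both
raw and as a z-score against the participant's own HR mean and SD. Lag
difference features (window minus each of the previous 5 windows, zero when
the earlier window is missing) add short-range temporal context for the
sequence-free classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import NightRecord, SLEEP, Window

logger = logging.getLogger(__name__)

BLOCKWISE_FEATURES = ("body_angle", "mean_x", "mean_y", "mean_z")
EXTENDED_BLOCKWISE_FEATURES = ("sd_x", "sd_y", "sd_z", "mag_mean", "mag_sd")
DIFF_LAGS = (1, 2, 3, 4, 5)
KEY_COLUMNS = ["participant", "group", "night", "window_index", "label"]


def base_feature_names(extended: bool = False) -> list[str]:
    """Ordered catalog of base (non-difference) feature names."""
    blockwise = BLOCKWISE_FEATURES + (EXTENDED_BLOCKWISE_FEATURES if extended else ())
    names = ["total_step_count"]
    for f in blockwise:
        names += [f"{f}_mean", f"{f}_sd", f"{f}_range"]
    names += ["mean_hr", "hr_z"]
    return names


@dataclass(frozen=True)
class ParticipantHrStats:
    """Mean and sample SD of a participant's valid block heart rates."""

    participant: str
    hr_mean: float
    hr_sd: float
    n_blocks: int


def participant_hr_stats(participant: str, block_hrs: list[float]) -> ParticipantHrStats:
    """HR normalization statistics over all of a participant's valid blocks.

    Requires at least two blocks with non-degenerate spread; otherwise the
    participant cannot be z-scored and is excluded upstream.
    """
    hrs = np.asarray(block_hrs, dtype=float)
    if hrs.size < 2:
        raise ValueError(
            f"participant {participant}: need >= 2 valid ECG blocks, got {hrs.size}"
        )
    sd = float(hrs.std(ddof=1))
    if sd <= 0:
        raise ValueError(f"participant {participant}: degenerate HR spread (SD=0)")
    return ParticipantHrStats(participant, float(hrs.mean()), sd, int(hrs.size))


def window_feature_vector(
    window: Window, stats: ParticipantHrStats, extended: bool = False
) -> dict[str, float]:
    """Base features of one valid window."""
    if not window.valid:
        raise ValueError(f"window {window.index} is not valid")
    blockwise = BLOCKWISE_FEATURES + (EXTENDED_BLOCKWISE_FEATURES if extended else ())
    out: dict[str, float] = {
        "total_step_count": float(sum(b.step_count for b in window.acc_blocks))
    }
    for f in blockwise:
        vals = np.array([getattr(b, f) for b in window.acc_blocks], dtype=float)
        out[f"{f}_mean"] = float(vals.mean())
        out[f"{f}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[f"{f}_range"] = float(np.ptp(vals))
    mean_hr = window.ecg_block.mean_hr
    out["mean_hr"] = float(mean_hr)
    out["hr_z"] = float((mean_hr - stats.hr_mean) / stats.hr_sd)
    return out


def build_feature_table(
    nights: list[tuple[str, NightRecord]], extended: bool = False
) -> pd.DataFrame:
    """Feature rows for every valid window of every usable night.

    ``nights`` pairs a group tag (SMI/HV) with a NightRecord. HR statistics
    are computed per participant over the kept ECG blocks of all their
    usable nights; participants with fewer than two such blocks (or zero HR
    spread) are dropped with a log message.
    """
    usable = [(g, n) for g, n in nights if n.usable]
    hr_by_participant: dict[str, list[float]] = {}
    for _, night in usable:
        for w in night.valid_windows:
            hr_by_participant.setdefault(night.participant, []).append(
                w.ecg_block.mean_hr
            )
    stats: dict[str, ParticipantHrStats] = {}
    for pid, hrs in hr_by_participant.items():
        try:
            stats[pid] = participant_hr_stats(pid, hrs)
        except ValueError as exc:
            logger.warning("excluding participant: %s", exc)

    rows = []
    for group, night in usable:
        if night.participant not in stats:
            continue
        for w in night.valid_windows:
            row = {
                "participant": night.participant,
                "group": group,
                "night": night.night,
                "window_index": w.index,
                "label": 1 if w.psg_label == SLEEP else 0,
            }
            row.update(window_feature_vector(w, stats[night.participant], extended))
            rows.append(row)
    columns = KEY_COLUMNS + base_feature_names(extended)
    return pd.DataFrame(rows, columns=columns)


def difference_features(
    table: pd.DataFrame, feature_names: list[str], lags: tuple[int, ...] = DIFF_LAGS
) -> pd.DataFrame:
    """Append lagged difference columns ``<f>_d<k>`` per night.

    For window w and lag k the difference is f(w) − f(w−k) when window
    w−k exists (is a valid window of the same night); a missing earlier
    window contributes 0, i.e. it is treated as having the current value.
    """
    table = table.sort_values(["participant", "night", "window_index"]).reset_index(
        drop=True
    )
    new_cols: dict[str, np.ndarray] = {
        f"{f}_d{k}": np.zeros(len(table)) for f in feature_names for k in lags
    }
    for _, night_df in table.groupby(["participant", "night"], sort=False):
        idx_of = {int(w): i for i, w in zip(night_df.index, night_df["window_index"])}
        for f in feature_names:
            vals = table[f]
            for row_i, w in zip(night_df.index, night_df["window_index"]):
                for k in lags:
                    j = idx_of.get(int(w) - k)
                    if j is not None:
                        new_cols[f"{f}_d{k}"][row_i] = vals[row_i] - vals[j]
    return pd.concat([table, pd.DataFrame(new_cols, index=table.index)], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the model-input columns of a feature table."""
    return [c for c in table.columns if c not in KEY_COLUMNS]
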