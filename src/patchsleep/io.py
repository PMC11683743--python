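"""Session CSV formats.

Per night: ``acc.csv`` (t_s, ax_g, ay_g, az_g), ``ecg.csv`` (t_s, mv) and
``psg.csv`` (epoch_start_s, stage in {W, N1, N2, N3, R}). Times are seconds
from session start; sensor rows are grouped back into 14-s duty-cycle blocks
by their 20-s interval.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import BLOCK_PERIOD_S, EPOCH_S, STAGES
from .session import AccBlock, EcgBlock, Hypnogram, SessionRecording


class SessionParseError(ValueError):
    """Malformed session file (reported with file and row context)."""


def write_session(session: SessionRecording, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    acc_rows = []
    for b in session.acc_blocks:
        t = b.start_time + np.arange(b.samples.shape[0]) / b.sampling_rate
        acc_rows.append(
            np.column_stack([t, b.samples[:, 0], b.samples[:, 1], b.samples[:, 2]])
        )
    acc = np.vstack(acc_rows) if acc_rows else np.empty((0, 4))
    pd.DataFrame(acc, columns=["t_s", "ax_g", "ay_g", "az_g"]).to_csv(
        out / "acc.csv", index=False, float_format="%.6f"
    )

    ecg_rows = []
    for b in session.ecg_blocks:
        t = b.start_time + np.arange(b.samples.shape[0]) / b.sampling_rate
        ecg_rows.append(np.column_stack([t, b.samples]))
    ecg = np.vstack(ecg_rows) if ecg_rows else np.empty((0, 2))
    pd.DataFrame(ecg, columns=["t_s", "mv"]).to_csv(
        out / "ecg.csv", index=False, float_format="%.6f"
    )

    hyp = session.hypnogram
    psg = pd.DataFrame(
        {
            "epoch_start_s": np.arange(len(hyp)) * hyp.epoch_duration,
            "stage": list(hyp.stages),
        }
    )
    psg.to_csv(out / "psg.csv", index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionParseError(f"{path}: missing column(s) {missing}")


def _check_monotone(t: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based row numbers
        raise SessionParseError(f"{path}: non-monotone time at data row {bad[0] + 2}")


def _blocks_from_stream(t: np.ndarray, values: np.ndarray, cls):
    blocks = []
    if t.size == 0:
        return blocks
    block_idx = np.floor(t / BLOCK_PERIOD_S).astype(int)
    for k in np.unique(block_idx):
        mask = block_idx == k
        n = int(mask.sum())
        if n < 2:
            continue
        tt = t[mask]
        dt = float(np.median(np.diff(tt)))
        rate = round(1.0 / dt)
        blocks.append(cls(float(k * BLOCK_PERIOD_S), float(rate), values[mask]))
    return blocks


def read_session(path: str | Path, participant: str = "", night: int = 0) -> SessionRecording:
    """Read one night's acc/ecg/psg CSVs into a typed, time-sorted session."""
    p = Path(path)
    psg_path = p / "psg.csv"
    psg = pd.read_csv(psg_path)
    _require_columns(psg, ["epoch_start_s", "stage"], psg_path)
    if len(psg) == 0:
        raise SessionParseError(f"{psg_path}: no epochs")
    starts = psg["epoch_start_s"].to_numpy(dtype=float)
    _check_monotone(starts, psg_path)
    expected = np.arange(len(psg)) * float(EPOCH_S)
    if not np.allclose(starts, expected):
        raise SessionParseError(
            f"{psg_path}: epoch starts must be contiguous multiples of {EPOCH_S} s"
        )
    stages = []
    for row, stage in enumerate(psg["stage"]):
        if stage not in STAGES:
            raise SessionParseError(
                f"{psg_path}: unknown stage {stage!r} at data row {row + 2}"
            )
        stages.append(stage)
    hyp = Hypnogram(tuple(stages))

    acc_path = p / "acc.csv"
    acc = pd.read_csv(acc_path)
    _require_columns(acc, ["t_s", "ax_g", "ay_g", "az_g"], acc_path)
    t = acc["t_s"].to_numpy(dtype=float)
    _check_monotone(t, acc_path)
    acc_blocks = _blocks_from_stream(
        t, acc[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float), AccBlock
    )

    ecg_path = p / "ecg.csv"
    ecg = pd.read_csv(ecg_path)
    _require_columns(ecg, ["t_s", "mv"], ecg_path)
    t = ecg["t_s"].to_numpy(dtype=float)
    _check_monotone(t, ecg_path)
    ecg_blocks = _blocks_from_stream(t, ecg["mv"].to_numpy(dtype=float), EcgBlock)

    return SessionRecording(
        participant=participant or p.parent.name or "P000",
        night=night,
        hypnogram=hyp,
        acc_blocks=acc_blocks,
        ecg_blocks=ecg_blocks,
    )
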