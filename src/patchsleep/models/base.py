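"""Shared modeling infrastructure: sequences, standardization, back-end registry.

All three back-ends consume per-night ordered window sequences; the
sequence-free gradient-boosting model simply flattens them. Features are
standardized with statistics fit on the training windows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import ModelSpec

MAX_SEQUENCE_GAP = 1  # nights split where more than this many windows are missing


@dataclass(frozen=True)
class Sequence:
    """One ordered run of valid windows from a single night."""

    participant: str
    night: int
    segment: int
    window_index: np.ndarray  # (T,)
    X: np.ndarray  # (T, D)
    y: np.ndarray | None  # (T,) in {0,1}; 1 = sleep


@dataclass(frozen=True)
class PredictionSeries:
    """Per-window sleep probabilities for one night segment."""

    participant: str
    night: int
    segment: int
    window_index: np.ndarray
    p_sleep: np.ndarray
    y_true: np.ndarray | None = None


def build_sequences(
    table: pd.DataFrame,
    feature_cols: list[str],
    with_labels: bool = True,
    max_gap: int = MAX_SEQUENCE_GAP,
) -> list[Sequence]:
    """Split each night's valid windows into contiguous-enough segments.

    A new segment starts wherever more than ``max_gap`` consecutive windows
    are missing, so the chain models never bridge long recording holes.
    """
    sequences: list[Sequence] = []
    table = table.sort_values(["participant", "night", "window_index"])
    for (pid, night), night_df in table.groupby(["participant", "night"], sort=True):
        idx = night_df["window_index"].to_numpy()
        breaks = np.where(np.diff(idx) > max_gap + 1)[0] + 1
        segments = np.split(np.arange(len(idx)), breaks)
        for seg_id, rows in enumerate(segments):
            if rows.size == 0:
                continue
            sub = night_df.iloc[rows]
            sequences.append(
                Sequence(
                    participant=str(pid),
                    night=int(night),
                    segment=seg_id,
                    window_index=sub["window_index"].to_numpy(),
                    X=sub[feature_cols].to_numpy(dtype=float),
                    y=sub["label"].to_numpy(dtype=int) if with_labels else None,
                )
            )
    return sequences


@dataclass
class Standardizer:
    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


class TrainedClassifier:
    """A fitted back-end plus the schema it was trained with."""

    def __init__(self, spec: ModelSpec, feature_names: list[str]):
        self.spec = spec
        self.feature_names = list(feature_names)
        self.scaler = Standardizer()
        self.metadata: dict = {}

    # back-ends implement _fit / _predict on standardized sequences
    def _fit(self, sequences: list[Sequence]) -> None:
        raise NotImplementedError

    def _predict(self, sequences: list[Sequence]) -> list[np.ndarray]:
        raise NotImplementedError

    def fit(self, sequences: list[Sequence]) -> "TrainedClassifier":
        if not sequences:
            raise ValueError("no training sequences")
        for s in sequences:
            if s.X.shape[0] == 0:
                raise ValueError("empty sequence")
            if s.y is None:
                raise ValueError("training sequences need labels")
        X_all = np.vstack([s.X for s in sequences])
        y_all = np.concatenate([s.y for s in sequences])
        if len(np.unique(y_all)) < 2:
            raise ValueError("training labels are single-class")
        self.scaler.fit(X_all)
        self.metadata = {
            "n_windows": int(len(y_all)),
            "n_sequences": len(sequences),
            "class_counts": {int(k): int(v) for k, v in zip(*np.unique(y_all, return_counts=True))},
        }
        self._fit([self._standardized(s) for s in sequences])
        return self

    def _standardized(self, s: Sequence) -> Sequence:
        return Sequence(
            s.participant, s.night, s.segment, s.window_index,
            self.scaler.transform(s.X), s.y,
        )

    def predict_series(self, sequences: list[Sequence]) -> list[PredictionSeries]:
        for s in sequences:
            if s.X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"feature schema mismatch: model expects {len(self.feature_names)} "
                    f"columns, got {s.X.shape[1]}"
                )
        probs = self._predict([self._standardized(s) for s in sequences])
        out = []
        for s, p in zip(sequences, probs):
            p = np.asarray(p, dtype=float)
            if p.shape[0] != s.X.shape[0]:
                raise RuntimeError("back-end returned wrong-length probabilities")
            out.append(
                PredictionSeries(s.participant, s.night, s.segment, s.window_index, p, s.y)
            )
        return out


def train_classifier(
    spec: ModelSpec, table: pd.DataFrame, feature_cols: list[str]
) -> TrainedClassifier:
    """Fit the requested back-end on a training feature table.

    Missing feature columns are reported by name.
    """
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    from .crf import CrfClassifier
    from .gbm import GbmClassifier
    from .lstm import LstmClassifier

    backends = {"gbm": GbmClassifier, "crf": CrfClassifier, "lstm": LstmClassifier}
    model = backends[spec.kind](spec, feature_cols)
    sequences = build_sequences(table, feature_cols, with_labels=True)
    return model.fit(sequences)


def predict_sleep_probability(
    model: TrainedClassifier, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-window P(sleep) for every valid window of a feature table."""
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    with_labels = "label" in table.columns
    sequences = build_sequences(table, model.feature_names, with_labels=with_labels)
    series = model.predict_series(sequences)
    rows = []
    for s in series:
        for i in range(len(s.window_index)):
            rows.append(
                {
                    "participant": s.participant,
                    "night": s.night,
                    "segment": s.segment,
                    "window_index": int(s.window_index[i]),
                    "p_sleep": float(s.p_sleep[i]),
                    **({"label": int(s.y_true[i])} if s.y_true is not None else {}),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["participant", "night", "window_index"]
    ).reset_index(drop=True)


def apply_threshold(p_sleep: np.ndarray, tau: float) -> np.ndarray:
    """Label sleep (1) where P(sleep) >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    return (np.asarray(p_sleep, dtype=float) >= tau).astype(int)
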