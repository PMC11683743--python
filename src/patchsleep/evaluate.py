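"""Splits, classification metrics, sleep parameters and agreement statistics.

Sensitivity is sleep detection (fraction of sleep windows labeled sleep),
specificity is wake detection, F1 is the harmonic mean of precision and
recall for the sleep class, and AUC is the rank-based probability that a
random sleep window scores above a random wake window. Night-level sleep
parameters (TST, SOL, WASO, Eff) are derived from the 5-minute label
sequence, and device-vs-PSG agreement uses the paired t test, the paired
Hedges g effect size, and the regression R² (proportional bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from sklearn.metrics import roc_auc_score

from .config import ModelSpec, SplitSpec

logger = logging.getLogger(__name__)

WINDOW_MINUTES = 5.0


def split_cohort(
    participant_ids: list[str], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Random participant-level train/test partition.

    |train| = round(train_fraction * N); all nights of a participant follow
    the participant.
    """
    ids = list(participant_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    n_train = int(round(spec.train_fraction * len(ids)))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("train_fraction leaves one side of the split empty")
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


@dataclass(frozen=True)
class MetricReport:
    sensitivity: float
    specificity: float
    f1: float
    auc: float  # nan when truth is single-class

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
        }


def confusion_metrics(
    pred_labels: np.ndarray, true_labels: np.ndarray, p_sleep: np.ndarray | None = None
) -> MetricReport:
    """Window-pooled classification metrics; sleep (1) is the positive class."""
    yp = np.asarray(pred_labels, dtype=int)
    yt = np.asarray(true_labels, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("prediction and truth lengths differ")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sens / (precision + sens)
        if (tp + fn) and (precision + sens) > 0
        else 0.0
    )
    if p_sleep is not None and len(np.unique(yt)) == 2:
        auc = float(roc_auc_score(yt, np.asarray(p_sleep, dtype=float)))
    else:
        if p_sleep is not None:
            logger.warning("single-class truth: AUC undefined")
        auc = float("nan")
    return MetricReport(float(sens), float(spec), float(f1), auc)


@dataclass(frozen=True)
class SleepParameters:
    """Night-level sleep summary in minutes (Eff is a proportion).

    SOL and WASO are undefined (nan) for a night with no sleep-labeled
    window; such nights are excluded from SOL/WASO aggregation upstream.
    """

    tst: float
    sol: float
    waso: float
    eff: float

    @property
    def onset_defined(self) -> bool:
        return not np.isnan(self.sol)


def derive_sleep_parameters(
    labels: np.ndarray,
    window_minutes: float = WINDOW_MINUTES,
    onset_rule: str = "first",
) -> SleepParameters:
    """TST/SOL/WASO/Eff from one night's ordered window labels (1 = sleep).

    Sleep onset is the first sleep window (``onset_rule='first'``) or the
    first of two consecutive sleep windows (``'two_consecutive'``).
    """
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("need at least one window")
    n_sleep = int(y.sum())
    tst = window_minutes * n_sleep
    eff = n_sleep / y.size

    if onset_rule == "first":
        onsets = np.flatnonzero(y == 1)
        onset = int(onsets[0]) if onsets.size else None
    elif onset_rule == "two_consecutive":
        pairs = np.flatnonzero((y[:-1] == 1) & (y[1:] == 1))
        onset = int(pairs[0]) if pairs.size else None
    else:
        raise ValueError(f"unknown onset rule {onset_rule!r}")

    if onset is None:
        return SleepParameters(tst, float("nan"), float("nan"), eff)
    sol = window_minutes * onset
    waso = window_minutes * int(np.sum(y[onset:] == 0))
    return SleepParameters(tst, sol, waso, eff)


@dataclass(frozen=True)
class ParameterComparison:
    """Paired device-vs-PSG agreement for one sleep parameter."""

    parameter: str
    n: int
    bias: float  # mean(device - psg)
    t: float
    p_value: float
    hedges_g: float
    r_squared: float
    degenerate: bool = False  # SD of differences is zero; t and g undefined


def compare_parameters(
    device: np.ndarray, psg: np.ndarray, parameter: str = ""
) -> ParameterComparison:
    """Paired t, paired Hedges g and regression R² between device and PSG values."""
    x = np.asarray(device, dtype=float)
    y = np.asarray(psg, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("device and psg must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 paired nights")
    d = x - y
    bias = float(d.mean())
    if np.allclose(y, y[0]):
        r2 = float("nan")  # no PSG variance to explain
    else:
        reg = pg.linear_regression(y, x)
        r2 = float(reg["r2"].iloc[0])
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        g = 0.0 if bias == 0 else float("inf") * np.sign(bias)
    else:
        g = float(pg.compute_effsize(x, y, paired=True, eftype="hedges"))
    if d.std(ddof=1) == 0:
        logger.warning("%s: zero variance of paired differences; t undefined", parameter)
        return ParameterComparison(
            parameter, x.size, bias, float("nan"), float("nan"), g, r2, degenerate=True
        )
    tt = pg.ttest(x, y, paired=True)
    pcol = "p_val" if "p_val" in tt.columns else "p-val"
    return ParameterComparison(
        parameter,
        x.size,
        bias,
        float(tt["T"].iloc[0]),
        float(tt[pcol].iloc[0]),
        g,
        r2,
    )


def threshold_sweep(
    p_sleep: np.ndarray, true_labels: np.ndarray, tau_grid: list[float]
) -> pd.DataFrame:
    """Sensitivity/specificity/F1 at each probability threshold."""
    if list(tau_grid) != sorted(tau_grid):
        raise ValueError("tau_grid must be sorted")
    from .models import apply_threshold

    rows = []
    for tau in tau_grid:
        m = confusion_metrics(apply_threshold(p_sleep, tau), true_labels, p_sleep)
        rows.append({"tau": tau, **m.as_dict()})
    return pd.DataFrame(rows)


def f1_maximizing_threshold(
    p_sleep: np.ndarray, true_labels: np.ndarray, tau_grid: list[float]
) -> float:
    """Grid threshold with the highest sleep-class F1 (first on ties)."""
    sweep = threshold_sweep(p_sleep, true_labels, tau_grid)
    return float(sweep.loc[sweep["f1"].idxmax(), "tau"])


@dataclass(frozen=True)
class CvReport:
    """Participant-level k-fold cross-validation summary."""

    folds: tuple[MetricReport, ...]
    fold_participants: tuple[tuple[str, ...], ...]
    summary: dict = field(default_factory=dict)


def _summarize(folds: tuple[MetricReport, ...]) -> dict:
    out = {}
    for name in ("sensitivity", "specificity", "f1", "auc"):
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        q1, q3 = np.nanpercentile(vals, [25, 75])
        out[name] = {
            "mean": float(np.nanmean(vals)),
            "sd": float(np.nanstd(vals, ddof=1)),
            "iqr": [float(q1), float(q3)],
        }
    return out


def participant_folds(
    participants: list[str], k: int, seed: int = 0
) -> list[np.ndarray]:
    """Shuffle participants and partition them into k near-equal folds."""
    ids = np.array(sorted(participants))
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of participants ({len(ids)})")
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(ids), k)


def kfold_cv(
    table: pd.DataFrame,
    feature_cols: list[str],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
) -> CvReport:
    """Re-randomized k-fold CV with participants as the fold unit.

    Every participant appears in exactly one validation fold; metrics are
    window-pooled within each fold at the spec's threshold.
    """
    from .models import apply_threshold, predict_sleep_probability, train_classifier

    folds_ids = participant_folds(list(table["participant"].unique()), k, seed)

    folds = []
    for fold in folds_ids:
        val_mask = table["participant"].isin(fold)
        model = train_classifier(spec, table[~val_mask], feature_cols)
        preds = predict_sleep_probability(model, table[val_mask])
        labels = apply_threshold(preds["p_sleep"].to_numpy(), spec.threshold)
        folds.append(
            confusion_metrics(labels, preds["label"].to_numpy(), preds["p_sleep"].to_numpy())
        )
    folds = tuple(folds)
    return CvReport(
        folds=folds,
        fold_participants=tuple(tuple(sorted(f)) for f in folds_ids),
        summary=_summarize(folds),
    )
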