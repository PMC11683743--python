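"""Greedy backwards feature elimination scored by F1.

Starting from the full catalog, each round fits one candidate model per
remaining feature with that feature removed and keeps the removal whose
cross-validated F1 (sleep class) is highest. Elimination continues while the
best removal does not *worsen* the score by more than a small tolerance, so
redundant or uninformative features are stripped even on score plateaus; it
stops when every remaining removal costs F1, or one feature remains.

Scores are estimated by participant-grouped k-fold cross-validation inside
the training set only, which keeps window-level leakage out of the estimate
and the test set untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold

# Plateau tolerance for the stopping rule, sized to the fold-level noise of
# the CV F1 estimate (F1 resolution is ~1/(2 * windows per fold)); removals
# that cost no more than this are treated as score-neutral.
DEFAULT_TOL = 5e-3
_SELECTION_LGBM = {
    "n_estimators": 60,
    "learning_rate": 0.1,
    "num_leaves": 15,
    "min_child_samples": 20,
    "n_jobs": 1,
    "verbose": -1,
    "deterministic": True,
    "force_row_wise": True,
}


@dataclass(frozen=True)
class SelectionTrace:
    """Elimination history: (removed feature, retained score) per round."""

    initial_score: float
    rounds: tuple[tuple[str, float], ...]
    final_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.final_subset:
            raise ValueError("final subset must be non-empty")


def _cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cols: list[int],
    n_folds: int,
    seed: int,
) -> float:
    from lightgbm import LGBMClassifier

    n_folds = min(n_folds, len(np.unique(groups)))
    if n_folds < 2:
        raise ValueError("need at least 2 participant groups for grouped CV")
    cv = GroupKFold(n_splits=n_folds)
    Xs = X[:, cols]
    scores = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        for train_idx, val_idx in cv.split(Xs, y, groups):
            model = LGBMClassifier(random_state=seed, **_SELECTION_LGBM)
            model.fit(Xs[train_idx], y[train_idx])
            pred = model.predict(Xs[val_idx])
            scores.append(f1_score(y[val_idx], pred, pos_label=1, zero_division=0))
    return float(np.mean(scores))


def backward_greedy_selection(
    table: pd.DataFrame,
    feature_names: list[str],
    n_folds: int = 5,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> SelectionTrace:
    """Run backwards greedy elimination on a training feature table.

    ``table`` must carry the feature columns plus ``label`` (1 = sleep) and
    ``participant`` (the CV grouping unit). Ties between equally scoring
    removals are broken toward the lowest feature index, so the procedure is
    deterministic given the seed.
    """
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features to select from")
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    X = table[feature_names].to_numpy(dtype=float)
    groups = table["participant"].to_numpy()

    remaining = list(range(len(feature_names)))
    current = _cv_f1(X, y, groups, remaining, n_folds, seed)
    initial = current
    rounds: list[tuple[str, float]] = []
    while len(remaining) > 1:
        best_score = -np.inf
        best_pos = None
        for pos in range(len(remaining)):  # ascending index; first wins ties
            cand = remaining[:pos] + remaining[pos + 1 :]
            score = _cv_f1(X, y, groups, cand, n_folds, seed)
            if score > best_score:
                best_score, best_pos = score, pos
        if best_score < current - tol:
            break  # every removal costs F1
        removed = remaining.pop(best_pos)
        rounds.append((feature_names[removed], best_score))
        current = best_score
    return SelectionTrace(
        initial_score=initial,
        rounds=tuple(rounds),
        final_subset=tuple(feature_names[i] for i in remaining),
    )
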