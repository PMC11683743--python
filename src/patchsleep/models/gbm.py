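"""Gradient-boosted tree back-end (LightGBM).

Window-independent: sequences are flattened and temporal context enters only
through the lag difference features.
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import Sequence, TrainedClassifier

DEFAULT_PARAMS = {
    "n_estimators": 200,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 20,
    "n_jobs": 1,
    "verbose": -1,
    "deterministic": True,
    "force_row_wise": True,
}


class GbmClassifier(TrainedClassifier):
    def __init__(self, spec, feature_names):
        super().__init__(spec, feature_names)
        from lightgbm import LGBMClassifier

        params = {**DEFAULT_PARAMS, **dict(spec.hyperparameters)}
        self.booster = LGBMClassifier(random_state=spec.seed, **params)

    def _fit(self, sequences: list[Sequence]) -> None:
        X = np.vstack([s.X for s in sequences])
        y = np.concatenate([s.y for s in sequences])
        self.booster.fit(X, y)

    def _predict(self, sequences: list[Sequence]) -> list[np.ndarray]:
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names even for
            # numpy-in/numpy-out round trips
            warnings.filterwarnings("ignore", message=".*valid feature names.*")
            return [self.booster.predict_proba(s.X)[:, 1] for s in sequences]
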