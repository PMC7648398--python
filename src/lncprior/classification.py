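"""The three class-weighted binary classifiers (LR, SVM, RF).

Models are trained on the concatenated expression-code + k-mer feature
table. Class imbalance is handled by weighting: with the study's 604
positive and 1,594 negative instances the negative/positive weights are
1 and 2.6391. Min-max scaling statistics are fit on the training rows
inside :func:`train_model` and stored with the model, so held-out and
candidate rows are always scaled with training statistics (a
``global_stats`` argument reproduces the fit-once-globally variant).

SVM probabilities come from Platt-style sigmoid calibration fitted via
internal cross-validation on the training folds (scikit-learn's
``SVC(probability=True)``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .expression_features import minmax_normalize
from .io_formats import LabelSet

logger = logging.getLogger("lncprior")

ALGORITHMS = ("LR", "SVM", "RF")

# Conventional defaults; every entry is overridable through
# ModelConfig.hyperparameters.
_DEFAULT_HYPERPARAMETERS = {
    "LR": {"C": 1.0, "max_iter": 2000, "solver": "lbfgs"},  # lbfgs => L2 penalty
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale", "probability": True},
    "RF": {"n_estimators": 500, "n_jobs": 1},
}


def make_class_weights(labels: LabelSet) -> tuple[float, float]:
    """Return (w_neg, w_pos) = (1, |negatives| / |positives|).

    Full precision is returned; round w_pos to 4 decimals for
    reporting (604/1,594 gives 2.6391).
    """
    n_pos, n_neg = len(labels.positives), len(labels.negatives)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    return 1.0, n_neg / n_pos


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm choice plus class weights and hyperparameter overrides.

    ``class_weight_neg_to_pos=None`` means: derive (1, n_neg/n_pos)
    from the training labels at fit time.
    """

    algorithm: str = "LR"
    class_weight_neg_to_pos: tuple[float, float] | None = None
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.class_weight_neg_to_pos is not None:
            w_neg, w_pos = self.class_weight_neg_to_pos
            if w_neg <= 0 or w_pos <= 0:
                raise ValueError("class weights must be > 0")


def build_estimator(config: ModelConfig, class_weight: dict):
    params = dict(_DEFAULT_HYPERPARAMETERS[config.algorithm])
    params.update(config.hyperparameters)
    params["class_weight"] = class_weight
    params["random_state"] = config.seed
    if config.algorithm == "LR":
        return LogisticRegression(**params)
    if config.algorithm == "SVM":
        return SVC(**params)
    return RandomForestClassifier(**params)


@dataclass
class TrainedModel:
    """A fitted classifier with its preprocessing state.

    ``scaling_stats`` are the per-feature (min, max) from the training
    rows; ``feature_names`` fixes the required column order for
    prediction.
    """

    config: ModelConfig
    estimator: object
    feature_names: list
    scaling_stats: tuple[np.ndarray, np.ndarray]
    class_weights: tuple[float, float]


def train_model(
    features: pd.DataFrame,
    labels: LabelSet,
    config: ModelConfig,
    global_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit one class-weighted classifier on the labeled rows of ``features``.

    Min-max statistics are computed on the training rows (or taken from
    ``global_stats``) and stored. Deterministic given ``config.seed``.
    Missing labeled genes raise an error listing the offending ids.
    """
    labeled = sorted(labels.positives) + sorted(labels.negatives)
    missing = [g for g in labeled if g not in features.index]
    if missing:
        raise ValueError(f"labeled genes missing from feature table: {missing[:10]}")
    X_raw = features.loc[labeled]
    if X_raw.isna().any().any():
        raise ValueError("feature table contains missing values")
    y = labels.as_series(labeled).to_numpy()

    X_scaled, stats = minmax_normalize(X_raw, fit_stats=global_stats)
    if config.class_weight_neg_to_pos is not None:
        w_neg, w_pos = config.class_weight_neg_to_pos
    else:
        w_neg, w_pos = make_class_weights(labels)
    estimator = build_estimator(config, {0: w_neg, 1: w_pos})
    estimator.fit(X_scaled.to_numpy(), y)
    return TrainedModel(
        config=config,
        estimator=estimator,
        feature_names=list(features.columns),
        scaling_stats=stats,
        class_weights=(w_neg, w_pos),
    )


def predict_proba(model: TrainedModel, features: pd.DataFrame) -> pd.Series:
    """Positive-class probability per gene, in [0, 1].

    Rows are scaled with the stored training statistics. The feature
    columns must match the model's ``feature_names`` (any order); an
    unknown or missing feature is an error.
    """
    extra = [c for c in features.columns if c not in model.feature_names]
    missing = [c for c in model.feature_names if c not in features.columns]
    if extra or missing:
        raise ValueError(
            f"feature mismatch: unknown={extra[:5]} missing={missing[:5]}"
        )
    X = features[model.feature_names]
    X_scaled, _ = minmax_normalize(X, fit_stats=model.scaling_stats)
    proba = model.estimator.predict_proba(X_scaled.to_numpy())
    positive_col = list(model.estimator.classes_).index(1)
    return pd.Series(proba[:, positive_col], index=features.index, name="probability")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the model; a .json sidecar records config and scaling."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "algorithm": model.config.algorithm,
        "seed": model.config.seed,
        "hyperparameters": model.config.hyperparameters,
        "class_weights": list(model.class_weights),
        "feature_names": list(model.feature_names),
        "scaling_min": np.asarray(model.scaling_stats[0]).tolist(),
        "scaling_max": np.asarray(model.scaling_stats[1]).tolist(),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as handle:
        json.dump(sidecar, handle, indent=2, sort_keys=True)
        handle.write("\n")


def load_model(path: str | Path) -> TrainedModel:
    return joblib.load(path)
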