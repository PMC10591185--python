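"""The three-classifier voting ensemble and the dual-species intersection.

Three base classifiers are trained on the selected feature columns with the
method's fixed hyperparameters:

* SVM with a Gaussian radial-basis kernel, C-classification (C = 1,
  gamma = 1/n_features); features are standardized for the SVM only.
* Random forest with 500 trees and 5 candidate variables per split.
* Stochastic gradient boosting: 150 trees, interaction depth 3,
  shrinkage 0.1, subsample fraction 0.5.

Each base model casts a binary vote P_i per window; the ensemble score is
the mean vote (1/M) * sum(P_i) with M = 3, and the call is positive when at
least two of the three votes are positive.  Because M is odd the score is
quantized to {0, 1/3, 2/3, 1} and ties are impossible.

For cross-species scanning, two independently trained ensembles (e.g. a
rice-trained and an Arabidopsis-trained model) are combined by intersection:
a window is called 6mA only if *both* models call it, which trades
sensitivity for a lower false-positive rate.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import encode
from .seqio import SequenceWindow, validate_window

N_MODELS = 3
CALL_THRESHOLD = 2 / 3  # at least two of three votes


@dataclass(frozen=True)
class BaseModelConfig:
    """Hyperparameters of the three base classifiers."""

    svm_c: float = 1.0
    svm_gamma: str | float = "auto"  # sklearn 'auto' == 1/n_features
    rf_n_trees: int = 500
    rf_vars_per_split: int = 5
    gb_subsample: float = 0.5
    gb_depth: int = 3
    gb_shrinkage: float = 0.1
    gb_n_trees: int = 150
    standardize_for_svm: bool = True

    def __post_init__(self) -> None:
        numeric = [self.svm_c, self.rf_n_trees, self.rf_vars_per_split,
                   self.gb_subsample, self.gb_depth, self.gb_shrinkage,
                   self.gb_n_trees]
        if any(v <= 0 for v in numeric):
            raise ValueError("all hyperparameters must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PredictionResult:
    """Per-window votes, mean-vote score and binary 6mA call."""

    window: SequenceWindow
    votes: tuple[int, ...] | None
    score: float
    call: bool


@dataclass
class EnsembleModel:
    """Three trained base models plus the feature subset they share."""

    svm: SVC
    rf: RandomForestClassifier
    gb: GradientBoostingClassifier
    scaler: StandardScaler | None
    selected_features: tuple[str, ...]
    species_tag: str
    config: BaseModelConfig
    metadata: dict

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain an EnsembleModel")
        return model


def train_ensemble(features: pd.DataFrame, labels,
                   selected_features: Sequence[str] | None = None,
                   config: BaseModelConfig | None = None,
                   species_tag: str = "", seed: int = 0) -> EnsembleModel:
    """Train the SVM/RF/GB trio on the selected feature columns.

    ``selected_features`` defaults to every column of ``features``.  All
    three models are fit on identical columns; the SVM additionally sees
    standardized values (train-set mean/sd, stored inside the model).
    Deterministic given the seed.
    """
    config = config or BaseModelConfig()
    y = np.asarray(labels).astype(int)
    if len(y) != len(features):
        raise ValueError("features and labels differ in length")
    if len(y) < 10:
        raise ValueError(f"need at least 10 training samples, got {len(y)}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.max() / counts.min() > 4:
        warnings.warn(
            f"class imbalance {counts.max()}:{counts.min()} exceeds 4:1; "
            "the voting ensemble assumes roughly balanced classes",
            stacklevel=2,
        )
    if selected_features is None:
        selected_features = tuple(features.columns)
    missing = [f for f in selected_features if f not in features.columns]
    if missing:
        raise ValueError(f"selected features absent from matrix: {missing}")
    X = features.loc[:, list(selected_features)].to_numpy(dtype=float)

    scaler = None
    X_svm = X
    if config.standardize_for_svm:
        scaler = StandardScaler().fit(X)
        X_svm = scaler.transform(X)
    svm = SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma)
    svm.fit(X_svm, y)
    rf = RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_features=min(config.rf_vars_per_split, X.shape[1]),
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y)
    gb = GradientBoostingClassifier(
        n_estimators=config.gb_n_trees, max_depth=config.gb_depth,
        learning_rate=config.gb_shrinkage, subsample=config.gb_subsample,
        random_state=seed + 1,
    )
    gb.fit(X, y)

    metadata = {
        "species_tag": species_tag,
        "n_pos": int(counts[classes == 1][0]) if 1 in classes else 0,
        "n_neg": int(counts[classes == 0][0]) if 0 in classes else 0,
        "seed": seed,
        "config_hash": config.hash(),
        "n_features": len(selected_features),
        # the reference server does not state whether SVM inputs are scaled;
        # this implementation's choice is recorded here explicitly
        "svm_standardized": config.standardize_for_svm,
    }
    return EnsembleModel(svm, rf, gb, scaler, tuple(selected_features),
                         species_tag, config, metadata)


def predict_features(model: EnsembleModel, features: pd.DataFrame,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vote matrix (n, 3), mean-vote scores and binary calls for a matrix."""
    missing = [f for f in model.selected_features if f not in features.columns]
    if missing:
        raise ValueError(
            f"feature matrix incompatible with model; missing: {missing[:5]}"
        )
    X = features.loc[:, list(model.selected_features)].to_numpy(dtype=float)
    X_svm = model.scaler.transform(X) if model.scaler is not None else X
    votes = np.column_stack([
        model.svm.predict(X_svm),
        model.rf.predict(X),
        model.gb.predict(X),
    ]).astype(int)
    scores = votes.sum(axis=1) / N_MODELS
    calls = votes.sum(axis=1) >= 2
    return votes, scores, calls


def predict(model: EnsembleModel,
            windows: Sequence[SequenceWindow | str]) -> list[PredictionResult]:
    """Encode windows, vote with the three base models, call by majority."""
    if len(windows) == 0:
        return []
    validated = [validate_window(w) for w in windows]
    mat = encode.encode_matrix(validated)
    votes, scores, calls = predict_features(model, mat)
    return [
        PredictionResult(w, tuple(int(v) for v in votes[i]),
                         float(scores[i]), bool(calls[i]))
        for i, w in enumerate(validated)
    ]


def intersect_calls(pred_a: Sequence[PredictionResult],
                    pred_b: Sequence[PredictionResult],
                    ) -> list[PredictionResult]:
    """Dual-model intersection: positive only where both models agree.

    The combined score is the minimum of the two scores (a conservative
    convention; any rule agreeing on the binary calls would do).  Both
    inputs must cover the same windows in the same order.
    """
    key = lambda p: (p.window.accession, p.window.window_index, p.window.start)
    keys_a = [key(p) for p in pred_a]
    keys_b = [key(p) for p in pred_b]
    if keys_a != keys_b:
        diff = set(keys_a) ^ set(keys_b)
        raise ValueError(
            f"prediction window sets differ; symmetric difference: "
            f"{sorted(diff)[:10]}"
        )
    out = []
    for a, b in zip(pred_a, pred_b):
        out.append(PredictionResult(
            window=a.window, votes=None,
            score=min(a.score, b.score),
            call=a.call and b.call,
        ))
    return out
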