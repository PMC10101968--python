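"""Hierarchical two-stage classification of cell feature vectors.

Stage A separates the white-blood-cell background (MC) from tumor cells
(NB ∪ OC); stage B, applied only to cells stage A called tumor, separates
the two tumor types. Stage-A errors therefore propagate: a true MC can
only be output as NB/OC through a stage-A mistake, and the hierarchical
MC recall equals the stage-A MC recall exactly.

For 3D tomogram features each stage is a shallow neural network
(44 → hidden ReLU layer → 1 sigmoid output; 100 hidden nodes for stage A,
10 for stage B). The 2D phase-map baseline uses logistic regression for
stage A and a linear discriminant for stage B. All stages standardize
features with training-set z-scores frozen at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

N_FEATURES = 44
HIDDEN_A = 100
HIDDEN_B = 10

STAGE_KINDS = ("shallow_nn", "logistic", "lda")


def _check_features(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(
            f"expected feature matrix of width {N_FEATURES}, got shape {features.shape}"
        )
    if not np.isfinite(features).all():
        bad = np.argwhere(~np.isfinite(features))
        raise ValueError(f"non-finite features at (row, column): {bad[:5].tolist()}")
    return features


@dataclass
class StageModel:
    """One binary decision stage: a fitted sklearn pipeline + label order.

    ``positive`` is the class mapped to score 1; a score ≥ 0.5 predicts it.
    """

    kind: str
    positive: str
    negative: str
    pipeline: Pipeline
    seed: int

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        features = _check_features(features)
        scores = self.pipeline.predict_proba(features)[:, 1]
        labels = np.where(scores >= 0.5, self.positive, self.negative)
        return labels, scores


def fit_stage(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str,
    positive: str,
    hidden_width: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
) -> StageModel:
    """Fit one binary stage with frozen z-score standardization.

    The shallow network trains with cross-entropy under Adam and stops
    when the training loss plateaus (tolerance 1e-4 over 10 epochs, at
    most ``max_iter`` epochs). Stopping on a held-out validation score
    is deliberately not used: with the small per-stage sample sizes the
    validation accuracy saturates within a few epochs and would freeze
    the network long before the loss has converged.
    """
    features = _check_features(features)
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {sorted(classes)}")
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from labels")
    negative = (classes - {positive}).pop()
    y = (labels == positive).astype(int)

    if kind == "shallow_nn":
        estimator = MLPClassifier(
            hidden_layer_sizes=(hidden_width or HIDDEN_A,),
            activation="relu",
            solver="adam",
            learning_rate_init=0.01,
            max_iter=max_iter,
            n_iter_no_change=10,
            random_state=seed,
        )
    elif kind == "logistic":
        estimator = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "lda":
        estimator = LinearDiscriminantAnalysis()
    else:
        raise ValueError(f"unknown stage kind {kind!r}; expected one of {STAGE_KINDS}")

    pipe = Pipeline([("scale", StandardScaler()), ("model", estimator)])
    pipe.fit(features, y)
    return StageModel(kind, positive, negative, pipe, seed)


def predict_stage(model: StageModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(features)


@dataclass
class HierarchicalModel:
    """Stage A (MC vs tumor) chained into stage B (NB vs OC)."""

    stage_a: StageModel
    stage_b: StageModel
    classes: tuple[str, str, str] = ("MC", "NB", "OC")


@dataclass
class HierarchicalConfig:
    """Model kinds and widths for the two stages."""

    kind_a: str = "shallow_nn"
    kind_b: str = "shallow_nn"
    hidden_a: int = HIDDEN_A
    hidden_b: int = HIDDEN_B
    max_iter: int = 500


def fit_hierarchical(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: HierarchicalConfig | None = None,
    seed: int = 0,
) -> HierarchicalModel:
    """Fit stage A on MC vs (NB ∪ OC) and stage B on NB vs OC only."""
    config = config or HierarchicalConfig()
    features = _check_features(train_features)
    labels = np.asarray(train_labels)
    present = set(labels.tolist())
    missing = {"MC", "NB", "OC"} - present
    if missing:
        raise ValueError(f"training set lacks classes: {sorted(missing)}")

    coarse = np.where(labels == "MC", "MC", "tumor")
    stage_a = fit_stage(
        features,
        coarse,
        config.kind_a,
        positive="tumor",
        hidden_width=config.hidden_a,
        seed=seed,
        max_iter=config.max_iter,
    )
    tumor_rows = labels != "MC"
    stage_b = fit_stage(
        features[tumor_rows],
        labels[tumor_rows],
        config.kind_b,
        positive="OC",
        hidden_width=config.hidden_b,
        seed=seed + 1,
        max_iter=config.max_iter,
    )
    return HierarchicalModel(stage_a, stage_b)


def predict_hierarchical(model: HierarchicalModel, features: np.ndarray) -> np.ndarray:
    """Route every cell through stage A, then tumor-labeled cells through B."""
    features = _check_features(features)
    coarse, _ = model.stage_a.predict(features)
    out = np.array(["MC"] * len(features), dtype=object)
    tumor = coarse == "tumor"
    if tumor.any():
        fine, _ = model.stage_b.predict(features[tumor])
        out[tumor] = fine
    return out.astype(str)
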