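"""Gaussian-kernel SVM over window features.

The classifier follows the original framework's settings: an RBF kernel
with cost C = 2 and kernel width γ = 2⁻⁵, a raw decision threshold of 0
(no cutoff adjustment), and all training samples used without class
reweighting by default.  Model selection, when requested, maximizes the
cross-validated Matthews correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from proterna.features import FeatureMatrix


@dataclass(frozen=True)
class ModelSpec:
    """RBF-SVM hyperparameters; defaults are the tuned values C=2¹, γ=2⁻⁵."""

    C: float = 2.0
    gamma: float = 2.0 ** -5
    class_weighting: float | None = None  # positive-class weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: SVC
    n_samples: int
    class_counts: dict[int, int]
    n_features: int


@dataclass
class PredictionResult:
    """Per-residue decision values and binary calls (score > threshold)."""

    chain_id: str
    scores: np.ndarray
    calls: np.ndarray
    threshold: float = 0.0


def _as_rows(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.rows
    return np.atleast_2d(np.asarray(features, dtype=float))


def train(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    spec: ModelSpec = ModelSpec(),
) -> TrainedModel:
    """Fit the RBF-SVM on window features.

    Deterministic for a fixed (data, spec, seed); raises on single-class
    input, which cannot define a decision boundary.
    """
    X = _as_rows(features)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both positive and negative samples")
    class_weight = {1: spec.class_weighting} if spec.class_weighting else None
    est = SVC(
        kernel="rbf",
        C=spec.C,
        gamma=spec.gamma,
        class_weight=class_weight,
        random_state=spec.seed,
        cache_size=200,
    )
    est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        n_samples=X.shape[0],
        class_counts=dict(zip(classes.tolist(), counts.tolist())),
        n_features=X.shape[1],
    )


def predict(
    model: TrainedModel,
    features: FeatureMatrix | np.ndarray,
    threshold: float = 0.0,
    chain_id: str = "",
) -> PredictionResult:
    """Score residues with the fitted decision function; call binding where
    the decision value exceeds ``threshold``."""
    X = _as_rows(features)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension {model.n_features}"
        )
    scores = model.estimator.decision_function(X)
    calls = (scores > threshold).astype(int)
    if isinstance(features, FeatureMatrix) and not chain_id:
        chain_id = features.chain_id
    return PredictionResult(chain_id=chain_id, scores=scores, calls=calls, threshold=threshold)


def grid_select(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    C_grid: Sequence[float],
    gamma_grid: Sequence[float],
    k: int = 5,
    seed: int = 0,
    chain_ids: Sequence[str] | None = None,
) -> ModelSpec:
    """Pick (C, γ) by k-fold cross-validated MCC.

    With ``chain_ids`` the folds are sequence-aware (whole chains held out
    together); ties favour the smaller C, then the smaller γ.
    """
    from proterna.evaluation import CVConfig, assign_folds, confusion, metrics

    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be nonempty")
    X = _as_rows(features)
    y = np.asarray(labels, dtype=int)

    if chain_ids is not None:
        chain_ids = np.asarray(chain_ids)
        unique_chains = sorted(set(chain_ids.tolist()))
        config = CVConfig(k=k, repeats=1, mode="sequence", seed=seed)
        chain_folds = assign_folds(unique_chains, config)[0]
        fold_of_chain = dict(zip(unique_chains, chain_folds))
        row_folds = np.array([fold_of_chain[c] for c in chain_ids])
    else:
        config = CVConfig(k=k, repeats=1, mode="window", seed=seed)
        row_folds = np.asarray(assign_folds(list(range(X.shape[0])), config)[0])

    best: tuple[float, float, float] | None = None  # (-mcc, C, gamma)
    for C in C_grid:
        for gamma in gamma_grid:
            spec = ModelSpec(C=C, gamma=gamma, seed=seed)
            mccs = []
            for fold in range(k):
                test = row_folds == fold
                if test.all() or not test.any():
                    continue
                ytr = y[~test]
                if len(np.unique(ytr)) < 2:
                    mccs.append(0.0)
                    continue
                model = train(X[~test], ytr, spec)
                calls = predict(model, X[test]).calls
                mccs.append(metrics(confusion(y[test], calls)).mcc)
            mean_mcc = float(np.mean(mccs)) if mccs else 0.0
            key = (-mean_mcc, C, gamma)
            if best is None or key < best:
                best = key
    return ModelSpec(C=best[1], gamma=best[2], seed=seed)


def write_predictions_tsv(result: PredictionResult) -> str:
    lines = ["chain_id\tresidue_index\tscore\tcall"]
    for i, (s, c) in enumerate(zip(result.scores, result.calls)):
        lines.append(f"{result.chain_id}\t{i + 1}\t{s:.6f}\t{c}")
    return "\n".join(lines) + "\n"
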