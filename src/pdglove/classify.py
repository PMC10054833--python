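"""Medication-state classification harness.

Trains the five classical model families — k-nearest neighbors, random
forest, naive Bayes, multilayer perceptron, and support vector machine — on
the glove feature table to predict medication state (0 = pre-intake, 1 =
post-intake), reporting class-support-weighted precision, recall, F1, and
accuracy per model.  Feature importance for the tree model is computed with
a permutation-sampling Shapley-value estimator: for random feature
orderings, the marginal change in the model's class-1 probability when a
feature's value is switched from a background sample to the explained
sample is averaged, and features are ranked by mean absolute attribution.

Rows are (participant, session) feature vectors with the left- and
right-glove features concatenated; identifiers are metadata, never
features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pdglove.features import LABEL_COLUMNS

MODEL_FAMILIES = ("knn", "random_forest", "naive_bayes", "mlp", "svm")

LABEL = "med_state"


def assemble_dataset(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the tidy per-(session, task, hand) table into one row per
    session, concatenating all task and hand feature blocks.

    Feature ids already carry task and hand prefixes, so the collapse takes
    the first non-null value per column within each (participant, session)
    group.  The result has ``participant_id``, ``session_datetime``,
    ``med_state``, then feature columns; combinations never observed stay
    NaN-free only if every session ran every task.
    """
    keys = ["participant_id", "session_datetime"]
    grouped = feature_table.groupby(keys, sort=True).first().reset_index()
    return grouped.drop(columns=[c for c in ("task", "hand") if c in grouped])


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in LABEL_COLUMNS]


def split_dataset(dataset: pd.DataFrame, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, reproducible train/test split on the session dataset.

    Requires both medication states present with at least 5 rows each.
    """
    if LABEL not in dataset:
        raise ValueError(f"dataset lacks the {LABEL!r} column")
    counts = dataset[LABEL].value_counts()
    if set(counts.index) != {0, 1}:
        raise ValueError(f"both medication states required; found {sorted(counts.index)}")
    if counts.min() < 5:
        raise ValueError(f"need >= 5 rows per class, got {counts.to_dict()}")
    train, test = train_test_split(dataset, train_size=train_fraction,
                                   random_state=seed, stratify=dataset[LABEL])
    return train, test


@dataclass
class EvaluationReport:
    """Per-model weighted metrics plus tree-model feature importance."""

    metrics: dict[str, dict[str, float]]
    train_fraction: float
    seed: int
    n_train: int
    n_test: int
    feature_names: list[str]
    importance: dict[str, float] | None = None
    hyperparameters: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "metrics": self.metrics,
            "split": {"train_fraction": self.train_fraction, "seed": self.seed,
                      "n_train": self.n_train, "n_test": self.n_test},
            "importance": self.importance,
            "hyperparameters": self.hyperparameters,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    def to_text(self) -> str:
        lines = [f"{'Model':<24}{'Precision':>10}{'Recall':>10}{'F1-Score':>10}{'Accuracy':>10}"]
        for name, m in self.metrics.items():
            lines.append(f"{name:<24}{m['precision']:>10.2f}{m['recall']:>10.2f}"
                         f"{m['f1']:>10.2f}{m['accuracy']:>10.2f}")
        return "\n".join(lines)


def _make_models(model_set, seed: int) -> dict:
    registry = {
        "knn": lambda: KNeighborsClassifier(),
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "mlp": lambda: MLPClassifier(random_state=seed, max_iter=800),
        "svm": lambda: SVC(random_state=seed),
    }
    if model_set is None:
        model_set = MODEL_FAMILIES
    unknown = set(model_set) - set(registry)
    if unknown:
        raise ValueError(f"unknown model families {sorted(unknown)}")
    return {name: registry[name]() for name in model_set}


def train_and_evaluate(train: pd.DataFrame, test: pd.DataFrame,
                       model_set: tuple[str, ...] | None = None, seed: int = 0,
                       compute_importance: bool = True,
                       ) -> EvaluationReport:
    """Fit the model families and report weighted metrics on the test set.

    Features are standardized with statistics from the training split only.
    When the random forest is in the model set and ``compute_importance`` is
    on, Shapley feature importance is computed on the test set.
    """
    if train[LABEL].nunique() < 2:
        raise ValueError("degenerate single-class training set")
    cols = _feature_columns(train)
    scaler = StandardScaler().fit(train[cols].to_numpy())
    X_train = scaler.transform(train[cols].to_numpy())
    X_test = scaler.transform(test[cols].to_numpy())
    y_train = train[LABEL].to_numpy().astype(int)
    y_test = test[LABEL].to_numpy().astype(int)

    models = _make_models(model_set, seed)
    metrics: dict[str, dict[str, float]] = {}
    hyper: dict[str, dict] = {}
    fitted = {}
    for name, model in models.items():
        model.fit(X_train, y_train)
        pred = model.predict(X_test)
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_test, pred, average="weighted", zero_division=0)
        metrics[name] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "accuracy": float(accuracy_score(y_test, pred)),
        }
        hyper[name] = {k: v for k, v in model.get_params().items()
                       if isinstance(v, (int, float, str, bool, type(None)))}
        fitted[name] = model

    importance = None
    if compute_importance and "random_forest" in fitted:
        scores = feature_importance(fitted["random_forest"],
                                    pd.DataFrame(X_test, columns=cols), seed=seed)
        importance = scores
    return EvaluationReport(metrics=metrics, train_fraction=len(train) / (len(train) + len(test)),
                            seed=seed, n_train=len(train), n_test=len(test),
                            feature_names=cols, importance=importance,
                            hyperparameters=hyper)


def _is_tree_ensemble(model) -> bool:
    return hasattr(model, "estimators_") and hasattr(model, "predict_proba")


def shapley_values(model, X: np.ndarray, background: np.ndarray,
                   n_permutations: int = 20, seed: int = 0) -> np.ndarray:
    """Monte-Carlo Shapley attributions of ``predict_proba[:, 1]``.

    For each sampled feature ordering, features are switched one by one
    from a randomly drawn background row to the explained row; the change
    in the model output at each switch is that feature's marginal
    contribution.  Averaging over orderings estimates the Shapley value.
    Returns an ``(n_samples, n_features)`` array.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, d = X.shape
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        z = background[rng.integers(0, len(background), size=n)]
        current = z.copy()
        prev = model.predict_proba(current)[:, 1]
        for j in order:
            current[:, j] = X[:, j]
            out = model.predict_proba(current)[:, 1]
            phi[:, j] += out - prev
            prev = out
    return phi / n_permutations


def feature_importance(tree_model, test: pd.DataFrame, n_permutations: int = 20,
                       seed: int = 0, max_rows: int = 100) -> dict[str, float]:
    """Shapley feature importance of a fitted tree ensemble on a test set.

    Attributions are aggregated as the mean absolute Shapley value per
    feature and returned in descending order.  Non-tree models are
    rejected.
    """
    if not _is_tree_ensemble(tree_model):
        raise TypeError("feature importance requires a fitted tree-ensemble model")
    cols = _feature_columns(test)
    X = test[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if len(X) > max_rows:
        X = X[rng.choice(len(X), size=max_rows, replace=False)]
    phi = shapley_values(tree_model, X, background=X,
                         n_permutations=n_permutations, seed=seed)
    scores = np.abs(phi).mean(axis=0)
    order = np.argsort(scores)[::-1]
    return {cols[i]: float(scores[i]) for i in order}
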