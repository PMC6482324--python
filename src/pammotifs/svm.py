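"""Supervised secondary-structure baseline.

A one-vs-one Gaussian-kernel support vector machine predicts 8-state
labels from dihedral-window or reduced-descriptor features.  Its
asymptotic accuracy bounds what any classifier can extract from a given
representation, separating representation insufficiency from genuine
mismatch between data-driven motifs and heuristic labels.

Features are standardised (zero mean, unit variance, fitted on the
training split only) and the kernel width is gamma = 1/N_f on the
standardised features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ssbench import SS3_GROUPS

logger = logging.getLogger(__name__)

_CODE_TO_GROUP = {c: g for g, cs in SS3_GROUPS.items() for c in cs}


@dataclass(frozen=True)
class SvmConfig:
    """Training protocol: split sizes, kernel and regularisation."""

    regularization: float = 1.0
    train_size: int = 50_000
    test_size: int = 150_000
    seed: int = 0


@dataclass
class ClassifierReport:
    """Q3/Q8 accuracies plus per-class counts on the test split."""

    q3: float
    q8: float
    per_class: dict[str, dict[str, int]] = field(default_factory=dict)
    n_test: int = 0


def split_data(
    X: np.ndarray, y: np.ndarray, config: SvmConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded disjoint train/test split by uniform sampling.

    When the pool is smaller than train_size + test_size, both sizes
    shrink proportionally (warned); samples are never reused across
    splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    n_train, n_test = config.train_size, config.test_size
    if n < n_train + n_test:
        scale = n / (n_train + n_test)
        n_train = max(int(n_train * scale), 1)
        n_test = min(int(n_test * scale), n - n_train)
        logger.warning(
            "pool of %d smaller than %d+%d; scaled split to %d/%d",
            n,
            config.train_size,
            config.test_size,
            n_train,
            n_test,
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    train_idx = perm[:n_train]
    test_idx = perm[n_train : n_train + n_test]
    return X[train_idx], y[train_idx], X[test_idx], y[test_idx]


def train_classifier(
    X_train: np.ndarray, y_train: np.ndarray, config: SvmConfig = SvmConfig()
) -> Pipeline:
    """Fit the standardiser and the one-vs-one RBF SVM on the train split."""
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    n_features = X_train.shape[1]
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    gamma=1.0 / n_features,
                    C=config.regularization,
                    decision_function_shape="ovo",
                    random_state=config.seed,
                ),
            ),
        ]
    )
    model.fit(X_train, y_train)
    return model


def _to3(labels: np.ndarray) -> np.ndarray:
    return np.array([_CODE_TO_GROUP.get(str(c), str(c)) for c in labels])


def evaluate(model: Pipeline, X_test: np.ndarray, y_test: np.ndarray) -> ClassifierReport:
    """Q8 (8-state accuracy) and Q3 (after strand/helix/coil grouping).

    Labels outside the 8-state alphabet are grouped as themselves, so
    synthetic class names degrade gracefully (then Q3 == Q8).
    """
    X_test = np.asarray(X_test, dtype=float)
    expected = model.named_steps["scale"].mean_.shape[0]
    if X_test.shape[1] != expected:
        raise ValueError(
            f"feature dimension {X_test.shape[1]} != fitted dimension {expected}"
        )
    pred = model.predict(X_test)
    y_test = np.asarray(y_test)
    q8 = float(np.mean(pred == y_test))
    q3 = float(np.mean(_to3(pred) == _to3(y_test)))
    per_class: dict[str, dict[str, int]] = {}
    for code in np.unique(y_test):
        truth = y_test == code
        hit = pred == code
        per_class[str(code)] = {
            "support": int(truth.sum()),
            "true_positive": int((truth & hit).sum()),
            "predicted": int(hit.sum()),
        }
    return ClassifierReport(q3=q3, q8=q8, per_class=per_class, n_test=len(y_test))
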