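"""Weak-train / true-test validation, classifier suite and noise robustness.

The validation routine mirrors the deployment setting: in each of 10 folds
the balanced rows are shuffled, 10% held out, a classifier is fit on the
*weak* labels of the remainder and scored against the *manual* labels of the
held-out rows.  Manual labels are never visible to the fitting step.

The default suite holds seven classifier specifications: nearest centroid,
decision tree, random forest, k-nearest neighbors, multi-class SVM, and two
feed-forward networks with hidden layers (12,) and (36, 12) on the
18-feature input.  Features are standardized with statistics fit on the
training split only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from stepfuse.types import ACTIVITY_PRIORITY, Activity, LabeledRow

CLASS_ORDER: tuple[Activity, ...] = ACTIVITY_PRIORITY


class ConfigurationError(ValueError):
    """Raised for an unknown model family or invalid hyperparameters."""


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameters."""

    family: str
    name: str
    params: dict = field(default_factory=dict)


_FAMILIES = {
    "nearest-centroid",
    "decision-tree",
    "random-forest",
    "k-nearest-neighbors",
    "svm",
    "neural-network",
}


def model_suite(alpha: float = 1.0) -> list[ModelSpec]:
    """The seven-model comparison suite.

    ``alpha`` is the network L2 regularization strength; larger values
    discourage large weights and help under label noise.
    """
    return [
        ModelSpec("nearest-centroid", "Nearest Centroid"),
        ModelSpec("decision-tree", "DT"),
        ModelSpec("random-forest", "Random Forests", {"n_estimators": 100}),
        ModelSpec("k-nearest-neighbors", "kNN", {"n_neighbors": 5}),
        ModelSpec("svm", "Multi-class SVM", {"kernel": "rbf", "C": 1.0}),
        ModelSpec("neural-network", "NN 18x12", {"hidden_layer_sizes": (12,), "alpha": alpha}),
        ModelSpec("neural-network", "NN 18x36x12", {"hidden_layer_sizes": (36, 12), "alpha": alpha}),
    ]


def spec_by_name(name: str, alpha: float = 1.0) -> ModelSpec:
    for spec in model_suite(alpha):
        if spec.name == name or spec.family == name:
            return spec
    raise ConfigurationError(f"unknown model {name!r}")


def build_estimator(spec: ModelSpec, seed: Optional[int] = None) -> Pipeline:
    """Instantiate a standardize-then-classify pipeline for a spec."""
    if spec.family not in _FAMILIES:
        raise ConfigurationError(f"unknown model family {spec.family!r}")
    p = dict(spec.params)
    if spec.family == "nearest-centroid":
        clf = NearestCentroid(**p)
    elif spec.family == "decision-tree":
        clf = DecisionTreeClassifier(random_state=seed, **p)
    elif spec.family == "random-forest":
        clf = RandomForestClassifier(random_state=seed, **p)
    elif spec.family == "k-nearest-neighbors":
        clf = KNeighborsClassifier(**p)
    elif spec.family == "svm":
        clf = SVC(random_state=seed, **p)
    else:
        p.setdefault("hidden_layer_sizes", (36, 12))
        p.setdefault("max_iter", 300)
        p.setdefault("early_stopping", True)
        clf = MLPClassifier(random_state=seed, **p)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def per_class_metrics(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision/recall/f arrays from a counts confusion matrix.

    Rows are true classes, columns predicted.  A class with zero predicted
    (resp. true) count contributes precision (resp. recall) 0.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
        raise ValueError("confusion must be a square non-negative matrix")
    if c.sum() <= 0:
        raise ValueError("confusion matrix has no observations")
    diag = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    prec = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
    rec = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    return prec, rec, f1


def metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """Unweighted macro precision, recall and f-score over all classes."""
    prec, rec, f1 = per_class_metrics(confusion)
    return float(prec.mean()), float(rec.mean()), float(f1.mean())


def row_normalize(confusion: np.ndarray) -> np.ndarray:
    """Confusion matrix with each true-class row summing to 1 (0 rows kept 0)."""
    c = np.asarray(confusion, dtype=float)
    row = c.sum(axis=1, keepdims=True)
    return np.divide(c, np.where(row > 0, row, 1.0))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Fold-averaged scores and the pooled row-normalized confusion matrix."""

    model: str
    precision: float
    recall: float
    f_score: float
    fold_scores: list[tuple[float, float, float]]
    confusion: np.ndarray  # row-normalized, CLASS_ORDER x CLASS_ORDER
    classes: tuple[str, ...]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "fold_scores": [list(s) for s in self.fold_scores],
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "seed": self.seed,
            "warnings": self.warnings,
        }


def _as_arrays(rows: Sequence[LabeledRow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.vstack([r.features for r in rows])
    idx = {a: i for i, a in enumerate(CLASS_ORDER)}
    y_weak = np.array([idx[r.weak_label] for r in rows])
    y_true = np.array([idx[r.label] for r in rows])
    return X, y_weak, y_true


def run_cv(
    rows: Sequence[LabeledRow],
    spec: ModelSpec,
    folds: int = 10,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated shuffled holdout: fit on weak labels, score on manual labels."""
    rows = list(rows)
    if any(r.weak_label is None or r.label is None for r in rows):
        raise ValueError("run_cv requires rows with both weak and manual labels")
    if len(rows) < folds * 10:
        raise ValueError(f"need at least {folds * 10} rows, got {len(rows)}")
    X, y_weak, y_true = _as_arrays(rows)
    n = len(rows)
    n_test = max(1, int(round(test_fraction * n)))
    rng = np.random.default_rng(seed)
    k = len(CLASS_ORDER)
    pooled = np.zeros((k, k))
    fold_scores = []
    notes: list[str] = []
    for fold in range(folds):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        present = np.unique(y_weak[train_idx])
        if len(present) < k:
            absent = [CLASS_ORDER[i].value for i in range(k) if i not in present]
            msg = f"fold {fold}: class(es) {absent} absent from training split"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        est = build_estimator(spec, seed=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            # fitting sees features and weak labels only; y_true is never passed
            est.fit(X[train_idx], y_weak[train_idx])
        pred = est.predict(X[test_idx])
        fold_conf = np.zeros((k, k))
        np.add.at(fold_conf, (y_true[test_idx], pred), 1)
        pooled += fold_conf
        # fold macro averages cover only classes present in the test split;
        # a small holdout missing a class entirely must not score it as 0
        prec, rec, f1 = per_class_metrics(fold_conf)
        in_test = fold_conf.sum(axis=1) > 0
        fold_scores.append(
            (float(prec[in_test].mean()), float(rec[in_test].mean()), float(f1[in_test].mean()))
        )
    means = np.mean(fold_scores, axis=0)
    return EvaluationReport(
        model=spec.name,
        precision=float(means[0]),
        recall=float(means[1]),
        f_score=float(means[2]),
        fold_scores=fold_scores,
        confusion=row_normalize(pooled),
        classes=tuple(a.value for a in CLASS_ORDER),
        seed=seed,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Label noise
# ---------------------------------------------------------------------------


def inject_label_noise(
    rows: Sequence[LabeledRow],
    rate: float,
    seed: int = 0,
    mode: str = "uniform",
    pair: Optional[tuple[Activity, Activity]] = None,
) -> list[LabeledRow]:
    """Flip the weak labels of exactly ``round(rate * n)`` rows.

    ``uniform`` replaces each selected weak label with a uniformly drawn
    *different* activity; ``pairwise`` flips only between the two activities
    of ``pair`` (rows of other classes are not selected), modeling the
    heuristic's real cycling/transportation confusion.  Manual labels are
    untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rows = list(rows)
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        eligible = np.arange(len(rows))
    elif mode == "pairwise":
        if pair is None:
            raise ValueError("pairwise mode requires a class pair")
        eligible = np.array([i for i, r in enumerate(rows) if r.weak_label in pair], dtype=int)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    n_flip = int(round(rate * len(eligible)))
    chosen = rng.choice(eligible, size=n_flip, replace=False) if n_flip else np.array([], int)
    out = rows
    for i in chosen:
        r = out[i]
        if mode == "uniform":
            others = [a for a in CLASS_ORDER if a is not r.weak_label]
            new = others[rng.integers(len(others))]
        else:
            new = pair[0] if r.weak_label is pair[1] else pair[1]
        out[i] = LabeledRow(r.label, new, r.probability, r.features, r.window_start)
    return out


def noise_experiment(
    rows: Sequence[LabeledRow],
    specs: Sequence[ModelSpec],
    rates: Sequence[float],
    seed: int = 0,
    folds: int = 10,
    mode: str = "uniform",
    pair: Optional[tuple[Activity, Activity]] = None,
) -> list[dict]:
    """Macro f-score and its degradation Δf = f(0) − f(ρ) per model and rate."""
    rates = list(rates)
    if 0.0 not in rates:
        raise ValueError("rates must include 0 as the noise-free reference")
    results = []
    for spec in specs:
        baseline = None
        for rho in rates:
            noisy = inject_label_noise(rows, rho, seed=seed, mode=mode, pair=pair)
            rep = run_cv(noisy, spec, folds=folds, seed=seed)
            if rho == 0.0:
                baseline = rep.f_score
            results.append(
                {
                    "model": spec.name,
                    "rate": rho,
                    "f_score": rep.f_score,
                    "precision": rep.precision,
                    "recall": rep.recall,
                    "delta_f": (baseline - rep.f_score) if baseline is not None else None,
                }
            )
    return results


def report_to_json(reports: Sequence[EvaluationReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
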