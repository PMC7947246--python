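"""Gradient-boosted-tree classifier: cohort splitting, training, attribution-
based feature retention, validation threshold choice, and prediction.

The ensemble is a histogram gradient-boosted tree classifier with RVOT as
the positive class.  Feature retention keeps features with non-zero mean
absolute per-sample attribution; for tree ensembles a feature's exact
Shapley attribution is non-zero exactly when the feature appears in a
split, and attribution magnitudes are computed by path decomposition (each
split contributes the change in the subtree's expected value to its split
feature).  The decision threshold maximizes Youden's J on the validation
ROC, ties resolved toward 0.5.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier

from .errors import (
    BadFeaturesError,
    DegenerateCohortError,
    DegenerateValidationError,
    MissingFeatureError,
    NoInformativeFeaturesError,
)

POSITIVE_CLASS = "RVOT"
NEGATIVE_CLASS = "LVOT"

#: Invented hyperparameter defaults (none are published).
DEFAULT_PARAMS = {
    "max_depth": 4,
    "max_iter": 200,
    "learning_rate": 0.1,
    "early_stopping": True,
    "validation_fraction": 0.15,
    "n_iter_no_change": 20,
}


@dataclass(frozen=True)
class SplitSpec:
    """Training/validation/testing fractions (default 81/9/10)."""

    train: float = 0.81
    validation: float = 0.09
    test: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(self.train + self.validation + self.test, 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass
class ModelBundle:
    """A fitted ensemble plus everything needed to reproduce predictions."""

    ensemble: HistGradientBoostingClassifier
    feature_names: tuple[str, ...]
    retained_features: tuple[str, ...]
    threshold: float = 0.5
    positive_class: str = POSITIVE_CLASS
    seed: int = 0
    training_meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Persist the ensemble (pickle) plus a JSON metadata sidecar."""
        from pathlib import Path

        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self.ensemble, fh)
        sidecar = {
            "feature_names_n": len(self.feature_names),
            "retained_features": list(self.retained_features),
            "threshold": self.threshold,
            "positive_class": self.positive_class,
            "seed": self.seed,
            "training_meta": self.training_meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - {POSITIVE_CLASS, NEGATIVE_CLASS}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    return (labels == POSITIVE_CLASS).astype(int)


def split_cohort(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random proportional allocation into train/validation/test index sets.

    Sizes follow largest-remainder rounding of the fractions (420 records at
    81/9/10 gives 340/38/42); the partition is disjoint, exhaustive and
    reproducible from the seed.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 records")
    if len(set(labels.tolist())) < 2:
        raise DegenerateCohortError("both classes must be present")
    fracs = np.array([spec.train, spec.validation, spec.test])
    sizes = np.floor(fracs * n).astype(int)
    remainders = fracs * n - sizes
    for i in np.argsort(-remainders)[: n - sizes.sum()]:
        sizes[i] += 1
    order = np.random.default_rng(spec.seed).permutation(n)
    a, b = sizes[0], sizes[0] + sizes[1]
    return order[:a], order[a:b], order[b:]


def train(features: np.ndarray, labels, feature_names,
          params: dict | None = None, seed: int = 0) -> ModelBundle:
    """Fit the boosted-tree ensemble; deterministic given the seed."""
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise BadFeaturesError("feature matrix contains NaN/inf")
    y = _encode(labels)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise DegenerateCohortError("need >= 2 records per class")
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length mismatch")
    hp = dict(DEFAULT_PARAMS, **(params or {}))
    clf = HistGradientBoostingClassifier(random_state=seed, **hp)
    clf.fit(X, y)
    meta = {"hyperparameters": {k: (v if not isinstance(v, float) else float(v))
                                for k, v in hp.items()},
            "n_train": int(X.shape[0]),
            "n_features": int(X.shape[1]),
            "class_counts": {POSITIVE_CLASS: int(y.sum()),
                             NEGATIVE_CLASS: int((1 - y).sum())}}
    return ModelBundle(ensemble=clf, feature_names=tuple(feature_names),
                       retained_features=tuple(feature_names), seed=seed,
                       training_meta=meta)


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def _tree_attributions(predictor_nodes: np.ndarray, X: np.ndarray,
                       attr: np.ndarray) -> None:
    """Accumulate per-sample path attributions of one tree into ``attr``.

    Internal expected values are count-weighted means of the leaves below;
    each split adds (E[child] - E[node]) to its feature's attribution.
    """
    nodes = predictor_nodes
    n_nodes = nodes.shape[0]
    expect = np.zeros(n_nodes)

    def fill(i: int) -> tuple[float, float]:
        if nodes["is_leaf"][i]:
            expect[i] = nodes["value"][i]
            return expect[i], float(nodes["count"][i])
        vl, cl = fill(nodes["left"][i])
        vr, cr = fill(nodes["right"][i])
        tot = cl + cr
        expect[i] = (vl * cl + vr * cr) / tot if tot else 0.0
        return expect[i], tot

    fill(0)
    for row in range(X.shape[0]):
        i = 0
        while not nodes["is_leaf"][i]:
            f = int(nodes["feature_idx"][i])
            x = X[row, f]
            go_left = (x <= nodes["num_threshold"][i]) if np.isfinite(x) else bool(
                nodes["missing_go_to_left"][i])
            child = int(nodes["left"][i] if go_left else nodes["right"][i])
            attr[row, f] += expect[child] - expect[i]
            i = child


def feature_attributions(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature path attributions of the raw decision score."""
    X = np.asarray(features, dtype=float)
    attr = np.zeros_like(X)
    for predictors in bundle.ensemble._predictors:
        for p in predictors:
            _tree_attributions(p.nodes, X, attr)
    return attr


ATTRIBUTION_FLOOR = 1e-12


def select_features_by_shap(bundle: ModelBundle, features: np.ndarray, labels,
                            top_k: int = 20) -> tuple[ModelBundle, "object"]:
    """Retain features with non-zero mean |attribution|; refit on them.

    Returns the refitted bundle and a top-k attribution report
    (:class:`pandas.DataFrame` of feature name and mean |attribution|).
    """
    import pandas as pd

    X = np.asarray(features, dtype=float)
    mean_abs = np.abs(feature_attributions(bundle, X)).mean(axis=0)
    keep = np.flatnonzero(mean_abs > ATTRIBUTION_FLOOR)
    if keep.size == 0:
        raise NoInformativeFeaturesError("all attributions are zero")
    retained = tuple(bundle.feature_names[i] for i in keep)
    refit = train(X[:, keep], labels, retained,
                  params=bundle.training_meta.get("hyperparameters"),
                  seed=bundle.seed)
    refit.retained_features = retained
    refit.training_meta["selected_from"] = len(bundle.feature_names)
    order = np.argsort(-mean_abs[keep])[:top_k]
    report = pd.DataFrame({
        "feature": [retained[i] for i in order],
        "mean_abs_attribution": mean_abs[keep][order],
    })
    return refit, report


def _project(bundle: ModelBundle, features: np.ndarray, feature_names) -> np.ndarray:
    """Column-select ``retained_features`` from a name-keyed feature matrix."""
    X = np.asarray(features, dtype=float)
    if tuple(feature_names) == bundle.retained_features:
        return X
    pos = {n: i for i, n in enumerate(feature_names)}
    try:
        cols = [pos[n] for n in bundle.retained_features]
    except KeyError as e:
        raise MissingFeatureError(f"feature {e.args[0]!r} missing") from None
    return X[:, cols]


def predict(bundle: ModelBundle, features: np.ndarray,
            feature_names=None) -> tuple[np.ndarray, np.ndarray]:
    """Scores in [0, 1] and class labels (RVOT iff score >= threshold)."""
    names = bundle.retained_features if feature_names is None else feature_names
    X = _project(bundle, features, names)
    scores = bundle.ensemble.predict_proba(X)[:, 1]
    labels = np.where(scores >= bundle.threshold, POSITIVE_CLASS, NEGATIVE_CLASS)
    return labels, scores


def choose_threshold(bundle: ModelBundle, features: np.ndarray, labels,
                     feature_names=None) -> ModelBundle:
    """Set the score cutoff to the Youden-J maximizer on the validation ROC.

    Candidate cutoffs are the distinct observed scores; among ties the
    cutoff nearest 0.5 wins.  If no cutoff improves on J = 0 (all scores
    identical), 0.5 is kept with a warning.
    """
    y = _encode(labels)
    if y.min() == y.max():
        raise DegenerateValidationError("validation set has a single class")
    _, scores = predict(bundle, features, feature_names)
    cands = np.unique(scores)
    if cands.size == 1:
        warnings.warn("validation scores are constant; keeping threshold 0.5")
        bundle.threshold = 0.5
        return bundle
    n_pos, n_neg = y.sum(), (1 - y).sum()
    best_j, best_t = -np.inf, 0.5
    for t in cands:
        pred = scores >= t
        j = (pred & (y == 1)).sum() / n_pos + (~pred & (y == 0)).sum() / n_neg - 1
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12
                                  and abs(t - 0.5) < abs(best_t - 0.5)):
            best_j, best_t = j, t
    bundle.threshold = float(np.clip(best_t, 1e-9, 1 - 1e-9))
    return bundle
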