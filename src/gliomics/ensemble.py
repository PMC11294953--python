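"""Two-stage balanced training framework and a SMOTE comparator.

Stage 1 draws multiple balanced subsets from an imbalanced cohort: each
subset keeps *all* minority-class samples and pairs them with an equal-sized
uniform draw (without replacement) of majority-class samples, giving an
exact 1:1 class ratio. One classifier (random forest or XGBoost) is fitted
per subset. Stage 2 forms the ensemble prediction as the arithmetic mean of
the members' mutated-class probabilities.

The SMOTE comparator instead oversamples the minority class by interpolating
between nearest minority neighbors until the classes balance, then fits a
single classifier; it exists to compare the two balancing strategies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

CLASSIFIER_KINDS = ("random_forest", "xgboost")


@dataclass
class BalancedSubset:
    indices: np.ndarray
    n_minority: int
    n_majority_drawn: int
    seed: int


@dataclass
class EnsembleModel:
    members: list
    classifier_kind: str
    feature_names: list
    n_subsets: int
    decision_threshold: float = 0.5
    seeds: list = field(default_factory=list)


def make_balanced_subsets(y, n_subsets: int, seed: int = 0) -> list[BalancedSubset]:
    """Balanced 1:1 subsets: all minority samples + a majority undersample."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("both classes must have at least 2 samples")
    minority_label = int(np.argmin(counts))
    if counts[1] > counts[0]:
        warnings.warn(
            "mutated class (1) outnumbers wild type (0); balancing roles "
            "swapped — the framework is symmetric in the classes", stacklevel=2)
    minority_idx = np.flatnonzero(y == minority_label)
    majority_idx = np.flatnonzero(y != minority_label)
    rng = np.random.default_rng(seed)
    subsets = []
    for k in range(n_subsets):
        draw = rng.choice(majority_idx, size=minority_idx.size, replace=False)
        idx = np.concatenate([minority_idx, draw])
        rng.shuffle(idx)
        subsets.append(BalancedSubset(
            indices=idx, n_minority=minority_idx.size,
            n_majority_drawn=minority_idx.size, seed=seed,
        ))
    return subsets


def _make_classifier(kind: str, hyperparams: dict, random_state: int):
    hp = dict(hyperparams or {})
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", "sqrt"),
            random_state=random_state,
            n_jobs=1,
        )
    if kind == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 300),
            max_depth=hp.get("max_depth", 4),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=random_state,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown classifier kind {kind!r}; use one of {CLASSIFIER_KINDS}")


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            extra = [c for c in X.columns if c not in feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature columns mismatch; missing={missing[:5]}, extra={extra[:5]}")
            X = X[feature_names]
        return X.to_numpy(dtype=np.float64), list(X.columns)
    X = np.asarray(X, dtype=np.float64)
    if feature_names is not None and X.shape[1] != len(feature_names):
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {len(feature_names)}")
    return X, feature_names


def train_ensemble(X, y, feature_names=None, classifier_kind: str = "random_forest",
                   n_subsets: int = 20, hyperparams: dict | None = None,
                   seed: int = 0, decision_threshold: float = 0.5) -> EnsembleModel:
    """Fit one classifier per balanced subset; the ensemble is their mean."""
    if isinstance(X, pd.DataFrame) and feature_names is None:
        feature_names = list(X.columns)
    Xm, feature_names = _as_matrix(X, feature_names)
    if feature_names is None:
        feature_names = [f"f{j:04d}" for j in range(Xm.shape[1])]
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values")
    y = np.asarray(y).astype(int)
    subsets = make_balanced_subsets(y, n_subsets, seed)
    rng = np.random.default_rng(seed)
    members, seeds, dropped = [], [], 0
    for sub in subsets:
        rs = int(rng.integers(2**31 - 1))
        Xs, ys = Xm[sub.indices], y[sub.indices]
        if np.unique(ys).size < 2 or (Xs.std(axis=0) == 0).all():
            dropped += 1
            warnings.warn("degenerate balanced subset dropped", stacklevel=2)
            continue
        clf = _make_classifier(classifier_kind, hyperparams, rs)
        clf.fit(Xs, ys)
        members.append(clf)
        seeds.append(rs)
    if dropped and len(members) < n_subsets / 2:
        raise RuntimeError(
            f"{dropped} of {n_subsets} subset models were degenerate; "
            "refusing to build a crippled ensemble")
    return EnsembleModel(
        members=members, classifier_kind=classifier_kind,
        feature_names=list(feature_names), n_subsets=len(members),
        decision_threshold=decision_threshold, seeds=seeds,
    )


def predict_proba(model: EnsembleModel, X) -> np.ndarray:
    """Mean mutated-class probability over ensemble members."""
    Xm, _ = _as_matrix(X, model.feature_names)
    probs = np.zeros(Xm.shape[0])
    for clf in model.members:
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        probs += clf.predict_proba(Xm)[:, pos_col]
    return probs / len(model.members)


def predict(model: EnsembleModel, X) -> np.ndarray:
    return (predict_proba(model, X) >= model.decision_threshold).astype(int)


def save_model(model: EnsembleModel, directory) -> None:
    """Serialize the ensemble to a directory (members + JSON metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, clf in enumerate(model.members):
        joblib.dump(clf, directory / f"member_{k:03d}.joblib")
    meta = {
        "classifier_kind": model.classifier_kind,
        "feature_names": model.feature_names,
        "n_subsets": model.n_subsets,
        "decision_threshold": model.decision_threshold,
        "seeds": model.seeds,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    members = [
        joblib.load(p) for p in sorted(directory.glob("member_*.joblib"))
    ]
    return EnsembleModel(members=members, classifier_kind=meta["classifier_kind"],
                         feature_names=meta["feature_names"],
                         n_subsets=meta["n_subsets"],
                         decision_threshold=meta["decision_threshold"],
                         seeds=meta["seeds"])


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    """Oversample the minority class by nearest-neighbor interpolation.

    New samples lie uniformly on segments between a minority sample and one
    of its ``k_neighbors`` nearest minority neighbors, generated until the
    class counts are equal. Already balanced data is returned unchanged.
    """
    Xm = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    minority_label = int(np.argmin(counts))
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return Xm.copy(), y.copy()
    minority = Xm[y == minority_label]
    if k_neighbors >= minority.shape[0]:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the minority "
            f"count {minority.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(minority)
    neighbors = nn.kneighbors(minority, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, minority.shape[0], size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    gap = rng.random(n_needed)[:, None]
    partners = minority[neighbors[base, pick]]
    synthetic = minority[base] + gap * (partners - minority[base])
    X_out = np.vstack([Xm, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority_label)])
    return X_out, y_out
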