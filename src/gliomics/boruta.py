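"""Boruta all-relevant feature selection with multi-subset aggregation.

Boruta compares each feature's tree-ensemble importance against "shadow"
features — column-wise permuted copies of the real features. In every
iteration a feature scores a *hit* when its importance exceeds the best
shadow importance; accumulated hits are tested against Binomial(n, 1/2)
(one-sided each way at alpha/2, Bonferroni-corrected across features) to
confirm or reject. Undecided features at the iteration cap stay tentative.

For imbalanced cohorts Boruta runs on several balanced subsets of the
training data; features are aggregated by confirmation frequency, and the
relevant set is those confirmed in at least a threshold fraction of subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .cohort import LABEL_COLUMN


@dataclass
class BorutaDecision:
    """Per-feature outcome of one Boruta run."""

    feature_names: list
    status: dict  # name -> "confirmed" | "rejected" | "tentative"
    hits: dict  # name -> hit count
    n_iterations: int
    alpha: float

    @property
    def confirmed(self) -> list:
        return [f for f in self.feature_names if self.status[f] == "confirmed"]

    @property
    def rejected(self) -> list:
        return [f for f in self.feature_names if self.status[f] == "rejected"]

    @property
    def tentative(self) -> list:
        return [f for f in self.feature_names if self.status[f] == "tentative"]


@dataclass
class SelectionFrequency:
    """Confirmation counts of features across balanced subsets."""

    counts: dict  # name -> number of subsets confirming the feature
    n_subsets: int
    threshold_fraction: float
    fallback_k: int = 10
    hit_totals: dict = field(default_factory=dict)  # name -> summed Boruta hits
    relevant: list = field(default_factory=list)

    def __post_init__(self):
        if not self.relevant:
            self.relevant = self._threshold_set()

    def _threshold_set(self) -> list:
        sel = [f for f, c in self.counts.items()
               if c / self.n_subsets >= self.threshold_fraction]
        if not sel:
            warnings.warn(
                f"no feature reaches the {self.threshold_fraction:.0%} "
                f"confirmation threshold; falling back to the top "
                f"{self.fallback_k} by confirmation frequency and hit count",
                stacklevel=3)
            ranked = sorted(
                self.counts,
                key=lambda f: (-self.counts[f], -self.hit_totals.get(f, 0), f),
            )
            sel = ranked[: self.fallback_k]
        return sel

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_subsets": self.n_subsets,
            "threshold_fraction": self.threshold_fraction,
            "relevant": list(self.relevant),
        }


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), list(X.columns)
    X = np.asarray(X, dtype=np.float64)
    return X, [f"f{j:04d}" for j in range(X.shape[1])]


def boruta(X, y, alpha: float = 0.05, max_iter: int = 100, seed: int = 0,
           n_estimators: int = 100) -> BorutaDecision:
    """One Boruta run on (X, y) with a random-forest importance estimator.

    Rejected features are removed from later iterations; confirmed features
    remain in the design so shadows stay representative. Constant columns
    are rejected up front (their importance is structurally zero).
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y).astype(int)
    n, p = Xm.shape
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")

    rng = np.random.default_rng(seed)
    status = np.zeros(p, dtype=np.int8)  # 0 tentative, 1 confirmed, -1 rejected
    hits = np.zeros(p, dtype=np.int64)

    constant = Xm.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) rejected "
            "before the first iteration", stacklevel=2)
        status[constant] = -1

    # one-sided tests at alpha/2 each, Bonferroni across all p features
    level = (alpha / 2.0) / p
    it = 0
    for it in range(1, max_iter + 1):
        active = status >= 0
        if not active.any():
            break
        Xa = Xm[:, active]
        shadows = rng.permuted(Xa, axis=0)
        Z = np.hstack([Xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Z, y)
        imp = rf.feature_importances_
        k = Xa.shape[1]
        shadow_max = imp[k:].max()
        hits[np.flatnonzero(active)[imp[:k] > shadow_max]] += 1

        und = status == 0
        if und.any():
            h = hits[und]
            p_up = stats.binom.sf(h - 1, it, 0.5)
            p_down = stats.binom.cdf(h, it, 0.5)
            s = status[und]
            s[p_up < level] = 1
            s[(p_down < level) & (p_up >= level)] = -1
            status[und] = s
        if not (status == 0).any():
            break

    labels = {1: "confirmed", -1: "rejected", 0: "tentative"}
    return BorutaDecision(
        feature_names=names,
        status={f: labels[int(s)] for f, s in zip(names, status)},
        hits={f: int(h) for f, h in zip(names, hits)},
        n_iterations=it,
        alpha=alpha,
    )


def multi_subset_select(X, y, n_subsets: int = 20, threshold_fraction: float = 0.5,
                        seed: int = 0, alpha: float = 0.05, max_iter: int = 100,
                        n_estimators: int = 100, fallback_k: int = 10) -> SelectionFrequency:
    """Aggregate Boruta confirmations over balanced subsets of (X, y)."""
    from .ensemble import make_balanced_subsets  # local import avoids a cycle

    Xm, names = _as_matrix(X)
    y = np.asarray(y).astype(int)
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    subsets = make_balanced_subsets(y, n_subsets, seed)
    counts = {f: 0 for f in names}
    hit_totals = {f: 0 for f in names}
    rng = np.random.default_rng(seed)
    for sub in subsets:
        idx = sub.indices
        dec = boruta(
            pd.DataFrame(Xm[idx], columns=names), y[idx],
            alpha=alpha, max_iter=max_iter,
            seed=int(rng.integers(2**31 - 1)), n_estimators=n_estimators,
        )
        for f in dec.confirmed:
            counts[f] += 1
        for f, h in dec.hits.items():
            hit_totals[f] += h
    return SelectionFrequency(counts=counts, n_subsets=n_subsets,
                              threshold_fraction=threshold_fraction,
                              fallback_k=fallback_k, hit_totals=hit_totals)


def select_for_roi_sets(table: pd.DataFrame, rois=("WT", "NONENH"), **kwargs) -> dict:
    """Run multi-subset selection per ROI feature block and on their union.

    Returns a dict keyed ``"WT"``, ``"NONENH"`` and ``"combined"`` (the
    latter only when both ROIs are requested and present).
    """
    from .cohort import split_features_labels

    X, y = split_features_labels(table)
    prefix = {"WT": "ROI1_", "NONENH": "ROI2_"}
    blocks = {}
    for roi in rois:
        cols = [c for c in X.columns if c.startswith(prefix[roi])]
        if not cols:
            raise ValueError(f"table has no feature columns for ROI {roi}")
        blocks[roi] = cols
    results = {}
    for roi, cols in blocks.items():
        results[roi] = multi_subset_select(X[cols], y, **kwargs)
    if len(blocks) == 2:
        combined = blocks["WT"] + blocks["NONENH"]
        results["combined"] = multi_subset_select(X[combined], y, **kwargs)
    return results
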