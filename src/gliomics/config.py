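"""Run configuration: every tunable of the pipeline in one serializable record.

A run's artifacts (feature tables, selection results, model bundles,
evaluation reports) embed ``RunConfig.config_hash()`` so that any number can
be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults.

    Attributes
    ----------
    bin_width
        Fixed bin width (intensity units) for gray-level discretization.
    wavelet
        Wavelet family for the slice-wise subband decomposition.
    log_sigmas_mm
        Laplacian-of-Gaussian scales in millimetres.
    boruta_alpha
        Significance level of the binomial hit test (Bonferroni-corrected
        across features).
    boruta_max_iter
        Iteration cap for a single Boruta run.
    boruta_n_estimators
        Trees in the random-forest importance estimator inside Boruta.
    n_subsets_select
        Number of balanced subsets over which Boruta confirmations are
        aggregated.
    selection_threshold
        Minimum confirmation fraction for a feature to enter the relevant set.
    selection_fallback_k
        Top-k fallback when the thresholded relevant set is empty.
    n_subsets_train
        Number of balanced subsets (= ensemble members) for training.
    classifier
        ``"random_forest"`` or ``"xgboost"``.
    rf_n_estimators, rf_max_features
        Random-forest size and per-split feature fraction.
    xgb_n_estimators, xgb_max_depth, xgb_learning_rate
        Gradient-boosting rounds, tree depth and shrinkage.
    decision_threshold
        Probability cutoff for hard class metrics.
    seed
        Master seed; all stage seeds are derived from it.
    """

    bin_width: float = 25.0
    wavelet: str = "coif1"
    log_sigmas_mm: tuple = (2.0, 3.0, 4.0, 5.0)
    normalize_intensity: bool = False
    boruta_alpha: float = 0.05
    boruta_max_iter: int = 100
    boruta_n_estimators: int = 100
    n_subsets_select: int = 20
    selection_threshold: float = 0.5
    selection_fallback_k: int = 10
    n_subsets_train: int = 20
    classifier: str = "random_forest"
    rf_n_estimators: int = 500
    rf_max_features: str = "sqrt"
    xgb_n_estimators: int = 300
    xgb_max_depth: int = 4
    xgb_learning_rate: float = 0.1
    decision_threshold: float = 0.5
    seed: int = 0
    # degenerate-statistic conventions, serialized with every run
    conventions: dict = field(
        default_factory=lambda: {
            "constant_roi_correlation": 1.0,
            "constant_roi_entropy": 0.0,
            "constant_roi_skewness": 0.0,
            "constant_roi_kurtosis": 0.0,
            "log_boundary": "mirror",
        }
    )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["log_sigmas_mm"] = list(self.log_sigmas_mm)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "log_sigmas_mm" in d:
            d = {**d, "log_sigmas_mm": tuple(d["log_sigmas_mm"])}
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=2, sort_keys=True))

    def derive_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)
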