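"""Random-forest motion/no-motion classifier.

An ensemble of CART decision trees, each grown on a bootstrap sample of the
per-second feature vectors with a random feature subset considered at each
split; the ensemble's motion probability is the average of the per-tree
class-1 probabilities.  Tree growing is delegated to
:class:`sklearn.ensemble.RandomForestClassifier` (Gini impurity, standard
CART practice); this module pins the ensemble mechanics, seeding, feature
ordering validation and model persistence.

Hyperparameters (tree count, feature-subset size, depth) and the upstream
denoising parameters can be optimized jointly with :func:`grid_search`,
which maximizes the mean sqrt(test ROC-AUC) across held-out clips under the
per-subject leave-one-out protocol - an objective that penalizes both false
positives and false negatives.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .denoise import DenoiseConfig
from .depth_io import LabelSeries, RawClip
from .features import FEATURE_COLUMNS, FeatureConfig

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``max_features`` is the number of features (out of 16) considered at
    each split; ``max_depth=None`` grows trees to purity.
    """

    n_trees: int = 100
    max_features: int = 4
    max_depth: int | None = None
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.max_features <= len(FEATURE_COLUMNS):
            raise ValueError(f"max_features must be in [1, {len(FEATURE_COLUMNS)}]")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class ProbabilitySignal:
    """Per-second ensemble motion probability, optionally with a threshold."""

    probs: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1:
            raise ValueError("probability signal must be 1-D")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.threshold is not None and not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.probs.size)


@dataclass
class MotionForest:
    """A fitted forest plus the provenance needed to apply it safely."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    forest_config: ForestConfig
    feature_config: FeatureConfig | None = None
    denoise_config: DenoiseConfig | None = None
    training_threshold: float | None = None


def _feature_matrix(features: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    extra = [
        c for c in features.columns if c not in names and c != "second_index"
    ]
    if missing:
        raise ValueError(
            f"feature table is missing columns {missing}"
            + (f"; unexpected columns {extra}" if extra else "")
        )
    return features.loc[:, list(names)].to_numpy(dtype=np.float64)


def fit_forest(
    features: pd.DataFrame,
    labels: LabelSeries | np.ndarray,
    cfg: ForestConfig = ForestConfig(),
    feature_config: FeatureConfig | None = None,
    denoise_config: DenoiseConfig | None = None,
) -> MotionForest:
    """Train the forest on a feature table and per-second labels.

    Deterministic given ``cfg.seed``.  Raises if the training labels
    contain a single class (no decision boundary can be learned).
    """
    y = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels)
    names = tuple(c for c in FEATURE_COLUMNS if c in features.columns)
    if len(names) != len(FEATURE_COLUMNS):
        # fall back to "every non-index column", preserving table order
        names = tuple(c for c in features.columns if c != "second_index")
    X = _feature_matrix(features, names)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "both motion and no-motion seconds are required"
        )
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
        criterion="gini",
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return MotionForest(
        estimator=est,
        feature_names=names,
        forest_config=cfg,
        feature_config=feature_config,
        denoise_config=denoise_config,
    )


def predict_proba(model: MotionForest, features: pd.DataFrame) -> ProbabilitySignal:
    """Per-second motion probability: mean over trees of P(class 1).

    The feature table must carry exactly the columns seen in training
    (order is restored from the stored names); a mismatch is an error
    naming the offending columns.
    """
    X = _feature_matrix(features, model.feature_names)
    idx = list(model.estimator.classes_).index(1)
    probs = model.estimator.predict_proba(X)[:, idx]
    return ProbabilitySignal(probs, threshold=model.training_threshold)


def classify_motion(signal: ProbabilitySignal, threshold: float) -> LabelSeries:
    """Flag motion where probability is *strictly* greater than threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return LabelSeries((signal.probs > threshold).astype(np.int64))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(path: str | Path, model: MotionForest) -> Path:
    """Persist the model with configs, feature ordering and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "feature_names": list(model.feature_names),
        "forest_config": asdict(model.forest_config),
        "feature_config": (
            asdict(model.feature_config) if model.feature_config else None
        ),
        "denoise_config": (
            asdict(model.denoise_config) if model.denoise_config else None
        ),
        "training_threshold": model.training_threshold,
    }
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path) -> MotionForest:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")

    def _cfg(cls, d):
        if d is None:
            return None
        for key in ("pct_range_mm", "median_kernels", "area_thresholds_mm",
                    "sum_thresholds_mm"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    return MotionForest(
        estimator=payload["estimator"],
        feature_names=tuple(payload["feature_names"]),
        forest_config=_cfg(ForestConfig, payload["forest_config"]),
        feature_config=_cfg(FeatureConfig, payload["feature_config"]),
        denoise_config=_cfg(DenoiseConfig, payload["denoise_config"]),
        training_threshold=payload.get("training_threshold"),
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def _depth_key(cfg: ForestConfig) -> float:
    return float("inf") if cfg.max_depth is None else float(cfg.max_depth)


def grid_search(
    clips: Sequence[RawClip | Callable[[], RawClip]],
    forest_grid: Iterable[ForestConfig],
    denoise_grid: Iterable[DenoiseConfig],
    feature_cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
) -> tuple[ForestConfig, DenoiseConfig, pd.DataFrame]:
    """Jointly optimize forest and denoising parameters.

    For every (forest, denoise) combination the clips are re-denoised,
    features re-extracted, and the per-subject leave-one-out protocol run;
    the objective is the mean over held-out clips of sqrt(test ROC-AUC).
    Clips whose truth labels are single-class are excluded (logged).  Ties
    are broken toward the smaller model: fewer trees, then shallower depth.

    ``clips`` may contain :class:`RawClip` objects or zero-argument
    callables returning one (so large clips can be loaded lazily from disk
    once per denoise setting).

    Returns ``(best_forest, best_denoise, scores)`` where ``scores`` has
    one row per combination.
    """
    from .evaluation import loocv
    from .pipeline import build_dataset

    forest_grid = list(forest_grid)
    denoise_grid = list(denoise_grid)
    if not forest_grid or not denoise_grid:
        raise ValueError("grid must contain at least one configuration")

    rows = []
    best: tuple | None = None
    for di, dcfg in enumerate(denoise_grid):
        dataset = build_dataset(clips, dcfg, feature_cfg)
        usable = []
        for lc in dataset:
            if np.unique(lc.labels.labels).size < 2:
                logger.warning(
                    "grid search: clip %s has single-class labels; excluded",
                    lc.clip_id,
                )
                continue
            usable.append(lc)
        for fi, fcfg in enumerate(forest_grid):
            report = loocv(usable, fcfg, seed=seed)
            aucs = report.per_clip["auc"].dropna().to_numpy()
            score = float(np.sqrt(aucs).mean()) if aucs.size else float("nan")
            rows.append(
                {
                    "denoise_index": di,
                    "forest_index": fi,
                    "n_trees": fcfg.n_trees,
                    "max_features": fcfg.max_features,
                    "max_depth": fcfg.max_depth,
                    "upper_pct": dcfg.upper_pct,
                    "lower_pct": dcfg.lower_pct,
                    "max_diff_mm": dcfg.max_diff_mm,
                    "min_region_px": dcfg.min_region_px,
                    "mean_sqrt_auc": score,
                }
            )
            key = (-score, fcfg.n_trees, _depth_key(fcfg))
            if np.isfinite(score) and (best is None or key < best[0]):
                best = (key, fcfg, dcfg)
    if best is None:
        raise ValueError("no grid combination produced a finite objective")
    scores = pd.DataFrame(rows)
    return best[1], best[2], scores


def forest_grid_from_lists(
    n_trees: Sequence[int] = (50, 100, 200),
    max_depth: Sequence[int | None] = (4, 8, None),
    max_features: Sequence[int] = (2, 4, 8),
    seed: int = 0,
) -> list[ForestConfig]:
    """Cartesian hyperparameter lattice used by the CLI grid-search command."""
    return [
        ForestConfig(n_trees=t, max_depth=d, max_features=f, seed=seed)
        for t, d, f in product(n_trees, max_depth, max_features)
    ]


__all__ = [
    "ForestConfig",
    "ProbabilitySignal",
    "MotionForest",
    "fit_forest",
    "predict_proba",
    "classify_motion",
    "save_model",
    "load_model",
    "grid_search",
    "forest_grid_from_lists",
]
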