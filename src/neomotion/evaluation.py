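"""ROC analysis and the per-subject leave-one-out evaluation protocol.

The protocol mirrors a per-neonate cross-validation with threshold
transfer: for each subject, a forest is trained on the pooled per-second
data of all *other* subjects, a training ROC curve is built from the
model's probabilities on that pooled training data, and the operating
threshold maximizing ``(sensitivity + specificity) / 2`` is selected.  The
model and its threshold are then applied unchanged to each of the held-out
subject's positional clips separately, yielding a per-clip test ROC-AUC and
sensitivity/specificity at the transferred threshold.  Summaries are means
and sample (n-1) standard deviations over clips.

ROC construction uses the strict ``probability > threshold`` decision rule
throughout (a second whose probability ties the threshold is classed as no
motion) and trapezoidal integration for the AUC, which equals the
Mann-Whitney pairwise-concordance statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ForestConfig,
    ProbabilitySignal,
    fit_forest,
    predict_proba,
)
from .depth_io import ClipMetadata, LabelSeries

logger = logging.getLogger(__name__)

SUBGROUP_KEYS = ("bed_type", "cover_type", "camera_location", "term_preterm")


@dataclass
class RocResult:
    """A swept ROC curve with its optimal operating point.

    ``thresholds`` ascend and include a ``-inf`` sentinel (everything
    flagged) before the unique probability values; the largest probability
    itself acts as the all-negative end under the strict ``>`` rule.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_index: int

    @property
    def optimal_threshold(self) -> float:
        return float(self.thresholds[self.optimal_index])

    @property
    def optimal_sensitivity(self) -> float:
        return float(self.sensitivity[self.optimal_index])

    @property
    def optimal_specificity(self) -> float:
        return float(self.specificity[self.optimal_index])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def sensitivity_specificity(
    probs: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of the strict ``prob > threshold`` rule."""
    pred = probs > threshold
    pos = labels == 1
    neg = ~pos
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def roc_curve(
    probs: ProbabilitySignal | np.ndarray,
    labels: LabelSeries | np.ndarray,
    clip_id: str | None = None,
) -> RocResult:
    """Sweep thresholds over the unique probabilities and build the ROC.

    Raises on single-class labels (the curve is undefined), naming the
    clip when given.
    """
    p = probs.probs if isinstance(probs, ProbabilitySignal) else np.asarray(probs, float)
    y = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"{p.size} probabilities vs {y.size} labels")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        where = f" (clip {clip_id})" if clip_id else ""
        raise ValueError(
            f"single-class truth labels{where}: {n_pos} positive, {n_neg} negative"
        )
    uniq = np.unique(p)
    thresholds = np.concatenate(([-np.inf], uniq))
    # counts of scores strictly greater than each threshold, per class
    pos_sorted = np.sort(p[y == 1])
    neg_sorted = np.sort(p[y == 0])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="right")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = 1.0 - spec
    # thresholds ascend => fpr descends; integrate in ascending-fpr order
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    balanced = (sens + spec) / 2.0
    optimal_index = int(np.argmax(balanced))  # first max = lowest threshold
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_index=optimal_index,
    )


def optimal_threshold(roc: RocResult) -> float:
    """Threshold maximizing mean(sensitivity, specificity); ties -> lowest."""
    balanced = (roc.sensitivity + roc.specificity) / 2.0
    return float(roc.thresholds[int(np.argmax(balanced))])


# ---------------------------------------------------------------------------
# leave-one-out protocol
# ---------------------------------------------------------------------------


@dataclass
class LabelledClip:
    """One positional test run reduced to its per-second representation."""

    features: pd.DataFrame
    labels: LabelSeries
    metadata: ClipMetadata
    clip_id: str = "clip"

    def __post_init__(self) -> None:
        if len(self.features) != self.labels.n_seconds:
            raise ValueError(
                f"clip {self.clip_id}: {len(self.features)} feature rows vs "
                f"{self.labels.n_seconds} labels"
            )

    @property
    def subject_id(self) -> str:
        return self.metadata.subject_id


@dataclass
class LoocvReport:
    """Per-clip results and pooled summaries of the leave-one-out run.

    ``per_clip`` has one row per positional test run with the test AUC and
    the sensitivity/specificity at that fold's transferred training
    threshold; clips with single-class truth have NaN metrics and
    ``excluded=True``.  ``summary`` holds mean/SD pairs recomputable from
    ``per_clip``; ``fold_thresholds`` maps held-out subject to the training
    threshold of its fold.
    """

    per_clip: pd.DataFrame
    summary: dict[str, float]
    fold_thresholds: dict[str, float]

    @property
    def n_clips(self) -> int:
        return int(len(self.per_clip))


def _fold_seeds(subjects: Sequence[str], seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))
    return {
        s: int(c.generate_state(1)[0] % (2**31))
        for s, c in zip(subjects, children)
    }


def loocv(
    clips: Sequence[LabelledClip],
    forest_cfg: ForestConfig = ForestConfig(),
    seed: int = 0,
) -> LoocvReport:
    """Per-subject leave-one-out cross-validation with threshold transfer.

    One fold per subject: train on everyone else's pooled seconds, pick the
    optimal threshold from the training ROC, then score each held-out clip
    separately.  Deterministic given ``seed`` (per-fold forest seeds are
    derived from it).
    """
    subjects = sorted({c.subject_id for c in clips})
    if len(subjects) < 2:
        raise ValueError(f"leave-one-out needs >= 2 subjects, got {len(subjects)}")
    seeds = _fold_seeds(subjects, seed)
    rows = []
    fold_thresholds: dict[str, float] = {}
    for subject in subjects:
        train = [c for c in clips if c.subject_id != subject]
        test = [c for c in clips if c.subject_id == subject]
        X = pd.concat([c.features for c in train], ignore_index=True)
        y = np.concatenate([c.labels.labels for c in train])
        model = fit_forest(X, y, replace(forest_cfg, seed=seeds[subject]))
        train_roc = roc_curve(predict_proba(model, X), y)
        thr = train_roc.optimal_threshold
        fold_thresholds[subject] = thr
        for clip in test:
            probs = predict_proba(model, clip.features).probs
            labels = clip.labels.labels
            meta = clip.metadata
            base = {
                "clip_id": clip.clip_id,
                "subject_id": subject,
                "bed_type": meta.bed_type,
                "cover_type": meta.cover_type,
                "camera_location": meta.camera_location,
                "distance_mm": meta.distance_mm,
                "gestational_age_weeks": meta.gestational_age_weeks,
                "term_preterm": meta.term,
                "n_seconds": labels.size,
                "threshold": thr,
                "train_sensitivity": train_roc.optimal_sensitivity,
                "train_specificity": train_roc.optimal_specificity,
                "train_auc": train_roc.auc,
            }
            if np.unique(labels).size < 2:
                logger.warning(
                    "clip %s has single-class truth labels; excluded from "
                    "metric summaries",
                    clip.clip_id,
                )
                rows.append(
                    {**base, "auc": np.nan, "sensitivity": np.nan,
                     "specificity": np.nan, "excluded": True}
                )
                continue
            roc = roc_curve(probs, labels, clip_id=clip.clip_id)
            sens, spec = sensitivity_specificity(probs, labels, thr)
            rows.append(
                {**base, "auc": roc.auc, "sensitivity": sens,
                 "specificity": spec, "excluded": False}
            )
    per_clip = pd.DataFrame(rows)
    summary = summarize(per_clip, fold_thresholds)
    return LoocvReport(per_clip=per_clip, summary=summary, fold_thresholds=fold_thresholds)


def summarize(
    per_clip: pd.DataFrame, fold_thresholds: dict[str, float]
) -> dict[str, float]:
    """Mean/sample-SD summaries over non-excluded clips and fold thresholds."""
    ok = per_clip[~per_clip["excluded"]]
    thr = np.array(list(fold_thresholds.values()), dtype=float)

    def _ms(col: str) -> tuple[float, float]:
        v = ok[col].to_numpy(dtype=float)
        if v.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd

    out: dict[str, float] = {}
    for col in ("auc", "sensitivity", "specificity"):
        m, s = _ms(col)
        out[f"mean_{col}"] = m
        out[f"sd_{col}"] = s
    out["mean_threshold"] = float(thr.mean()) if thr.size else float("nan")
    out["sd_threshold"] = (
        float(np.std(thr, ddof=1)) if thr.size > 1 else 0.0
    )
    out["n_clips"] = int(len(per_clip))
    out["n_excluded"] = int(per_clip["excluded"].sum())
    return out


def subgroup_auc(report: LoocvReport, key: str) -> pd.DataFrame:
    """Per-clip AUC rows tagged by a capture-condition grouping.

    ``key`` is one of bed_type, cover_type, camera_location or
    term_preterm; every clip lands in exactly one group (term_preterm may
    be None when gestational age is unknown).
    """
    if key not in SUBGROUP_KEYS:
        raise ValueError(f"unknown subgroup key {key!r}; choose from {SUBGROUP_KEYS}")
    return (
        report.per_clip.loc[
            :, ["clip_id", "subject_id", key, "distance_mm", "auc"]
        ]
        .rename(columns={key: "group"})
        .reset_index(drop=True)
    )


__all__ = [
    "RocResult",
    "roc_curve",
    "optimal_threshold",
    "sensitivity_specificity",
    "LabelledClip",
    "LoocvReport",
    "loocv",
    "summarize",
    "subgroup_auc",
    "SUBGROUP_KEYS",
]
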