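"""The 16 per-second time-variant features fed to the motion classifier.

Each second yields one 16-vector computed from the cleaned depth-difference
frame and the clipped averaged depth frame at the start of the interval.
Four groups:

* **spatial scale** (5): fraction of the frame area whose |diff| exceeds a
  graded threshold (1, 3, 6, 12, 25 mm), normalized by squared distance so
  that the same physical motion scores the same near or far from the
  camera.  Captures motions of different depth change over larger areas.
* **summed difference** (4): total |diff| above a graded threshold
  (1, 5, 15, 40 mm) per valid pixel - the magnitude of motion, sensitive to
  strong motion over small areas.
* **average depth** (4): mean, median, 25th and 75th percentile of the
  valid depths (mm) - lets the classifier normalize difference features
  with respect to distance from the camera.
* **skew set** (3): standard deviation of the depths at or below their 75th
  percentile (robust spread), excess kurtosis of the depths (noise/skew
  indicator, 0 for Gaussian) and the 75th-percentile depth again as a
  how-far-away-is-the-scene proxy.  These help with skewed camera angles
  (head's/foot's end placements) and noisy streams.

The published description names the groups and their intent but not closed
formulas or threshold values; the concrete definitions here are this
package's interpretation, with every parameter exposed in
:class:`FeatureConfig`.  Column order is fixed (see ``FEATURE_COLUMNS``) so
trained models are portable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .denoise import DepthDiffFrame
from .depth_io import DepthFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds (mm) for the graded difference features.

    ``reference_depth_mm`` anchors the inverse-square distance
    normalization of the spatial-scale features: at the reference distance
    the raw area fraction is reported unscaled.
    """

    area_thresholds_mm: tuple[float, ...] = (1.0, 3.0, 6.0, 12.0, 25.0)
    sum_thresholds_mm: tuple[float, ...] = (1.0, 5.0, 15.0, 40.0)
    reference_depth_mm: float = 500.0

    def __post_init__(self) -> None:
        if len(self.area_thresholds_mm) != 5:
            raise ValueError("area_thresholds_mm must list exactly 5 values")
        if len(self.sum_thresholds_mm) != 4:
            raise ValueError("sum_thresholds_mm must list exactly 4 values")
        for name, ts in (
            ("area_thresholds_mm", self.area_thresholds_mm),
            ("sum_thresholds_mm", self.sum_thresholds_mm),
        ):
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{name} must be strictly ascending")
        if self.reference_depth_mm <= 0:
            raise ValueError("reference_depth_mm must be positive")


FEATURE_COLUMNS: tuple[str, ...] = (
    "area_frac_gt_1mm",
    "area_frac_gt_3mm",
    "area_frac_gt_6mm",
    "area_frac_gt_12mm",
    "area_frac_gt_25mm",
    "sum_diff_gt_1mm",
    "sum_diff_gt_5mm",
    "sum_diff_gt_15mm",
    "sum_diff_gt_40mm",
    "depth_mean_mm",
    "depth_median_mm",
    "depth_p25_mm",
    "depth_p75_mm",
    "depth_std_below_p75_mm",
    "depth_kurtosis",
    "scene_distance_p75_mm",
)
N_FEATURES = len(FEATURE_COLUMNS)


def spatial_scale_features(
    diff: DepthDiffFrame, depth: DepthFrame, cfg: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Distance-normalized area fractions above graded |diff| thresholds.

    For threshold ``T``: ``count(valid & |diff| > T) / count(valid depth)``
    times ``(mean valid depth / reference_depth)**2``.  Zero when the depth
    frame has no valid pixels.
    """
    valid_depth = depth.valid_mask
    n_depth = int(valid_depth.sum())
    if n_depth == 0:
        return np.zeros(len(cfg.area_thresholds_mm))
    mean_depth = float(depth.depths[valid_depth].mean())
    scale = (mean_depth / cfg.reference_depth_mm) ** 2
    ad = np.abs(diff.diffs)
    vm = diff.valid_mask
    return np.array(
        [
            scale * int((vm & (ad > t)).sum()) / n_depth
            for t in cfg.area_thresholds_mm
        ]
    )


def summed_diff_features(
    diff: DepthDiffFrame, cfg: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Per-valid-pixel summed |diff| above graded thresholds (mm)."""
    vm = diff.valid_mask
    n = int(vm.sum())
    if n == 0:
        return np.zeros(len(cfg.sum_thresholds_mm))
    ad = np.abs(diff.diffs)
    return np.array(
        [float(ad[vm & (ad > t)].sum()) / n for t in cfg.sum_thresholds_mm]
    )


def average_depth_features(depth: DepthFrame) -> np.ndarray:
    """(mean, median, p25, p75) of the valid depths in mm; zeros if none."""
    vals = depth.valid_depths()
    if vals.size == 0:
        logger.warning("depth frame at t=%.1fs fully invalid; depth summaries set to 0",
                       depth.timestamp)
        return np.zeros(4)
    p25, p50, p75 = np.percentile(vals, [25, 50, 75])
    return np.array([float(vals.mean()), float(p50), float(p25), float(p75)])


def skew_features(depth: DepthFrame) -> np.ndarray:
    """(std of depths <= p75, excess kurtosis, p75) of the valid depths.

    Kurtosis uses the Fisher (excess) convention - 0 for a Gaussian - with
    the population (biased) estimator, and is defined as 0 for fewer than 4
    valid pixels or a zero-variance frame.
    """
    vals = depth.valid_depths()
    if vals.size == 0:
        return np.zeros(3)
    p75 = float(np.percentile(vals, 75))
    below = vals[vals <= p75]
    spread = float(below.std()) if below.size else 0.0
    if vals.size >= 4 and float(vals.var()) > 0:
        kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    else:
        kurt = 0.0
    return np.array([spread, kurt, p75])


def feature_vector(
    diff: DepthDiffFrame, depth: DepthFrame, cfg: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """All 16 features for one second, in ``FEATURE_COLUMNS`` order."""
    return np.concatenate(
        [
            spatial_scale_features(diff, depth, cfg),
            summed_diff_features(diff, cfg),
            average_depth_features(depth),
            skew_features(depth),
        ]
    )


def extract_features(
    diffs: Sequence[DepthDiffFrame],
    depths: Sequence[DepthFrame],
    cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature table for a clip: one row per second.

    ``depths`` are the clipped averaged frames; either one per difference
    (the frame at the start of each interval) or one per span boundary
    (``len(diffs) + 1``, in which case the trailing frame is unused).
    """
    if len(depths) == len(diffs) + 1:
        depths = depths[:-1]
    if len(depths) != len(diffs):
        raise ValueError(
            f"length mismatch: {len(diffs)} diff frames vs {len(depths)} depth frames"
        )
    rows = np.stack(
        [feature_vector(d, z, cfg) for d, z in zip(diffs, depths)]
    ) if diffs else np.empty((0, N_FEATURES))
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.insert(0, "second_index", [d.second_index for d in diffs])
    if not np.isfinite(rows).all():
        raise AssertionError("non-finite feature value produced")
    return df


def write_feature_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("second_index", *FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns {missing}")
    return df


__all__ = [
    "FeatureConfig",
    "FEATURE_COLUMNS",
    "N_FEATURES",
    "spatial_scale_features",
    "summed_diff_features",
    "average_depth_features",
    "skew_features",
    "feature_vector",
    "extract_features",
    "write_feature_table",
    "read_feature_table",
]
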