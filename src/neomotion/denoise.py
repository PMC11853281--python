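"""Temporal averaging and the five-stage noise-removal cascade.

The raw 30 fps depth stream is reduced to one *depth difference* frame per
second, cleaned so that surviving pixels plausibly correspond to neonatal
motion.  Stages, applied in order:

1. temporal median averaging - the stream is divided into 1-s spans and a
   median frame is computed from the 10 frames at the start of every span
   (robust to single-frame speckle and dropouts);
2. percentile clipping - depths above the 87th or below the 3rd percentile
   of the in-range (200-1000 mm) depths are removed, keeping the band of
   depths where the neonate lies;
3. differencing - consecutive averaged, clipped frames one second apart are
   subtracted where both are valid;
4. spatial median filtering - 5x5 then 3x3 masked median filters smooth the
   difference raster and reject isolated speckle;
5. large-difference removal - |diff| > 150 mm is too large to be neonatal
   motion and is discarded;
6. small-region removal - connected regions of active pixels smaller than
   40 px are too small to be genuine motion and are discarded.

All thresholds are configurable through :class:`DenoiseConfig`; the
defaults are the operating point of the published pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .depth_io import DepthFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the denoising cascade.

    Attributes
    ----------
    span_s:
        Length of a temporal span in seconds (1 s: differences are per
        second).
    frames_per_median:
        Number of raw frames medianed at each span boundary.
    lower_pct, upper_pct:
        Percentile clipping bounds (defaults 3rd and 87th).
    pct_range_mm:
        Depth band over which percentiles are computed; depths outside are
        always invalidated.
    median_kernels:
        Spatial median kernel sizes applied in order (default 5 then 3).
    max_diff_mm:
        Absolute depth-difference ceiling (mm); larger changes cannot be
        neonatal motion.
    min_region_px:
        Minimum connected-component area (px) of active difference pixels.
    connectivity:
        4- or 8-connectivity for region labelling.
    """

    span_s: float = 1.0
    frames_per_median: int = 10
    lower_pct: float = 3.0
    upper_pct: float = 87.0
    pct_range_mm: tuple[float, float] = (200.0, 1000.0)
    median_kernels: tuple[int, ...] = (5, 3)
    max_diff_mm: float = 150.0
    min_region_px: int = 40
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.lower_pct < self.upper_pct <= 100:
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if any(k < 1 or k % 2 == 0 for k in self.median_kernels):
            raise ValueError("median kernels must be odd and >= 1")
        if self.max_diff_mm <= 0:
            raise ValueError("max_diff_mm must be positive")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.frames_per_median < 1:
            raise ValueError("frames_per_median must be >= 1")


@dataclass
class DepthDiffFrame:
    """Signed per-pixel depth change (mm) between consecutive averaged frames.

    ``diffs`` is zero wherever ``valid_mask`` is false; a pixel whose diff
    is exactly 0 but whose mask is true is *valid but inactive* (it carries
    no motion evidence but did return a depth in both frames).
    """

    diffs: np.ndarray
    valid_mask: np.ndarray
    second_index: int = 0

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.diffs.shape != self.valid_mask.shape:
            raise ValueError("diffs and valid_mask shapes differ")
        # enforce the "zero outside the mask" storage convention
        self.diffs = np.where(self.valid_mask, self.diffs, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.diffs.shape  # type: ignore[return-value]

    @property
    def active_mask(self) -> np.ndarray:
        """Valid pixels with a nonzero difference (motion evidence)."""
        return self.valid_mask & (self.diffs != 0)

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


# ---------------------------------------------------------------------------
# masked median primitives
# ---------------------------------------------------------------------------


def _masked_median_axis0(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median over axis 0 ignoring invalid entries.

    Returns ``(median, n_valid)``; positions with no valid entry get 0.
    """
    vals = np.where(valid, values, np.inf)
    vals = np.sort(vals, axis=0)
    cnt = valid.sum(axis=0)
    lo_idx = np.maximum(cnt - 1, 0) // 2
    hi_idx = np.maximum(cnt, 1) // 2
    lo = np.take_along_axis(vals, lo_idx[None], axis=0)[0]
    hi = np.take_along_axis(vals, hi_idx[None], axis=0)[0]
    med = 0.5 * (lo + hi)
    med = np.where(cnt > 0, med, 0.0)
    return med, cnt


def _masked_median_filter(values: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """k x k median filter that ignores invalid pixels.

    Valid pixels whose whole window is valid take the plain (fast) median
    filter result; pixels whose window touches an invalid pixel or the
    frame border fall back to an explicit masked median.  Invalid pixels
    are returned unchanged (the caller keeps them masked).
    """
    h, w = values.shape
    r = k // 2
    cnt = ndimage.convolve(
        mask.astype(np.int32), np.ones((k, k), np.int32), mode="constant", cval=0
    )
    out = values.copy()
    full = mask & (cnt == k * k)
    if full.any():
        base = ndimage.median_filter(values, size=k, mode="nearest")
        out[full] = base[full]
    partial = mask & (cnt < k * k)
    if partial.any():
        padded = np.pad(np.where(mask, values, np.inf), r, constant_values=np.inf)
        win = sliding_window_view(padded, (k, k)).reshape(h, w, k * k)
        sub = np.sort(win[partial], axis=1)
        c = cnt[partial]  # >= 1: the centre pixel itself is valid
        rows = np.arange(sub.shape[0])
        med = 0.5 * (sub[rows, (c - 1) // 2] + sub[rows, c // 2])
        out[partial] = med
    return out


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------


def infer_fps(frames: Sequence[DepthFrame]) -> float:
    """Frame rate from the (constant-step) timestamps."""
    if len(frames) < 2:
        raise ValueError("need at least two frames to infer fps")
    step = frames[1].timestamp - frames[0].timestamp
    if step <= 0:
        raise ValueError("timestamps must be strictly increasing")
    return 1.0 / step


def temporal_median(
    frames: Sequence[DepthFrame], cfg: DenoiseConfig = DenoiseConfig()
) -> list[DepthFrame]:
    """Median-average the 10 frames at the start of every 1-s span.

    Returns one averaged frame per span boundary (span starts).  A pixel of
    the averaged frame is invalid when it was invalid in more than half of
    the contributing frames; otherwise it is the median of its valid values.
    """
    fps = infer_fps(frames)
    per_span = int(round(fps * cfg.span_s))
    if per_span < cfg.frames_per_median:
        raise ValueError(
            f"span holds {per_span} frames < frames_per_median={cfg.frames_per_median}"
        )
    n_spans = len(frames) // per_span
    if n_spans < 2:
        raise ValueError(
            f"clip has {n_spans} full span(s); need >= 2 to form a difference"
        )
    out: list[DepthFrame] = []
    m = cfg.frames_per_median
    for t in range(n_spans):
        start = t * per_span
        block = np.stack([f.depths for f in frames[start : start + m]])
        valid = np.stack([f.valid_mask for f in frames[start : start + m]])
        med, cnt = _masked_median_axis0(block, valid)
        ok = (m - cnt) <= m // 2  # invalid in more than half -> invalid
        depths = np.where(ok & (cnt > 0), med, 0.0)
        out.append(
            DepthFrame(
                depths,
                timestamp=t * cfg.span_s,
                valid_range=frames[0].valid_range,
            )
        )
    return out


def clip_depth_percentiles(
    frame: DepthFrame, cfg: DenoiseConfig = DenoiseConfig()
) -> DepthFrame:
    """Invalidate depths outside the [lower_pct, upper_pct] percentile band.

    Percentiles (linear interpolation between order statistics) are taken
    over the valid pixels inside ``pct_range_mm`` only; pixels outside that
    band are always invalidated.  A frame with no in-range pixel is
    returned fully invalid (and logged) so downstream stages can skip it.
    """
    lo_mm, hi_mm = cfg.pct_range_mm
    d = frame.depths
    in_range = frame.valid_mask & (d >= lo_mm) & (d <= hi_mm)
    if not in_range.any():
        logger.warning(
            "frame at t=%.1fs has no depths in range %s mm; fully invalidated",
            frame.timestamp,
            cfg.pct_range_mm,
        )
        return DepthFrame(
            np.zeros_like(d), timestamp=frame.timestamp, valid_range=frame.valid_range
        )
    p_lo, p_hi = np.percentile(d[in_range], [cfg.lower_pct, cfg.upper_pct])
    keep = in_range & (d >= p_lo) & (d <= p_hi)
    return DepthFrame(
        np.where(keep, d, 0.0), timestamp=frame.timestamp, valid_range=frame.valid_range
    )


def depth_difference(
    prev: DepthFrame, curr: DepthFrame, second_index: int = 0
) -> DepthDiffFrame:
    """Subtract consecutive averaged frames: ``curr - prev`` where both valid."""
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    mask = prev.valid_mask & curr.valid_mask
    diffs = np.where(mask, curr.depths - prev.depths, 0.0)
    return DepthDiffFrame(diffs, mask, second_index=second_index)


def spatial_median_filter(
    diff: DepthDiffFrame, cfg: DenoiseConfig = DenoiseConfig()
) -> DepthDiffFrame:
    """Apply the configured median kernels (default 5x5 then 3x3) in order.

    The filters ignore invalid pixels (no zero-filling, which would drag
    medians toward zero at mask borders); the validity mask is unchanged.
    """
    vals = diff.diffs
    for k in cfg.median_kernels:
        vals = _masked_median_filter(vals, diff.valid_mask, k)
    return DepthDiffFrame(vals, diff.valid_mask.copy(), second_index=diff.second_index)


def remove_large_differences(
    diff: DepthDiffFrame, cfg: DenoiseConfig = DenoiseConfig()
) -> DepthDiffFrame:
    """Invalidate |diff| > max_diff_mm - too large to be neonatal motion."""
    keep = diff.valid_mask & (np.abs(diff.diffs) <= cfg.max_diff_mm)
    return DepthDiffFrame(
        np.where(keep, diff.diffs, 0.0), keep, second_index=diff.second_index
    )


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def remove_small_regions(
    diff: DepthDiffFrame, cfg: DenoiseConfig = DenoiseConfig()
) -> DepthDiffFrame:
    """Invalidate connected active regions smaller than min_region_px.

    Regions are connected components (4- or 8-connectivity) of pixels that
    are valid *and* nonzero; exact-zero valid pixels carry no motion
    evidence and neither form nor join regions.
    """
    active = diff.active_mask
    labels, n = ndimage.label(active, structure=_structure(cfg.connectivity))
    if n == 0:
        return DepthDiffFrame(
            diff.diffs.copy(), diff.valid_mask.copy(), second_index=diff.second_index
        )
    sizes = np.bincount(labels.ravel())
    small = sizes < cfg.min_region_px
    small[0] = False
    drop = small[labels]
    keep = diff.valid_mask & ~drop
    return DepthDiffFrame(
        np.where(keep, diff.diffs, 0.0), keep, second_index=diff.second_index
    )


def preprocess_clip(
    frames: Sequence[DepthFrame], cfg: DenoiseConfig = DenoiseConfig()
) -> tuple[list[DepthDiffFrame], list[DepthFrame]]:
    """Run the full cascade on a clip.

    Returns ``(diff_frames, clipped_frames)``: one cleaned difference frame
    per second (``n_spans - 1`` of them) and the clipped averaged depth
    frames (``n_spans``) needed by the feature extractor for depth
    statistics and distance normalization.
    """
    averaged = temporal_median(frames, cfg)
    clipped = [clip_depth_percentiles(f, cfg) for f in averaged]
    diffs: list[DepthDiffFrame] = []
    for t in range(len(clipped) - 1):
        d = depth_difference(clipped[t], clipped[t + 1], second_index=t)
        d = spatial_median_filter(d, cfg)
        d = remove_large_differences(d, cfg)
        d = remove_small_regions(d, cfg)
        diffs.append(d)
    return diffs, clipped


__all__ = [
    "DenoiseConfig",
    "DepthDiffFrame",
    "infer_fps",
    "temporal_median",
    "clip_depth_percentiles",
    "depth_difference",
    "spatial_median_filter",
    "remove_large_differences",
    "remove_small_regions",
    "preprocess_clip",
]
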