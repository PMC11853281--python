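"""Brute-force reference implementations used as independent oracles.

Everything here is written for transparency, not speed: explicit Python
loops, flood fill with an explicit stack, pairwise concordance counting.
These functions deliberately share no code with the package.
"""

from __future__ import annotations

import numpy as np


def median_of(values: list[float]) -> float:
    """Sort-and-middle median."""
    s = sorted(values)
    n = len(s)
    if n == 0:
        raise ValueError("median of empty list")
    if n % 2:
        return float(s[n // 2])
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def pixelwise_median(stack: np.ndarray, valid: np.ndarray, min_valid: int):
    """Per-pixel median over axis 0 using only valid entries.

    Returns (median, ok) where ok marks pixels valid in at least
    ``min_valid`` frames.
    """
    n, h, w = stack.shape
    med = np.zeros((h, w))
    ok = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            vals = [float(stack[k, i, j]) for k in range(n) if valid[k, i, j]]
            if len(vals) >= min_valid:
                med[i, j] = median_of(vals)
                ok[i, j] = True
    return med, ok


def percentile_clip(depths: np.ndarray, valid: np.ndarray, lo_pct, hi_pct, rng_mm):
    """Keep pixels with depth in [p_lo, p_hi] of the in-range distribution."""
    in_range = valid & (depths >= rng_mm[0]) & (depths <= rng_mm[1])
    vals = depths[in_range]
    if vals.size == 0:
        return np.zeros_like(in_range)
    p_lo = np.percentile(vals, lo_pct)
    p_hi = np.percentile(vals, hi_pct)
    return in_range & (depths >= p_lo) & (depths <= p_hi)


def masked_median_filter(values: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Windowed median over valid neighbours only; invalid pixels untouched."""
    h, w = values.shape
    r = k // 2
    out = values.copy()
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            window = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    y, x = i + di, j + dj
                    if 0 <= y < h and 0 <= x < w and mask[y, x]:
                        window.append(float(values[y, x]))
            out[i, j] = median_of(window)
    return out


def large_diff_survivors(diffs: np.ndarray, mask: np.ndarray, max_diff: float):
    """Mask of pixels surviving the |diff| <= max_diff rule."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            out[i, j] = mask[i, j] and abs(float(diffs[i, j])) <= max_diff
    return out


def flood_fill_regions(active: np.ndarray, connectivity: int):
    """Connected components of an active mask via explicit flood fill."""
    h, w = active.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if active[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and active[ny, nx] and labels[ny, nx] == 0
                        ):
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels, current


def small_region_survivors(diffs, mask, min_px: int, connectivity: int):
    """Valid mask after dropping active components smaller than min_px."""
    active = mask & (diffs != 0)
    labels, n = flood_fill_regions(active, connectivity)
    keep = mask.copy()
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_px:
            keep &= ~comp
    return keep


def concordance_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_optimal_threshold(probs: np.ndarray, labels: np.ndarray):
    """Enumerate swept thresholds; return (threshold, best mean sens/spec).

    Sweeps -inf plus every unique probability with the strict ``>`` rule,
    breaking ties toward the lower threshold.
    """
    candidates = [-np.inf] + sorted(set(probs.tolist()))
    best_t, best_m = None, -1.0
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    for t in candidates:
        pred = probs > t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        m = (sens + spec) / 2
        if m > best_m:  # strict: first (lowest) threshold wins ties
            best_m, best_t = m, t
    return best_t, best_m
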