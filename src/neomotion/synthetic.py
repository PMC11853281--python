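"""Synthetic labelled depth clips emulating a NICU depth-camera scene.

No study recordings are distributed, so every stage of the pipeline is
exercised on simulated scenes with the structure the method assumes:

* a flat background (cot surface) at ~950 mm with a neonate-like
  half-ellipsoid body surface bulging toward the camera, its chest
  230-800 mm from the lens (the study's placement range); the body carries
  static low-frequency relief (bedding folds, limbs) so the scene's depth
  distribution is diffuse near its minimum, as real scenes are, rather
  than a smooth dome whose whole apex sits below the 3rd percentile;
* near clutter: nesting rolls / isolette edges in the frame corners,
  closer to the camera than the chest.  The percentile clip exists to cut
  exactly this near (and far) non-neonate structure; without any
  closer-than-body surface the 3rd-percentile cut would erase the body
  apex - the place where motion happens - instead;
* quiet breathing: a ~2 mm sinusoidal surface modulation at ~50
  breaths/min over a chest sub-ellipse (present in both classes - it is
  *not* motion);
* intermittent limb/torso motion events: an elliptical bump (50-500 px)
  raised toward the camera by 5-120 mm, with a half-cosine onset/offset
  ramp (0.3 s), a piecewise-smooth random height trajectory, and a lateral
  wander of the bump centre so consecutive one-second snapshots differ the
  way a fidgeting limb does (real motion is largely lateral in the image
  plane; a patch that only plunged axially would dive below the scene's
  3rd-percentile depth and be clipped away);
* sensor noise: per-pixel Gaussian jitter whose sigma grows linearly with
  depth (0.5 mm at 300 mm to 2 mm at 900 mm, the error growth of stereo
  depth sensors), no-return dropouts (value 0) and sparse far outliers.

Truth labels follow the package-wide alignment rule: second ``t`` is
motion iff an event is active at some point of ``[t, t+1]``, the interval
between the two averaged snapshots whose difference the feature vector for
second ``t`` measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .depth_io import (
    BED_TYPES,
    CAMERA_LOCATIONS,
    COVER_TYPES,
    ClipMetadata,
    DepthFrame,
    LabelSeries,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RespirationConfig:
    """Quiet-breathing surface motion over the chest sub-ellipse."""

    amplitude_mm: float = 2.0
    rate_bpm: float = 50.0


@dataclass(frozen=True)
class EventConfig:
    """Gross-motion events (the positive class).

    Events arrive as a Poisson process at ``rate_per_min``; each has a
    uniform duration, patch area, and peak amplitude drawn from the given
    ranges.  ``ramp_s`` is the half-cosine onset/offset ramp;
    ``trajectory_step_s`` spaces the random control points of the
    within-event motion trajectory.
    """

    rate_per_min: float = 3.0
    duration_s_range: tuple[float, float] = (1.0, 5.0)
    region_px_range: tuple[float, float] = (50.0, 500.0)
    amplitude_mm_range: tuple[float, float] = (5.0, 120.0)
    ramp_s: float = 0.3
    trajectory_step_s: float = 0.5
    wander_frac: float = 0.7  # lateral wander of the bump centre, in radii


@dataclass(frozen=True)
class NoiseConfig:
    """Depth-sensor noise model.

    ``sigma_mm`` is the Gaussian jitter at ``sigma_ref_mm``;
    ``sigma_slope_per_mm`` adds to it linearly with distance (the default
    pair gives 0.5 mm at 300 mm and 2 mm at 900 mm).  Dropouts are encoded
    as 0 (no return); outliers take ``outlier_mm``.
    """

    sigma_mm: float = 0.5
    sigma_ref_mm: float = 300.0
    sigma_slope_per_mm: float = 0.0025
    dropout_prob: float = 0.005
    outlier_prob: float = 5e-4
    outlier_mm: float = 1500.0

    def sigma_at(self, depth_mm: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(
            self.sigma_mm + self.sigma_slope_per_mm * (np.asarray(depth_mm) - self.sigma_ref_mm),
            0.05,
        )


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic clip."""

    frame_shape: tuple[int, int] = (240, 320)
    fps: int = 30
    duration_s: float = 300.0
    background_depth_mm: float = 950.0
    body_depth_mm: float = 450.0
    body_axes_px: tuple[float, float] = (90.0, 130.0)
    chest_axes_px: tuple[float, float] = (30.0, 42.0)
    relief_mm: float = 25.0  # RMS of the static body-surface texture
    relief_scale_px: float = 28.0  # correlation length of the texture
    clutter_area_frac: float = 0.08  # frame fraction of near clutter (0 = off)
    clutter_offset_mm: float = 80.0  # how much closer the clutter sits
    respiration: RespirationConfig = field(default_factory=RespirationConfig)
    events: EventConfig = field(default_factory=EventConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    valid_range_mm: tuple[float, float] = (200.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_depth_mm >= self.background_depth_mm:
            raise ValueError("body must be closer to the camera than the background")
        if self.body_depth_mm <= 0:
            raise ValueError("body_depth_mm must be positive")
        if min(self.events.amplitude_mm_range) <= 0:
            raise ValueError("event amplitudes must be positive")
        if max(self.events.amplitude_mm_range) >= 150:
            raise ValueError(
                "event amplitudes must stay below 150 mm to survive the "
                "large-difference filter"
            )
        body_area = math.pi * self.body_axes_px[0] * self.body_axes_px[1]
        if max(self.region_px_range) > body_area:
            raise ValueError(
                f"event region up to {max(self.region_px_range):.0f} px exceeds "
                f"the body area ({body_area:.0f} px)"
            )
        if self.fps * 1.0 < 10:
            raise ValueError("fps must allow 10 frames per 1-s span")

    @property
    def region_px_range(self) -> tuple[float, float]:
        return self.events.region_px_range

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def n_spans(self) -> int:
        return self.n_frames // self.fps


@dataclass(frozen=True)
class _Event:
    start_s: float
    duration_s: float
    amplitude_mm: float
    center_px: tuple[float, float]
    axes_px: tuple[float, float]
    # control points, one per trajectory_step_s: bump height in [0, 1] and
    # lateral centre offsets in pixels
    trajectory: tuple[float, ...]
    offsets_y: tuple[float, ...] = (0.0,)
    offsets_x: tuple[float, ...] = (0.0,)

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def _ellipse_profile(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
) -> np.ndarray:
    """Smooth bump sqrt(1 - r^2) inside the ellipse, 0 outside."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    r2 = ((yy - center[0]) / axes[0]) ** 2 + ((xx - center[1]) / axes[1]) ** 2
    return np.sqrt(np.clip(1.0 - r2, 0.0, None)).astype(np.float32)


def _surface_relief(
    shape: tuple[int, int], scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth zero-mean unit-RMS random field with the given correlation length."""
    from scipy import ndimage

    h, w = shape
    ch = max(int(np.ceil(h / scale_px)) + 3, 4)
    cw = max(int(np.ceil(w / scale_px)) + 3, 4)
    coarse = rng.standard_normal((ch, cw))
    field = ndimage.zoom(coarse, (h / ch, w / cw), order=3, mode="nearest")
    field = field[:h, :w]
    field -= field.mean()
    rms = float(np.sqrt((field**2).mean()))
    return field / rms if rms > 0 else field


def _envelope(t_in_event: np.ndarray, duration: float, ramp: float) -> np.ndarray:
    """Half-cosine onset/offset ramp, clipped to the event duration."""
    ramp = min(ramp, duration / 2)
    up = np.clip(t_in_event / ramp, 0.0, 1.0) if ramp > 0 else np.ones_like(t_in_event)
    down = (
        np.clip((duration - t_in_event) / ramp, 0.0, 1.0)
        if ramp > 0
        else np.ones_like(t_in_event)
    )
    env = np.minimum(up, down)
    return 0.5 * (1.0 - np.cos(np.pi * env))


def _interp_control(points, t_in_event: np.ndarray, step: float) -> np.ndarray:
    """Linear interpolation of per-event random control points."""
    pts = np.asarray(points, dtype=np.float64)
    grid = np.arange(pts.size) * step
    return np.interp(t_in_event, grid, pts)


def _schedule_events(cfg: SceneConfig, rng: np.random.Generator) -> list[_Event]:
    ec = cfg.events
    if ec.rate_per_min <= 0:
        return []
    n = int(rng.poisson(ec.rate_per_min * cfg.duration_s / 60.0))
    h, w = cfg.frame_shape
    cy, cx = h / 2.0, w / 2.0
    by, bx = cfg.body_axes_px
    events = []
    for _ in range(n):
        dur = float(rng.uniform(*ec.duration_s_range))
        start = float(rng.uniform(0.0, max(cfg.duration_s - dur, 0.0)))
        area = float(rng.uniform(*ec.region_px_range))
        # random elongation, area-preserving
        elong = float(rng.uniform(0.6, 1.6))
        ry = math.sqrt(area / math.pi) * elong
        rx = math.sqrt(area / math.pi) / elong
        # keep the patch centre well inside the body ellipse
        theta = float(rng.uniform(0, 2 * math.pi))
        rad = float(rng.uniform(0, 0.6))
        center = (cy + rad * by * math.sin(theta), cx + rad * bx * math.cos(theta))
        amp = float(rng.uniform(*ec.amplitude_mm_range))
        n_pts = max(int(math.ceil(dur / ec.trajectory_step_s)) + 1, 2)
        traj = tuple(float(v) for v in rng.uniform(0.2, 1.0, size=n_pts))
        off_y = tuple(
            float(v) for v in rng.uniform(-1.0, 1.0, size=n_pts) * ec.wander_frac * ry
        )
        off_x = tuple(
            float(v) for v in rng.uniform(-1.0, 1.0, size=n_pts) * ec.wander_frac * rx
        )
        events.append(
            _Event(
                start_s=start,
                duration_s=dur,
                amplitude_mm=amp,
                center_px=center,
                axes_px=(ry, rx),
                trajectory=traj,
                offsets_y=off_y,
                offsets_x=off_x,
            )
        )
    return sorted(events, key=lambda e: e.start_s)


def _labels_from_schedule(events: Sequence[_Event], n_spans: int) -> LabelSeries:
    """Second t is motion iff an event is active somewhere in [t, t+1]."""
    labels = np.zeros(max(n_spans - 1, 0), dtype=np.int64)
    for ev in events:
        for t in range(labels.size):
            if ev.start_s <= t + 1 and ev.end_s > t:
                labels[t] = 1
    return LabelSeries(labels)


def default_metadata(cfg: SceneConfig, subject_id: str = "synthetic") -> ClipMetadata:
    return ClipMetadata(
        subject_id=subject_id,
        bed_type="bassinet",
        cover_type="sleep suit",
        camera_location="above",
        distance_mm=cfg.body_depth_mm,
        gestational_age_weeks=40.0,
    )


def generate_clip(
    cfg: SceneConfig, metadata: ClipMetadata | None = None
) -> tuple[list[DepthFrame], LabelSeries, ClipMetadata]:
    """Render one labelled clip; deterministic given ``cfg.seed``.

    Returns frames in integer millimetres (dropouts as 0), the per-second
    truth labels and the clip metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_shape
    events = _schedule_events(cfg, rng)
    labels = _labels_from_schedule(events, cfg.n_spans)

    cy, cx = h / 2.0, w / 2.0
    body = _ellipse_profile((h, w), (cy, cx), cfg.body_axes_px)
    base = cfg.background_depth_mm - (cfg.background_depth_mm - cfg.body_depth_mm) * body
    if cfg.relief_mm > 0:
        base = base + cfg.relief_mm * _surface_relief(
            (h, w), cfg.relief_scale_px, rng
        ) * np.sqrt(body)  # texture tapers toward the body edge
    if cfg.clutter_area_frac > 0:
        # nesting rolls / isolette edges in two corners, closer than the chest
        lo = cfg.valid_range_mm[0]
        depth_c = max(cfg.body_depth_mm - cfg.clutter_offset_mm, lo + 5.0)
        aspect = 1.3
        a = math.sqrt(cfg.clutter_area_frac * h * w / (2.0 * math.pi * aspect))
        axes_c = (a, a * aspect)
        for center in ((0.08 * h, 0.10 * w), (0.92 * h, 0.90 * w)):
            prof_c = _ellipse_profile((h, w), center, axes_c)
            surf = depth_c + 40.0 * (1.0 - prof_c)  # gently sloped roll
            base = np.where(prof_c > 0, np.minimum(base, surf), base)
    base = np.clip(base, 1.0, None).astype(np.float32)
    chest_center = (cy - 0.25 * cfg.body_axes_px[0], cx)
    chest = _ellipse_profile((h, w), chest_center, cfg.chest_axes_px)
    sigma_map = cfg.noise.sigma_at(base).astype(np.float32)

    n = cfg.n_frames
    stack = np.empty((n, h, w), dtype=np.uint16)
    resp = cfg.respiration
    omega = 2.0 * math.pi * resp.rate_bpm / 60.0
    resp_phase = float(rng.uniform(0, 2 * math.pi))
    nz = cfg.noise
    chunk = cfg.fps  # one second of frames at a time
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        times = idx / cfg.fps
        depth = np.broadcast_to(base, (idx.size, h, w)).copy()
        if resp.amplitude_mm > 0:
            disp = resp.amplitude_mm * np.sin(omega * times + resp_phase)
            depth -= disp[:, None, None].astype(np.float32) * chest[None]
        for ev in events:
            sel = (times >= ev.start_s) & (times < ev.end_s)
            if not sel.any():
                continue
            step = cfg.events.trajectory_step_s
            t_in = times[sel] - ev.start_s
            amp = (
                ev.amplitude_mm
                * _envelope(t_in, ev.duration_s, cfg.events.ramp_s)
                * _interp_control(ev.trajectory, t_in, step)
            ).astype(np.float32)
            cys = ev.center_px[0] + _interp_control(ev.offsets_y, t_in, step)
            cxs = ev.center_px[1] + _interp_control(ev.offsets_x, t_in, step)
            ry, rx = ev.axes_px
            # bounding box covering the bump over its whole wander range
            y0 = max(int(np.floor(cys.min() - ry)) - 1, 0)
            y1 = min(int(np.ceil(cys.max() + ry)) + 2, h)
            x0 = max(int(np.floor(cxs.min() - rx)) - 1, 0)
            x1 = min(int(np.ceil(cxs.max() + rx)) + 2, w)
            if y0 >= y1 or x0 >= x1:
                continue
            yy = np.arange(y0, y1, dtype=np.float32)
            xx = np.arange(x0, x1, dtype=np.float32)
            r2 = (
                ((yy[None, :, None] - cys[:, None, None].astype(np.float32)) / ry) ** 2
                + ((xx[None, None, :] - cxs[:, None, None].astype(np.float32)) / rx) ** 2
            )
            bump = np.sqrt(np.clip(1.0 - r2, 0.0, None))
            depth[sel, y0:y1, x0:x1] -= amp[:, None, None] * bump
        if nz.sigma_mm > 0:
            depth += rng.standard_normal(depth.shape, dtype=np.float32) * sigma_map
        if nz.dropout_prob > 0 or nz.outlier_prob > 0:
            u = rng.random(depth.shape, dtype=np.float32)
            if nz.outlier_prob > 0:
                depth[u >= 1.0 - nz.outlier_prob] = nz.outlier_mm
            drop = u < nz.dropout_prob
        else:
            drop = None
        np.clip(depth, 0, np.iinfo(np.uint16).max, out=depth)
        quant = np.rint(depth).astype(np.uint16)
        if drop is not None:
            quant[drop] = 0
        stack[idx[0] : idx[-1] + 1] = quant

    frames = [
        DepthFrame(stack[i], timestamp=i / cfg.fps, valid_range=cfg.valid_range_mm)
        for i in range(n)
    ]
    meta = metadata if metadata is not None else default_metadata(cfg)
    return frames, labels, meta


# ---------------------------------------------------------------------------
# multi-subject studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Shape of a multi-subject synthetic study.

    ``clips_per_subject`` is an int (same count for everyone) or one count
    per subject.  Per-clip camera distance is drawn uniformly from
    ``distance_range_mm``, mirroring the varied placements of the study
    design.
    """

    n_subjects: int = 20
    clips_per_subject: int | tuple[int, ...] = 6
    distance_range_mm: tuple[float, float] = (230.0, 800.0)
    scene: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0

    def counts(self) -> list[int]:
        if isinstance(self.clips_per_subject, int):
            return [self.clips_per_subject] * self.n_subjects
        if len(self.clips_per_subject) != self.n_subjects:
            raise ValueError("clips_per_subject list length must equal n_subjects")
        return list(self.clips_per_subject)


@dataclass(frozen=True)
class SyntheticClip:
    """A lazily-rendered clip of a study: metadata now, frames on demand."""

    clip_id: str
    scene: SceneConfig
    metadata: ClipMetadata

    def generate(self) -> tuple[list[DepthFrame], LabelSeries, ClipMetadata]:
        frames, labels, _ = generate_clip(self.scene, metadata=self.metadata)
        return frames, labels, self.metadata

    def labels(self) -> LabelSeries:
        """Truth labels without rendering the frames (schedule only)."""
        rng = np.random.default_rng(self.scene.seed)
        events = _schedule_events(self.scene, rng)
        return _labels_from_schedule(events, self.scene.n_spans)


def generate_study(
    n_subjects: int,
    clips_per_subject: int | Sequence[int],
    seed: int = 0,
    scene: SceneConfig = SceneConfig(),
    distance_range_mm: tuple[float, float] = (230.0, 800.0),
) -> list[SyntheticClip]:
    """Plan a reproducible multi-subject study.

    Each subject gets randomly drawn bed/cover metadata and gestational
    age; each clip gets its own camera location, camera distance and scene
    seed, all derived from the master seed.  Rendering is deferred:
    call :meth:`SyntheticClip.generate` per clip (a whole study of frames
    would not fit in memory).
    """
    if n_subjects < 2:
        raise ValueError("a study needs at least 2 subjects")
    cfg = StudyConfig(
        n_subjects=n_subjects,
        clips_per_subject=(
            clips_per_subject
            if isinstance(clips_per_subject, int)
            else tuple(clips_per_subject)
        ),
        distance_range_mm=distance_range_mm,
        scene=scene,
        seed=seed,
    )
    counts = cfg.counts()
    master = np.random.default_rng(np.random.SeedSequence(seed))
    clips: list[SyntheticClip] = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        bed = str(master.choice(BED_TYPES))
        cover = str(master.choice(COVER_TYPES))
        ga = float(master.uniform(30.0, 42.0))
        for c in range(counts[s]):
            distance = float(master.uniform(*distance_range_mm))
            location = str(master.choice(CAMERA_LOCATIONS))
            clip_seed = int(master.integers(0, 2**31 - 1))
            meta = ClipMetadata(
                subject_id=subject_id,
                bed_type=bed,
                cover_type=cover,
                camera_location=location,
                distance_mm=distance,
                gestational_age_weeks=ga,
            )
            clip_scene = replace(scene, body_depth_mm=distance, seed=clip_seed)
            clips.append(
                SyntheticClip(
                    clip_id=f"{subject_id}C{c + 1:02d}",
                    scene=clip_scene,
                    metadata=meta,
                )
            )
    return clips


__all__ = [
    "RespirationConfig",
    "EventConfig",
    "NoiseConfig",
    "SceneConfig",
    "StudyConfig",
    "SyntheticClip",
    "generate_clip",
    "generate_study",
    "default_metadata",
]
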