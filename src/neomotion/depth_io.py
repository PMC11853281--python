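"""Depth-frame stacks, truth labels and clip metadata: data model and disk formats.

A recording ("positional test run" or *clip*) is a stack of single-channel
depth frames in integer millimetres at a nominal 30 fps, together with a
per-second binary motion truth label table and capture-condition metadata
(bed type, cover type, camera location, camera-to-chest distance).

On disk a clip is either

* a single ``.npy`` file holding a ``T x H x W`` ``uint16`` array (mm), or
* a directory of 16-bit grayscale PNG frames in lexicographic order,

in both cases accompanied by a JSON sidecar (same basename with ``.json``,
or ``sidecar.json`` inside the frame directory) carrying ``fps``,
``valid_range_mm`` and the :class:`ClipMetadata` fields.  Labels and feature
tables are plain CSV with a header row, one row per second.

Conventions used throughout the package:

* depths are stored as integer millimetres and processed in floating point;
* a pixel is *invalid* iff its value is 0 (sensor no-return) or outside the
  clip's plausible ``valid_range`` (default 200-1000 mm);
* images are row-major, origin at the top-left, 0-based indices;
* the feature/label alignment rule: the difference frame (and hence feature
  vector) for second ``t`` is computed between the temporally averaged
  frames at span boundaries ``t`` and ``t + 1`` and is compared with the
  truth label for second ``t``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default plausible depth range (mm); values outside are sensor noise.
DEFAULT_VALID_RANGE_MM = (200.0, 1000.0)

BED_TYPES = ("bassinet", "covered isolette", "uncovered isolette")
COVER_TYPES = (
    "bare skin",
    "sleep suit",
    "loosely covered",
    "loosely swaddled",
    "tightly swaddled",
    "nested",
)
CAMERA_LOCATIONS = ("above", "above-side", "foots end", "heads end", "side")

#: Camera-to-chest distances used in the study design (mm).
STUDY_DISTANCE_RANGE_MM = (230.0, 800.0)

#: Gestational age (weeks) separating term from preterm subjects.
TERM_BOUNDARY_WEEKS = 37.0

_SIDE_CAR_REQUIRED = ("fps", "valid_range_mm")


@dataclass(frozen=True)
class DepthFrame:
    """One depth raster: per-pixel distance to the nearest surface in mm.

    ``depths`` is an ``H x W`` float array.  Invalid pixels (no sensor
    return, or implausibly near/far) are encoded as 0 or as values outside
    ``valid_range``; :attr:`valid_mask` derives validity on the fly so a
    frame never carries a separate mask that can drift out of sync.
    """

    depths: np.ndarray
    timestamp: float = 0.0
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE_MM

    def __post_init__(self) -> None:
        d = np.asarray(self.depths)
        if d.ndim != 2:
            raise ValueError(f"depth frame must be 2-D, got shape {d.shape}")
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("depths must be non-negative (mm)")
        object.__setattr__(self, "depths", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depths.shape  # type: ignore[return-value]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of genuine sensor returns within ``valid_range``."""
        lo, hi = self.valid_range
        d = self.depths
        return (d > 0) & (d >= lo) & (d <= hi)

    def valid_depths(self) -> np.ndarray:
        """1-D array of the valid depth values (mm)."""
        return self.depths[self.valid_mask]


@dataclass(frozen=True)
class LabelSeries:
    """Per-second binary motion truth: 1 = motion, 0 = no motion.

    The series has one entry per depth *difference*, i.e. for a clip with
    ``n`` one-second spans there are ``n - 1`` labels (differences are taken
    between consecutive span boundaries).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("labels must be a 1-D sequence")
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary; found values {sorted(bad)}")
        object.__setattr__(self, "labels", arr)

    @property
    def n_seconds(self) -> int:
        return int(self.labels.size)

    def __len__(self) -> int:
        return self.n_seconds

    @property
    def prevalence(self) -> float:
        """Fraction of seconds labelled as motion."""
        return float(self.labels.mean()) if self.labels.size else 0.0


@dataclass(frozen=True)
class ClipMetadata:
    """Capture conditions for one positional test run.

    ``distance_mm`` is camera-to-chest distance.  The study design used
    230-800 mm; values outside that range are accepted (they are needed for
    stress experiments) but logged.  ``gestational_age_weeks`` is optional
    and only used for the term/preterm subgroup split.
    """

    subject_id: str
    bed_type: str = "bassinet"
    cover_type: str = "sleep suit"
    camera_location: str = "above"
    distance_mm: float = 500.0
    gestational_age_weeks: float | None = None

    def __post_init__(self) -> None:
        if self.bed_type not in BED_TYPES:
            raise ValueError(f"bed_type {self.bed_type!r} not in {BED_TYPES}")
        if self.cover_type not in COVER_TYPES:
            raise ValueError(f"cover_type {self.cover_type!r} not in {COVER_TYPES}")
        if self.camera_location not in CAMERA_LOCATIONS:
            raise ValueError(
                f"camera_location {self.camera_location!r} not in {CAMERA_LOCATIONS}"
            )
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be positive")
        lo, hi = STUDY_DISTANCE_RANGE_MM
        if not lo <= self.distance_mm <= hi:
            logger.info(
                "clip distance %.0f mm outside study range %s mm",
                self.distance_mm,
                STUDY_DISTANCE_RANGE_MM,
            )

    @property
    def term(self) -> str | None:
        """``"term"``/``"preterm"`` split at 37 weeks, or None if unknown."""
        if self.gestational_age_weeks is None:
            return None
        return "term" if self.gestational_age_weeks > TERM_BOUNDARY_WEEKS else "preterm"

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "bed_type": self.bed_type,
            "cover_type": self.cover_type,
            "camera_location": self.camera_location,
            "distance_mm": self.distance_mm,
            "gestational_age_weeks": self.gestational_age_weeks,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClipMetadata":
        return cls(**d)


@dataclass
class RawClip:
    """An in-memory clip: frames + truth labels + capture metadata."""

    frames: Sequence[DepthFrame]
    labels: LabelSeries
    metadata: ClipMetadata
    clip_id: str = "clip"


# ---------------------------------------------------------------------------
# depth stack IO
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "sidecar.json"
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc}: a depth stack requires a JSON sidecar with "
            f"keys {_SIDE_CAR_REQUIRED} (and optionally 'metadata')"
        )
    with open(sc) as fh:
        info = json.load(fh)
    missing = [k for k in _SIDE_CAR_REQUIRED if k not in info]
    if missing:
        raise KeyError(f"sidecar {sc} is missing required keys {missing}")
    return info


def read_depth_stack(path: str | Path) -> list[DepthFrame]:
    """Read a depth stack (``.npy`` file or PNG directory) into frames.

    Timestamps are derived from the sidecar ``fps``; pixel units are mm.
    """
    path = Path(path)
    info = _read_sidecar(path)
    fps = float(info["fps"])
    valid_range = tuple(float(v) for v in info["valid_range_mm"])
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        arrays = []
        shape = None
        for f in files:
            a = np.asarray(iio.imread(f))
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(
                    f"inconsistent frame shapes: {f.name} has {a.shape}, "
                    f"expected {shape}"
                )
            arrays.append(a)
        stack = np.stack(arrays)
    else:
        stack = np.load(path)
        if stack.ndim != 3:
            raise ValueError(f"depth stack must be T x H x W, got shape {stack.shape}")
    stack = stack.astype(np.float64)
    return [
        DepthFrame(stack[i], timestamp=i / fps, valid_range=valid_range)  # type: ignore[arg-type]
        for i in range(stack.shape[0])
    ]


def write_depth_stack(
    path: str | Path,
    frames: Sequence[DepthFrame],
    fps: float,
    metadata: ClipMetadata | None = None,
    as_png_dir: bool = False,
) -> Path:
    """Write frames as a ``uint16`` mm stack plus JSON sidecar.

    ``as_png_dir`` selects the directory-of-PNGs layout; otherwise a single
    ``.npy`` file is written.  Round trips are bit exact for integer depths.
    """
    path = Path(path)
    if not frames:
        raise ValueError("cannot write an empty depth stack")
    stack = np.stack([f.depths for f in frames])
    if np.any(stack < 0) or np.any(stack > np.iinfo(np.uint16).max):
        raise ValueError("depths out of uint16 mm range")
    stack16 = np.rint(stack).astype(np.uint16)
    if as_png_dir:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(len(frames) - 1))
        for i in range(stack16.shape[0]):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", stack16[i])
    else:
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path, stack16)
        path = path if path.suffix == ".npy" else path.with_suffix(".npy")
    info = {
        "fps": fps,
        "valid_range_mm": list(frames[0].valid_range),
    }
    if metadata is not None:
        info["metadata"] = metadata.to_dict()
    with open(_sidecar_path(path), "w") as fh:
        json.dump(info, fh, indent=1)
    return path


def read_clip_metadata(path: str | Path) -> ClipMetadata:
    """Read the :class:`ClipMetadata` embedded in a stack's sidecar."""
    info = _read_sidecar(Path(path))
    if "metadata" not in info:
        raise KeyError(f"sidecar for {path} carries no 'metadata' block")
    return ClipMetadata.from_dict(info["metadata"])


# ---------------------------------------------------------------------------
# label tables
# ---------------------------------------------------------------------------


def read_labels(path: str | Path) -> LabelSeries:
    """Read a per-second label CSV with columns ``second_index,label``.

    The table must be dense: second indices 0..n-1 each exactly once and
    labels strictly binary.
    """
    df = pd.read_csv(path)
    required = {"second_index", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label file {path} must have columns {sorted(required)}")
    sec = df["second_index"].to_numpy()
    if len(np.unique(sec)) != len(sec):
        dupes = sorted(set(sec[pd.Series(sec).duplicated()]))
        raise ValueError(f"duplicate second_index values {dupes} in {path}")
    order = np.argsort(sec)
    sec = sec[order]
    if not np.array_equal(sec, np.arange(len(sec))):
        missing = sorted(set(range(int(sec.max()) + 1)) - set(sec.tolist()))
        raise ValueError(f"label file {path} is not dense; missing seconds {missing[:10]}")
    labels = df["label"].to_numpy()[order]
    if not np.isin(labels, [0, 1]).all():
        raise ValueError(f"non-binary labels in {path}")
    return LabelSeries(labels)


def write_labels(path: str | Path, labels: LabelSeries) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"second_index": np.arange(labels.n_seconds), "label": labels.labels}
    ).to_csv(path, index=False)
    return path


__all__ = [
    "DepthFrame",
    "LabelSeries",
    "ClipMetadata",
    "RawClip",
    "read_depth_stack",
    "write_depth_stack",
    "read_clip_metadata",
    "read_labels",
    "write_labels",
    "DEFAULT_VALID_RANGE_MM",
    "BED_TYPES",
    "COVER_TYPES",
    "CAMERA_LOCATIONS",
    "STUDY_DISTANCE_RANGE_MM",
    "TERM_BOUNDARY_WEEKS",
]
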