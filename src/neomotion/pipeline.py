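"""End-to-end orchestration: simulate, extract, train, predict, evaluate.

These functions are the programmatic counterparts of the CLI commands.
They tie the stage modules together, define the on-disk dataset layout and
keep every run reproducible from a single :class:`~neomotion.config.RunConfig`.

Dataset layout written by :func:`run_simulate`::

    dataset_dir/
      manifest.json            # clip list + study seed + config hash
      clips/<clip_id>.npy      # uint16 mm depth stack
      clips/<clip_id>.json     # sidecar: fps, valid range, metadata
      labels/<clip_id>.csv     # per-second truth labels
      features/<clip_id>.csv   # written by run_extract

Clips are processed strictly one at a time - a full study of raw frames
does not fit in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import classifier, denoise, depth_io, evaluation, features, synthetic
from .denoise import DenoiseConfig
from .depth_io import DepthFrame, RawClip
from .evaluation import LabelledClip, LoocvReport
from .features import FeatureConfig

logger = logging.getLogger(__name__)


def extract_clip_features(
    frames: Sequence[DepthFrame],
    denoise_cfg: DenoiseConfig = DenoiseConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Denoise one clip and compute its per-second feature table."""
    diffs, clipped = denoise.preprocess_clip(frames, denoise_cfg)
    valid_fracs = [d.valid_mask.mean() for d in diffs]
    if valid_fracs:
        logger.debug(
            "clip: %d diff frames, valid-pixel fraction %.2f-%.2f",
            len(diffs), min(valid_fracs), max(valid_fracs),
        )
    return features.extract_features(diffs, clipped, feature_cfg)


def _resolve(clip) -> RawClip:
    if callable(clip):
        clip = clip()
    if isinstance(clip, synthetic.SyntheticClip):
        frames, labels, meta = clip.generate()
        return RawClip(frames, labels, meta, clip_id=clip.clip_id)
    if isinstance(clip, RawClip):
        return clip
    raise TypeError(f"cannot interpret {type(clip).__name__} as a clip")


def build_dataset(
    clips: Sequence,
    denoise_cfg: DenoiseConfig = DenoiseConfig(),
    feature_cfg: FeatureConfig = FeatureConfig(),
) -> list[LabelledClip]:
    """Reduce raw/synthetic clips to their per-second labelled features.

    Accepts :class:`RawClip`, :class:`~neomotion.synthetic.SyntheticClip`
    or zero-argument callables returning either; frames are released after
    each clip.
    """
    out: list[LabelledClip] = []
    for item in clips:
        raw = _resolve(item)
        t0 = time.perf_counter()
        table = extract_clip_features(raw.frames, denoise_cfg, feature_cfg)
        n = len(table)
        if n != raw.labels.n_seconds:
            raise ValueError(
                f"clip {raw.clip_id}: {n} feature rows vs "
                f"{raw.labels.n_seconds} labels"
            )
        logger.info(
            "extracted %s: %d seconds in %.1fs", raw.clip_id, n,
            time.perf_counter() - t0,
        )
        out.append(
            LabelledClip(
                features=table,
                labels=raw.labels,
                metadata=raw.metadata,
                clip_id=raw.clip_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# disk-backed runs
# ---------------------------------------------------------------------------


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_simulate(run_cfg) -> Path:
    """Render the configured synthetic study to disk with a manifest."""
    study = run_cfg.study
    out = Path(run_cfg.paths.dataset_dir)
    (out / "clips").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    plan = synthetic.generate_study(
        n_subjects=study.n_subjects,
        clips_per_subject=study.clips_per_subject,
        seed=run_cfg.seed,
        scene=study.scene,
        distance_range_mm=study.distance_range_mm,
    )
    entries = []
    for clip in plan:
        frames, labels, meta = clip.generate()
        stack_path = depth_io.write_depth_stack(
            out / "clips" / f"{clip.clip_id}.npy",
            frames,
            fps=clip.scene.fps,
            metadata=meta,
        )
        label_path = depth_io.write_labels(
            out / "labels" / f"{clip.clip_id}.csv", labels
        )
        entries.append(
            {
                "clip_id": clip.clip_id,
                "subject_id": meta.subject_id,
                "stack": str(stack_path.relative_to(out)),
                "labels": str(label_path.relative_to(out)),
            }
        )
        logger.info("simulated %s (%d frames)", clip.clip_id, len(frames))
    manifest = {
        "seed": run_cfg.seed,
        "n_subjects": study.n_subjects,
        "config_hash": _config_hash(asdict(study)),
        "clips": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out / "manifest.json"


def _read_manifest(dataset_dir: Path) -> dict:
    mf = dataset_dir / "manifest.json"
    if not mf.exists():
        raise FileNotFoundError(f"no manifest.json in {dataset_dir}")
    with open(mf) as fh:
        return json.load(fh)


def clip_loaders(dataset_dir: str | Path) -> list[Callable[[], RawClip]]:
    """Lazy loaders for every clip in a dataset directory."""
    dataset_dir = Path(dataset_dir)
    manifest = _read_manifest(dataset_dir)

    def make(entry):
        def load() -> RawClip:
            frames = depth_io.read_depth_stack(dataset_dir / entry["stack"])
            labels = depth_io.read_labels(dataset_dir / entry["labels"])
            meta = depth_io.read_clip_metadata(dataset_dir / entry["stack"])
            return RawClip(frames, labels, meta, clip_id=entry["clip_id"])

        return load

    return [make(e) for e in manifest["clips"]]


def run_extract(run_cfg) -> list[Path]:
    """Compute and store one feature CSV per clip of the dataset."""
    dataset_dir = Path(run_cfg.paths.dataset_dir)
    manifest = _read_manifest(dataset_dir)
    feat_dir = dataset_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    written, failures = [], []
    for entry in manifest["clips"]:
        try:
            frames = depth_io.read_depth_stack(dataset_dir / entry["stack"])
            table = extract_clip_features(frames, run_cfg.denoise, run_cfg.features)
            written.append(
                features.write_feature_table(
                    feat_dir / f"{entry['clip_id']}.csv", table
                )
            )
        except Exception:  # noqa: BLE001 - skip corrupt clips, fail if all do
            logger.exception("failed to extract clip %s; skipped", entry["clip_id"])
            failures.append(entry["clip_id"])
    if failures and not written:
        raise RuntimeError(f"feature extraction failed for every clip: {failures}")
    return written


def load_labelled_clips(run_cfg) -> list[LabelledClip]:
    """Assemble LabelledClips from extracted feature CSVs + label tables."""
    dataset_dir = Path(run_cfg.paths.dataset_dir)
    manifest = _read_manifest(dataset_dir)
    out = []
    for entry in manifest["clips"]:
        table = features.read_feature_table(
            dataset_dir / "features" / f"{entry['clip_id']}.csv"
        )
        labels = depth_io.read_labels(dataset_dir / entry["labels"])
        meta = depth_io.read_clip_metadata(dataset_dir / entry["stack"])
        out.append(
            LabelledClip(
                features=table, labels=labels, metadata=meta,
                clip_id=entry["clip_id"],
            )
        )
    return out


def run_train(run_cfg) -> Path:
    """Train one forest on all extracted seconds and persist it.

    The stored model embeds the training-ROC optimal threshold so
    ``predict`` can flag motion out of the box.
    """
    clips = load_labelled_clips(run_cfg)
    X = pd.concat([c.features for c in clips], ignore_index=True)
    y = np.concatenate([c.labels.labels for c in clips])
    model = classifier.fit_forest(
        X, y, run_cfg.forest,
        feature_config=run_cfg.features, denoise_config=run_cfg.denoise,
    )
    roc = evaluation.roc_curve(classifier.predict_proba(model, X), y)
    model.training_threshold = roc.optimal_threshold
    path = Path(run_cfg.paths.model_path)
    classifier.save_model(path, model)
    logger.info(
        "trained on %d seconds; training threshold %.3f", len(y),
        roc.optimal_threshold,
    )
    return path


def run_predict(run_cfg, clip_path: str | Path, out_path: str | Path) -> Path:
    """Apply a stored model to one clip and write the per-second signal."""
    model = classifier.load_model(run_cfg.paths.model_path)
    frames = depth_io.read_depth_stack(clip_path)
    dcfg = model.denoise_config or run_cfg.denoise
    fcfg = model.feature_config or run_cfg.features
    table = extract_clip_features(frames, dcfg, fcfg)
    signal = classifier.predict_proba(model, table)
    thr = (
        model.training_threshold
        if model.training_threshold is not None
        else 0.5
    )
    flags = classifier.classify_motion(signal, thr)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "second_index": table["second_index"],
            "probability": signal.probs,
            "motion": flags.labels,
        }
    ).to_csv(out_path, index=False)
    return out_path


def run_evaluate(run_cfg, plots: bool = False) -> LoocvReport:
    """Run the per-subject leave-one-out protocol and write the report."""
    clips = load_labelled_clips(run_cfg)
    report = evaluation.loocv(clips, run_cfg.forest, seed=run_cfg.seed)
    out = Path(run_cfg.paths.report_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_clip.to_csv(out / "per_clip.csv", index=False)
    pd.DataFrame([report.summary]).to_csv(out / "summary.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": list(report.fold_thresholds),
            "threshold": list(report.fold_thresholds.values()),
        }
    ).to_csv(out / "fold_thresholds.csv", index=False)
    if plots:
        _write_plots(report, out)
    logger.info(
        "evaluation: mean AUC %.3f, sens %.3f, spec %.3f over %d clips",
        report.summary["mean_auc"], report.summary["mean_sensitivity"],
        report.summary["mean_specificity"], report.n_clips,
    )
    return report


def _write_plots(report: LoocvReport, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ok = report.per_clip[~report.per_clip["excluded"]]
    ax.scatter(ok["distance_mm"], ok["auc"], s=12)
    ax.set_xlabel("camera distance (mm)")
    ax.set_ylabel("test ROC-AUC")
    ax.set_ylim(0.0, 1.02)
    fig.tight_layout()
    fig.savefig(out / "auc_vs_distance.png", dpi=120)
    plt.close(fig)


def run_grid_search(run_cfg, forest_grid, denoise_grid, out_path: str | Path):
    """Grid search over disk-backed clips; writes the score table."""
    loaders = clip_loaders(run_cfg.paths.dataset_dir)
    best_forest, best_denoise, scores = classifier.grid_search(
        loaders, forest_grid, denoise_grid, run_cfg.features, seed=run_cfg.seed
    )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out_path, index=False)
    return best_forest, best_denoise, scores


__all__ = [
    "extract_clip_features",
    "build_dataset",
    "clip_loaders",
    "load_labelled_clips",
    "run_simulate",
    "run_extract",
    "run_train",
    "run_predict",
    "run_evaluate",
    "run_grid_search",
]
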