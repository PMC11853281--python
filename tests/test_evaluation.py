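"""ROC construction, optimal-threshold selection and the LOOCV protocol."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from neomotion.classifier import ForestConfig
from neomotion.depth_io import ClipMetadata, LabelSeries
from neomotion.evaluation import (
    LabelledClip,
    loocv,
    optimal_threshold,
    roc_curve,
    subgroup_auc,
)
from neomotion.features import FEATURE_COLUMNS


def random_instance(rng, n=40, tied=False):
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    probs = rng.random(n)
    if tied:
        probs = np.round(probs, 1)  # force ties
    return probs, labels


class TestRocCurve:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        roc = roc_curve(np.array([0.1, 0.2, 0.8, 0.9]), labels)
        assert roc.auc == 1.0
        assert roc.optimal_sensitivity == 1.0
        assert roc.optimal_specificity == 1.0

    def test_null_scores_auc_near_half(self, rng):
        labels = rng.integers(0, 2, size=4000)
        probs = rng.random(4000)
        roc = roc_curve(probs, labels)
        assert 0.46 < roc.auc < 0.54

    @pytest.mark.parametrize("tied", [False, True])
    def test_auc_equals_concordance_oracle(self, rng, tied):
        for _ in range(60):
            probs, labels = random_instance(rng, n=int(rng.integers(6, 50)), tied=tied)
            roc = roc_curve(probs, labels)
            assert roc.auc == pytest.approx(
                oracle.concordance_auc(probs, labels), abs=1e-12
            )

    def test_monotone_operating_points(self, rng):
        probs, labels = random_instance(rng, n=60, tied=True)
        roc = roc_curve(probs, labels)
        assert np.all(np.diff(roc.sensitivity) <= 0)  # thresholds ascend
        assert np.all(np.diff(roc.specificity) >= 0)

    def test_single_class_error_names_clip(self):
        with pytest.raises(ValueError, match="clip77"):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]), clip_id="clip77")


class TestOptimalThreshold:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            probs, labels = random_instance(rng, n=int(rng.integers(6, 50)), tied=True)
            roc = roc_curve(probs, labels)
            expect_t, expect_m = oracle.exhaustive_optimal_threshold(probs, labels)
            assert optimal_threshold(roc) == expect_t
            got_m = (roc.optimal_sensitivity + roc.optimal_specificity) / 2
            assert got_m == pytest.approx(expect_m, abs=1e-12)

    def test_three_point_enumeration(self):
        # balanced means 0.75, 1.0, 0.75 -> the middle threshold wins
        probs = np.array([0.1, 0.1, 0.5, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert optimal_threshold(roc_curve(probs, labels)) == 0.1

    def test_invariant_to_duplicated_probabilities(self, rng):
        probs, labels = random_instance(rng, n=30, tied=True)
        t1 = optimal_threshold(roc_curve(probs, labels))
        t2 = optimal_threshold(
            roc_curve(np.concatenate([probs, probs]), np.concatenate([labels, labels]))
        )
        assert t1 == t2


def synthetic_clip(subject, clip_idx, rng, n=60, signal=4.0, meta_kwargs=None,
                   labels=None):
    """A LabelledClip whose first feature carries the class signal."""
    if labels is None:
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]  # both classes present
    n = len(labels)
    X = rng.normal(0, 1.0, size=(n, len(FEATURE_COLUMNS)))
    X[:, 0] += signal * labels
    meta = ClipMetadata(
        subject_id=subject, **(meta_kwargs or {"distance_mm": 400.0})
    )
    return LabelledClip(
        features=pd.DataFrame(X, columns=list(FEATURE_COLUMNS)),
        labels=LabelSeries(labels),
        metadata=meta,
        clip_id=f"{subject}C{clip_idx}",
    )


def small_forest():
    return ForestConfig(n_trees=30, seed=0)


class TestLoocv:
    def test_two_subject_protocol(self, rng):
        clips = [synthetic_clip("A", 1, rng), synthetic_clip("B", 1, rng)]
        report = loocv(clips, small_forest(), seed=0)
        assert report.n_clips == 2
        assert set(report.fold_thresholds) == {"A", "B"}
        assert report.summary["mean_auc"] > 0.85  # strong signal

    def test_requires_two_subjects(self, rng):
        with pytest.raises(ValueError, match="2 subjects"):
            loocv([synthetic_clip("A", 1, rng)], small_forest())

    def test_study_arithmetic_115_clips(self, rng):
        """17 subjects x 6 clips plus 3, 5, 5 -> exactly 115 per-clip rows."""
        counts = [6] * 17 + [3, 5, 5]
        clips = [
            synthetic_clip(f"S{s:02d}", c, rng, n=25)
            for s, cnt in enumerate(counts)
            for c in range(cnt)
        ]
        report = loocv(clips, ForestConfig(n_trees=10, seed=0), seed=0)
        assert report.n_clips == 115
        assert len(report.fold_thresholds) == 20

    def test_single_class_clip_excluded_not_dropped(self, rng):
        clips = [
            synthetic_clip("A", 1, rng),
            synthetic_clip("A", 2, rng, labels=np.zeros(30, dtype=int)),
            synthetic_clip("B", 1, rng),
        ]
        report = loocv(clips, small_forest(), seed=0)
        assert report.n_clips == 3
        assert report.summary["n_excluded"] == 1
        row = report.per_clip[report.per_clip["clip_id"] == "AC2"].iloc[0]
        assert bool(row["excluded"]) and np.isnan(row["auc"])

    def test_no_leakage_across_folds(self, rng):
        """Corrupting one subject's labels must not change other folds."""
        def build(poison):
            r = np.random.default_rng(42)
            clips = [
                synthetic_clip("A", 1, r), synthetic_clip("B", 1, r),
                synthetic_clip("C", 1, r),
            ]
            if poison:
                flipped = 1 - clips[2].labels.labels
                flipped[:2] = [0, 1]
                clips[2] = LabelledClip(
                    features=clips[2].features, labels=LabelSeries(flipped),
                    metadata=clips[2].metadata, clip_id=clips[2].clip_id,
                )
            return loocv(clips, small_forest(), seed=1)

        clean, poisoned = build(False), build(True)
        # fold C (trained on A+B) is identical in both runs
        assert clean.fold_thresholds["C"] == poisoned.fold_thresholds["C"]
        a = clean.per_clip.set_index("clip_id").loc["CC1", "threshold"]
        b = poisoned.per_clip.set_index("clip_id").loc["CC1", "threshold"]
        assert a == b

    def test_summary_recomputable_from_rows(self, rng):
        clips = [synthetic_clip(s, c, rng) for s in "ABC" for c in (1, 2)]
        report = loocv(clips, small_forest(), seed=0)
        ok = report.per_clip[~report.per_clip["excluded"]]
        assert report.summary["mean_auc"] == pytest.approx(ok["auc"].mean())
        assert report.summary["sd_sensitivity"] == pytest.approx(
            np.std(ok["sensitivity"].to_numpy(), ddof=1)
        )


class TestSubgroups:
    def test_partition_and_unknown_key(self, rng):
        metas = [
            {"bed_type": "bassinet", "distance_mm": 300.0},
            {"bed_type": "covered isolette", "distance_mm": 600.0},
        ]
        clips = [
            synthetic_clip(s, c, rng, meta_kwargs=metas[i % 2])
            for i, (s, c) in enumerate([("A", 1), ("A", 2), ("B", 1), ("B", 2)])
        ]
        report = loocv(clips, small_forest(), seed=0)
        table = subgroup_auc(report, "bed_type")
        assert len(table) == 4  # every clip in exactly one group
        assert set(table["group"]) == {"bassinet", "covered isolette"}
        with pytest.raises(ValueError, match="unknown"):
            subgroup_auc(report, "favourite_color")
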