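"""Decoding engine: concatenation, voxel selection, CV, permutation inference."""

import numpy as np
import pytest

from flowmvpa import mvpa, pipeline, synth
from flowmvpa.mvpa import (
    MultiVoxelSamples,
    SVMConfig,
    accuracy_vs_voxel_count,
    concatenate_subjects,
    derive_binary_from_confusion,
    identity_labels,
    loro_cv_classify,
    motion_labels,
    pairwise_accuracy_difference_test,
    permutation_test,
    select_voxels,
    size_labels,
    stereo_labels,
)


def make_samples(
    n_runs=8, per_class=2, n_classes=3, n_vox=12, sep=0.0, seed=0, subject="sub-01"
):
    """Synthetic sample grid with optional class separation ``sep``."""
    rng = np.random.default_rng(seed)
    n_per_run = per_class * n_classes
    runs = np.repeat(np.arange(1, n_runs + 1), n_per_run)
    labels = np.tile(np.repeat(np.arange(n_classes), per_class), n_runs)
    centers = rng.normal(size=(n_classes, n_vox))
    X = rng.normal(size=(len(runs), n_vox)) + sep * centers[labels]
    occ = np.tile(np.tile(np.arange(per_class), n_classes), n_runs)
    return MultiVoxelSamples(
        X=X, run=runs, condition_index=labels,
        voxel_subject=np.repeat(subject, n_vox), roi_label="test", occurrence=occ,
    )


class TestConcatenation:
    def test_voxel_dimension_grows_sample_dimension_fixed(self):
        subs = [make_samples(n_vox=20, seed=i, subject=f"sub-{i:02d}") for i in range(9)]
        pooled = concatenate_subjects(subs)
        assert pooled.n_voxels == 180
        assert pooled.n_samples == subs[0].n_samples
        assert np.array_equal(pooled.condition_index, subs[0].condition_index)

    def test_single_subject_identity(self):
        s = make_samples()
        pooled = concatenate_subjects([s])
        assert np.array_equal(pooled.X, s.X)

    def test_misaligned_grid_names_offender(self):
        a = make_samples(subject="sub-01")
        b = make_samples(n_runs=7, subject="sub-02")
        with pytest.raises(ValueError, match="sub-02"):
            concatenate_subjects([a, b])


class TestVoxelSelection:
    def test_top_k_by_mean_activation(self):
        s = make_samples(n_vox=4, seed=1)
        s.X[:, 2] += 5.0
        s.X[:, 0] += 3.0
        top = select_voxels(s, 2)
        assert np.allclose(top.X[:, 0], s.X[:, 2])
        assert np.allclose(top.X[:, 1], s.X[:, 0])

    def test_keep_all_orders_by_rank(self):
        s = make_samples(n_vox=5, seed=2)
        allv = select_voxels(s, 5)
        means = allv.X.mean(axis=0)
        assert np.all(np.diff(means) <= 1e-12)

    def test_tie_breaks_on_stable_index(self):
        s = make_samples(n_vox=3, seed=3)
        s.X[:] = 1.0
        top = select_voxels(s, 2)
        assert np.array_equal(top.voxel_subject, s.voxel_subject[:2])

    def test_bounds_checked(self):
        s = make_samples(n_vox=3)
        with pytest.raises(ValueError):
            select_voxels(s, 4)
        with pytest.raises(ValueError):
            select_voxels(s, 0)

    def test_112_from_pooled_roi(self, default_study):
        assert default_study["samples"]["CSv"].n_voxels == 112


class TestLabelMaps:
    def test_class_counts(self):
        assert len(motion_labels().class_names) == 3
        assert len(size_labels().class_names) == 4
        assert len(stereo_labels().class_names) == 2
        assert len(motion_labels(("coherent", "random")).mapping) == 16
        assert len(size_labels("coherent").mapping) == 8

    def test_unknown_levels_rejected(self):
        with pytest.raises(ValueError):
            motion_labels(("coherent", "sideways"))
        with pytest.raises(ValueError):
            size_labels("sideways")


class TestLoroCv:
    def test_separable_data_classified_perfectly(self):
        s = make_samples(sep=10.0, seed=4)
        res = loro_cv_classify(s, identity_labels(3))
        assert res.accuracy == 1.0
        assert np.allclose(np.diag(res.confusion), 100.0)

    def test_eight_fold_accuracies(self):
        res = loro_cv_classify(make_samples(seed=5), identity_labels(3))
        assert len(res.fold_accuracies) == 8
        assert res.accuracy == pytest.approx(res.fold_accuracies.mean())

    def test_confusion_rows_sum_to_100(self):
        res = loro_cv_classify(make_samples(seed=6), identity_labels(3))
        assert np.allclose(res.confusion.sum(axis=1), 100.0)
        # mass conservation: row counts equal per-class test-sample counts
        assert np.allclose(res.confusion_counts.sum(axis=1), 8 * 2)
        assert res.confusion_counts.sum() == 48

    def test_pure_noise_near_chance(self):
        accs = [
            loro_cv_classify(make_samples(seed=s), identity_labels(3)).accuracy
            for s in range(12)
        ]
        assert abs(np.mean(accs) - 1 / 3) < 0.05

    def test_missing_training_class_rejected(self):
        s = make_samples()
        s.condition_index[(s.run != 1) & (s.condition_index == 2)] = 1
        with pytest.raises(ValueError, match="absent"):
            loro_cv_classify(s, identity_labels(3))

    def test_engines_agree(self):
        """DCD solver predictions match the libsvm reference implementation."""
        diffs = []
        for seed, sep in ((0, 0.0), (1, 0.4), (2, 1.5)):
            s = make_samples(n_vox=24, sep=sep, seed=seed)
            a = loro_cv_classify(s, identity_labels(3), SVMConfig(engine="dcd"))
            b = loro_cv_classify(s, identity_labels(3), SVMConfig(engine="libsvm"))
            diffs.append(abs(a.accuracy - b.accuracy))
        assert max(diffs) < 0.05

    def test_standardized_variant_runs(self):
        s = make_samples(sep=2.0, seed=7)
        res = loro_cv_classify(s, identity_labels(3), SVMConfig(standardize=True))
        assert res.accuracy > 0.8


class TestBinaryFromConfusion:
    def test_identity_confusion(self):
        conf = np.eye(3) * 100
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert derive_binary_from_confusion(conf, ["a", "b", "c"], pair) == 1.0

    def test_uniform_confusion_is_chance(self):
        conf = np.full((3, 3), 100 / 3)
        assert derive_binary_from_confusion(conf, ["a", "b", "c"], ("a", "b")) == 0.5

    def test_hand_computed_renormalization(self):
        conf = np.array([[70, 20, 10], [25, 50, 25], [10, 10, 80]], float)
        acc = derive_binary_from_confusion(conf, ["coh", "ran", "sta"], ("coh", "ran"))
        assert acc == pytest.approx((70 / 90 + 50 / 75) / 2, abs=1e-12)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            derive_binary_from_confusion(np.eye(3), ["a", "b", "c"], ("a", "x"))


class TestPermutationTest:
    def test_below_median_gives_large_p(self):
        s = make_samples(seed=8)
        res = loro_cv_classify(s, identity_labels(3))
        res.accuracy = 0.0  # force an observed value below every null
        out = permutation_test(s, identity_labels(3), n_perm=120, seed=0, observed=res)
        assert out.p_value > 0.5

    def test_separable_data_minimal_p(self):
        s = make_samples(sep=10.0, seed=9)
        out = permutation_test(s, identity_labels(3), n_perm=999, seed=1)
        assert out.p_value == pytest.approx(1 / 1000)
        assert out.significant

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(make_samples(), identity_labels(3), n_perm=50)

    def test_within_run_permutation_preserves_label_multiset(self):
        s = make_samples(seed=10)
        rng = np.random.default_rng(0)
        yp = mvpa._permute_within_runs(s.condition_index, s.run, rng)
        for r in np.unique(s.run):
            assert sorted(yp[s.run == r]) == sorted(s.condition_index[s.run == r])
        assert not np.array_equal(yp, s.condition_index)

    def test_null_distribution_centers_on_chance(self):
        s = make_samples(seed=11)
        out = permutation_test(s, identity_labels(3), n_perm=150, seed=2)
        assert abs(out.null_accuracies.mean() - 1 / 3) < 0.03


class TestPairwiseDifference:
    def test_self_comparison_is_null(self):
        s = make_samples(sep=1.0, seed=12)
        out = pairwise_accuracy_difference_test(
            s, s, identity_labels(3), n_perm=150, seed=0
        )
        assert out.observed_difference == 0.0
        assert out.p_value > 0.4

    def test_constructed_extreme_case(self):
        strong = make_samples(sep=10.0, seed=13, n_vox=24)
        noise = make_samples(sep=0.0, seed=14, n_vox=24, subject="sub-01")
        out = pairwise_accuracy_difference_test(
            strong, noise, identity_labels(3), n_perm=999, seed=1
        )
        assert out.p_value <= 0.01

    def test_swapping_negates_difference(self):
        a = make_samples(sep=2.0, seed=15)
        b = make_samples(sep=0.5, seed=16)
        ab = pairwise_accuracy_difference_test(a, b, identity_labels(3), n_perm=120, seed=2)
        ba = pairwise_accuracy_difference_test(b, a, identity_labels(3), n_perm=120, seed=2)
        assert ab.observed_difference == pytest.approx(-ba.observed_difference)

    def test_misaligned_grids_rejected(self):
        a = make_samples(seed=17)
        b = make_samples(n_runs=7, seed=18)
        with pytest.raises(ValueError, match="aligned"):
            pairwise_accuracy_difference_test(a, b, identity_labels(3), n_perm=120)


class TestVoxelCountCurve:
    def test_full_count_reproduces_headline(self):
        s = make_samples(sep=3.0, seed=19, n_vox=16)
        curve = accuracy_vs_voxel_count(s, identity_labels(3), [4, 8, 16])
        headline = loro_cv_classify(select_voxels(s, 16), identity_labels(3)).accuracy
        assert curve.accuracy.iloc[-1] == pytest.approx(headline)

    def test_strong_signal_curve_saturates(self):
        s = make_samples(sep=6.0, seed=20, n_vox=32)
        curve = accuracy_vs_voxel_count(s, identity_labels(3), [2, 8, 16, 24, 32])
        assert abs(curve.accuracy.iloc[-1] - curve.accuracy.iloc[-2]) < 0.05
        assert curve.accuracy.iloc[0] <= curve.accuracy.max()
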