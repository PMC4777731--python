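"""Cross-subject multi-voxel pattern analysis with permutation inference.

Trial-wise GLM betas form a sample x voxel matrix; voxels are concatenated
across subjects on the shared (run, condition, occurrence) sample grid,
ranked by mean activation and truncated to a fixed count (112 by default,
the equalized-ROI convention). A linear support vector machine (C = 1,
one-vs-one) is evaluated with leave-one-run-out cross-validation; null
distributions come from re-running the full cross-validation under labels
permuted independently within each run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._svm import ovo_svm_predict
from . import design as dz
from .design import conditions
from .glm import GLMResult, to_percent_signal_change

N_SELECTED_VOXELS = 112


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    standardize: bool = False  # per-voxel z-scoring fit on training folds
    engine: str = "dcd"  # 'dcd' (fast dual coordinate descent) or 'libsvm'


@dataclass
class MultiVoxelSamples:
    """Sample x voxel matrix of trial-wise betas with run/condition labels."""

    X: np.ndarray  # (n_samples, n_voxels)
    run: np.ndarray  # (n_samples,)
    condition_index: np.ndarray  # (n_samples,)
    voxel_subject: np.ndarray  # (n_voxels,) subject of origin per column
    roi_label: str = ""
    occurrence: np.ndarray | None = None  # (n_samples,) trial slot within run

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.run = np.asarray(self.run)
        self.condition_index = np.asarray(self.condition_index)
        if self.X.shape[0] != len(self.run) or len(self.run) != len(
            self.condition_index
        ):
            raise ValueError("sample dimensions are inconsistent")
        if self.X.shape[1] != len(self.voxel_subject):
            raise ValueError("voxel dimensions are inconsistent")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def grid_key(self) -> np.ndarray:
        occ = (
            self.occurrence
            if self.occurrence is not None
            else np.zeros(self.n_samples, int)
        )
        return np.stack([self.run, self.condition_index, occ], axis=1)


def build_subject_samples(
    trial_results: Sequence[GLMResult],
    voxel_columns: np.ndarray,
    baseline: np.ndarray,
    subject_id: str,
    roi_label: str = "",
) -> MultiVoxelSamples:
    """Assemble one subject's trial-beta samples (percent signal change).

    One GLM result per run, in run order; samples are sorted to the
    canonical (run, condition, occurrence) grid so subjects align.
    """
    X_rows, runs, conds, occs = [], [], [], []
    for res in trial_results:
        psc = to_percent_signal_change(res, baseline)[:, voxel_columns]
        info = res.design.regressor_info
        order = np.lexsort(
            (info["occurrence"].to_numpy(), info["condition_index"].to_numpy())
        )
        X_rows.append(psc[order])
        runs.append(np.repeat(info["run"].iloc[0], len(order)))
        conds.append(info["condition_index"].to_numpy()[order])
        occs.append(info["occurrence"].to_numpy()[order])
    return MultiVoxelSamples(
        X=np.vstack(X_rows),
        run=np.concatenate(runs),
        condition_index=np.concatenate(conds),
        voxel_subject=np.repeat(subject_id, len(voxel_columns)),
        roi_label=roi_label,
        occurrence=np.concatenate(occs),
    )


def concatenate_subjects(
    per_subject: Sequence[MultiVoxelSamples],
) -> MultiVoxelSamples:
    """Concatenate voxels across subjects on the shared sample grid."""
    if len(per_subject) == 0:
        raise ValueError("no subjects to concatenate")
    ref = per_subject[0]
    ref_key = ref.grid_key()
    offending = [
        str(s.voxel_subject[0])
        for s in per_subject[1:]
        if s.grid_key().shape != ref_key.shape
        or not np.array_equal(s.grid_key(), ref_key)
    ]
    if offending:
        raise ValueError(
            "sample grids are not aligned across subjects: " + ", ".join(offending)
        )
    return MultiVoxelSamples(
        X=np.hstack([s.X for s in per_subject]),
        run=ref.run.copy(),
        condition_index=ref.condition_index.copy(),
        voxel_subject=np.concatenate([s.voxel_subject for s in per_subject]),
        roi_label=ref.roi_label,
        occurrence=None if ref.occurrence is None else ref.occurrence.copy(),
    )


def select_voxels(samples: MultiVoxelSamples, k: int = N_SELECTED_VOXELS) -> MultiVoxelSamples:
    """Keep the top-k voxels by mean activation across all samples.

    Ranking is by descending mean beta; ties break on the stable original
    voxel index.
    """
    if k > samples.n_voxels:
        raise ValueError(
            f"requested {k} voxels but only {samples.n_voxels} are available"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    means = samples.X.mean(axis=0)
    order = np.lexsort((np.arange(samples.n_voxels), -means))[:k]
    return MultiVoxelSamples(
        X=samples.X[:, order],
        run=samples.run.copy(),
        condition_index=samples.condition_index.copy(),
        voxel_subject=samples.voxel_subject[order],
        roi_label=samples.roi_label,
        occurrence=None if samples.occurrence is None else samples.occurrence.copy(),
    )


# ---------------------------------------------------------------------------
# label maps


@dataclass(frozen=True)
class LabelMap:
    """Maps condition indices to class labels; None drops the sample."""

    name: str
    mapping: dict[int, int]
    class_names: tuple[str, ...]

    def apply(self, condition_index: np.ndarray) -> np.ndarray:
        return np.array([self.mapping.get(int(c), -1) for c in condition_index])


def _factor_of(ci: int, factor: str):
    cond = conditions()[ci]
    return getattr(cond, factor)


def motion_labels(restrict_pair: tuple[str, str] | None = None) -> LabelMap:
    """3-class motion decoding, or a binary motion pair."""
    if restrict_pair is None:
        levels = list(dz.MOTIONS)
        name = "motion"
    else:
        for m in restrict_pair:
            if m not in dz.MOTIONS:
                raise ValueError(f"unknown motion level {m!r}")
        levels = list(restrict_pair)
        name = f"motion:{restrict_pair[0]}-vs-{restrict_pair[1]}"
    mapping = {
        ci: levels.index(_factor_of(ci, "motion"))
        for ci in range(len(conditions()))
        if _factor_of(ci, "motion") in levels
    }
    return LabelMap(name, mapping, tuple(levels))


def size_labels(restrict_motion: str | None = None) -> LabelMap:
    """4-class stimulus-size decoding, optionally within one motion pattern."""
    if restrict_motion is not None and restrict_motion not in dz.MOTIONS:
        raise ValueError(f"unknown motion level {restrict_motion!r}")
    mapping = {}
    for ci in range(len(conditions())):
        if restrict_motion is not None and _factor_of(ci, "motion") != restrict_motion:
            continue
        mapping[ci] = dz.SIZES_DEG.index(_factor_of(ci, "size_deg"))
    name = "size" if restrict_motion is None else f"size|{restrict_motion}"
    return LabelMap(name, mapping, tuple(str(s) for s in dz.SIZES_DEG))


def stereo_labels() -> LabelMap:
    mapping = {
        ci: dz.STEREO.index(_factor_of(ci, "stereo"))
        for ci in range(len(conditions()))
    }
    return LabelMap("stereo", mapping, tuple(dz.STEREO))


def identity_labels(n_classes: int) -> LabelMap:
    """Labels equal to the stored condition index (synthetic sample sets)."""
    return LabelMap(
        "identity",
        {c: c for c in range(n_classes)},
        tuple(str(c) for c in range(n_classes)),
    )


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationResult:
    problem: str
    roi_label: str
    class_names: tuple[str, ...]
    fold_accuracies: np.ndarray  # (n_runs,)
    accuracy: float
    confusion: np.ndarray  # row-normalized percents (true x predicted)
    confusion_counts: np.ndarray
    n_voxels: int
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    null_95th: float | None = None

    @property
    def significant(self) -> bool:
        """Paper convention: observed accuracy above the null 95th percentile."""
        if self.null_95th is None:
            raise ValueError("run a permutation test first")
        return self.accuracy > self.null_95th


def _restrict(samples: MultiVoxelSamples, label_map: LabelMap):
    y = label_map.apply(samples.condition_index)
    keep = y >= 0
    return samples.X[keep], y[keep], samples.run[keep]


def _cv_accuracy_gram(
    G: np.ndarray, y: np.ndarray, runs: np.ndarray, C: float,
    n_classes: int, collect_confusion: bool = False, engine: str = "dcd",
):
    """Leave-one-run-out CV on a precomputed linear Gram matrix."""
    uruns = np.unique(runs)
    fold_acc = np.empty(len(uruns))
    confusion = np.zeros((n_classes, n_classes))
    for i, r in enumerate(uruns):
        te = runs == r
        tr = ~te
        if len(np.unique(y[tr])) < n_classes:
            raise ValueError(f"a class is absent from the training fold for run {r}")
        if engine == "dcd":
            pred = ovo_svm_predict(
                G[np.ix_(tr, tr)], G[np.ix_(te, tr)], y[tr], n_classes, C
            )
        else:
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(G[np.ix_(tr, tr)], y[tr])
            pred = clf.predict(G[np.ix_(te, tr)])
        fold_acc[i] = float(np.mean(pred == y[te]))
        if collect_confusion:
            np.add.at(confusion, (y[te], pred), 1)
    return fold_acc, confusion


def _cv_accuracy_standardized(
    X: np.ndarray, y: np.ndarray, runs: np.ndarray, C: float,
    n_classes: int, collect_confusion: bool = False,
):
    uruns = np.unique(runs)
    fold_acc = np.empty(len(uruns))
    confusion = np.zeros((n_classes, n_classes))
    for i, r in enumerate(uruns):
        te = runs == r
        tr = ~te
        if len(np.unique(y[tr])) < n_classes:
            raise ValueError(f"a class is absent from the training fold for run {r}")
        mu, sd = X[tr].mean(0), X[tr].std(0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mu) / sd, y[tr])
        pred = clf.predict((X[te] - mu) / sd)
        fold_acc[i] = float(np.mean(pred == y[te]))
        if collect_confusion:
            np.add.at(confusion, (y[te], pred), 1)
    return fold_acc, confusion


def loro_cv_classify(
    samples: MultiVoxelSamples,
    label_map: LabelMap,
    svm_config: SVMConfig = SVMConfig(),
) -> ClassificationResult:
    """Leave-one-run-out linear-SVM classification of one problem."""
    X, y, runs = _restrict(samples, label_map)
    if len(np.unique(runs)) < 2:
        raise ValueError("at least two runs are required for cross-validation")
    n_classes = len(label_map.class_names)
    if svm_config.standardize:
        fold_acc, counts = _cv_accuracy_standardized(
            X, y, runs, svm_config.C, n_classes, collect_confusion=True
        )
    else:
        G = X @ X.T
        fold_acc, counts = _cv_accuracy_gram(
            G, y, runs, svm_config.C, n_classes, collect_confusion=True,
            engine=svm_config.engine,
        )
    row_sums = counts.sum(axis=1, keepdims=True)
    confusion = 100.0 * counts / np.maximum(row_sums, 1)
    return ClassificationResult(
        problem=label_map.name,
        roi_label=samples.roi_label,
        class_names=label_map.class_names,
        fold_accuracies=fold_acc,
        accuracy=float(fold_acc.mean()),
        confusion=confusion,
        confusion_counts=counts,
        n_voxels=samples.n_voxels,
    )


def derive_binary_from_confusion(
    confusion: np.ndarray,
    class_names: Sequence[str],
    pair: tuple[str, str],
) -> float:
    """Binary accuracy read off a multi-class confusion matrix.

    For the pair's two rows, predictions of third classes are excluded and
    each row renormalized; the accuracy is the mean of the two resulting
    per-class correct fractions.
    """
    names = list(class_names)
    for p in pair:
        if p not in names:
            raise ValueError(f"class {p!r} not in confusion labels {names}")
    i, j = names.index(pair[0]), names.index(pair[1])
    acc = 0.0
    for a, b in ((i, j), (j, i)):
        denom = confusion[a, a] + confusion[a, b]
        if denom == 0:
            raise ValueError("empty confusion rows for the requested pair")
        acc += confusion[a, a] / denom
    return acc / 2.0


def _permute_within_runs(
    y: np.ndarray, runs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for r in np.unique(runs):
        idx = np.flatnonzero(runs == r)
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def permutation_test(
    samples: MultiVoxelSamples,
    label_map: LabelMap,
    n_perm: int = 1000,
    seed: int = 0,
    svm_config: SVMConfig = SVMConfig(),
    observed: ClassificationResult | None = None,
) -> ClassificationResult:
    """Within-run label-permutation test of the decoding accuracy.

    Each replicate permutes sample labels independently within every run
    and reruns the full leave-one-run-out cross-validation. The p value
    uses the add-one estimator p = (1 + #{null >= observed}) / (1 + n);
    the null 95th percentile implements the "above the 95% percentile"
    significance criterion.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable null tail")
    if observed is None:
        observed = loro_cv_classify(samples, label_map, svm_config)
    X, y, runs = _restrict(samples, label_map)
    n_classes = len(label_map.class_names)
    rng = np.random.default_rng(seed)
    G = None if svm_config.standardize else X @ X.T
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = _permute_within_runs(y, runs, rng)
        # the permutation preserves each run's label multiset by construction
        if G is not None:
            fold_acc, _ = _cv_accuracy_gram(
                G, yp, runs, svm_config.C, n_classes, engine=svm_config.engine
            )
        else:
            fold_acc, _ = _cv_accuracy_standardized(
                X, yp, runs, svm_config.C, n_classes
            )
        null[b] = fold_acc.mean()
    observed.null_accuracies = null
    observed.p_value = float((1 + np.sum(null >= observed.accuracy)) / (1 + n_perm))
    observed.null_95th = float(np.quantile(null, 0.95))
    return observed


@dataclass
class PairwiseAccuracyTest:
    label_a: str
    label_b: str
    observed_difference: float
    null_differences: np.ndarray
    p_value: float
    p_holm: float | None = None


def pairwise_accuracy_difference_test(
    samples_a: MultiVoxelSamples,
    samples_b: MultiVoxelSamples,
    label_map_a: LabelMap,
    label_map_b: LabelMap | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    svm_config: SVMConfig = SVMConfig(),
) -> PairwiseAccuracyTest:
    """One-sided permutation test of an accuracy difference (A minus B).

    A single within-run label permutation per replicate is applied to both
    problems (shared draws), making the null a paired difference. The two
    sample sets must share the (run, condition, occurrence) grid.
    """
    label_map_b = label_map_b or label_map_a
    key_a, key_b = samples_a.grid_key(), samples_b.grid_key()
    same_problem = label_map_a.name == label_map_b.name
    if same_problem and (
        key_a.shape != key_b.shape or not np.array_equal(key_a, key_b)
    ):
        raise ValueError("sample grids of the two ROIs are not aligned")

    Xa, ya, runs_a = _restrict(samples_a, label_map_a)
    Xb, yb, runs_b = _restrict(samples_b, label_map_b)
    na, nb = len(label_map_a.class_names), len(label_map_b.class_names)
    Ga, Gb = Xa @ Xa.T, Xb @ Xb.T

    eng = svm_config.engine
    acc_a = _cv_accuracy_gram(Ga, ya, runs_a, svm_config.C, na, engine=eng)[0].mean()
    acc_b = _cv_accuracy_gram(Gb, yb, runs_b, svm_config.C, nb, engine=eng)[0].mean()
    observed = float(acc_a - acc_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        if same_problem:
            # one shared draw: permute positions within run once, apply to both
            perm = _permutation_indices(runs_a, rng)
            ya_p, yb_p = ya[perm], yb[perm]
        else:
            ya_p = _permute_within_runs(ya, runs_a, rng)
            yb_p = _permute_within_runs(yb, runs_b, rng)
        pa = _cv_accuracy_gram(Ga, ya_p, runs_a, svm_config.C, na, engine=eng)[0].mean()
        pb = _cv_accuracy_gram(Gb, yb_p, runs_b, svm_config.C, nb, engine=eng)[0].mean()
        null[b] = pa - pb
    p = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return PairwiseAccuracyTest(
        label_a=f"{samples_a.roi_label}:{label_map_a.name}",
        label_b=f"{samples_b.roi_label}:{label_map_b.name}",
        observed_difference=observed,
        null_differences=null,
        p_value=p,
    )


def _permutation_indices(runs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.arange(len(runs))
    for r in np.unique(runs):
        pos = np.flatnonzero(runs == r)
        idx[pos] = pos[rng.permutation(len(pos))]
    return idx


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="holm")[1]


def accuracy_vs_voxel_count(
    samples: MultiVoxelSamples,
    label_map: LabelMap,
    k_grid: Sequence[int],
    svm_config: SVMConfig = SVMConfig(),
) -> pd.DataFrame:
    """Decoding accuracy as a function of the selected voxel count.

    Every k draws down the same activation ranking.
    """
    rows = []
    for k in k_grid:
        res = loro_cv_classify(select_voxels(samples, k), label_map, svm_config)
        rows.append({"n_voxels": int(k), "accuracy": res.accuracy})
    return pd.DataFrame(rows)
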