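"""Neuro-perceptual correlation between ROI activation and vection strength.

ROI condition responses are z-scored within subject, collected across
subjects and correlated (Pearson) with magnitude-estimation ratings of
perceived self-motion. Inference is available in two modes: pooled
(correlation over all subject x condition points, r-to-t conversion) and
per-subject (Fisher-z transformed subject correlations, one-sample t),
the latter being the default because it respects the subject as the unit
of inference. ROI pairs are compared with the Meng-Rosenthal-Rubin Z test
for dependent correlations sharing one variable (the ratings), Bonferroni
corrected over the tested family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import design as dz
from .design import conditions


def zscore_within_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each subject's condition vector to mean 0, SD 1."""
    values = np.asarray(table, float)
    sd = values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = table.index[np.flatnonzero(sd == 0)].tolist()
        raise ValueError(f"constant response vector for subject(s) {bad}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=table.index, columns=table.columns)


@dataclass
class CorrelationResult:
    roi_label: str
    mode: str  # 'pooled' | 'per_subject'
    r: float
    n: int
    t: float
    p: float
    degenerate: bool = False
    per_subject_r: np.ndarray | None = None


def _pooled_vectors(
    bold_table: pd.DataFrame,
    rating_table: pd.DataFrame,
    zscore_bold: bool = True,
    zscore_ratings: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    if not bold_table.index.equals(rating_table.index) or not bold_table.columns.equals(
        rating_table.columns
    ):
        raise ValueError("BOLD and rating tables must share the subject x condition grid")
    b = zscore_within_subject(bold_table) if zscore_bold else bold_table
    r = zscore_within_subject(rating_table) if zscore_ratings else rating_table
    return np.asarray(b, float).ravel(), np.asarray(r, float).ravel()


def r_to_t(r: float, n: int) -> float:
    """t = r * sqrt(n - 2) / sqrt(1 - r^2)."""
    if abs(r) >= 1.0:
        raise ValueError("|r| = 1: t statistic undefined")
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)


def neuro_perceptual_correlation(
    bold_table: pd.DataFrame,
    rating_table: pd.DataFrame,
    mode: str = "per_subject",
    roi_label: str = "",
    zscore_ratings: bool = False,
) -> CorrelationResult:
    """Pearson correlation between ROI responses and vection ratings.

    pooled: one r over all subject-condition points; t from the closed
    form r*sqrt(n-2)/sqrt(1-r^2), two-tailed p.
    per_subject: r per subject, Fisher-z transform, one-sample t across
    subjects (df = n_subjects - 1).
    """
    if mode not in ("pooled", "per_subject"):
        raise ValueError(f"unknown inference mode {mode!r}")
    x, y = _pooled_vectors(bold_table, rating_table, zscore_ratings=zscore_ratings)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    r_pooled = float(stats.pearsonr(x, y).statistic)

    if mode == "pooled":
        if abs(r_pooled) >= 1.0 - 1e-12:
            return CorrelationResult(roi_label, mode, r_pooled, n, np.inf, 0.0, True)
        t = float(r_to_t(r_pooled, n))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        return CorrelationResult(roi_label, mode, r_pooled, n, t, p)

    bz = zscore_within_subject(bold_table)
    rt = zscore_within_subject(rating_table) if zscore_ratings else rating_table
    per_r = np.array(
        [
            stats.pearsonr(bz.iloc[i], rt.iloc[i]).statistic
            for i in range(len(bz))
        ]
    )
    degenerate = bool(np.any(np.abs(per_r) >= 1.0 - 1e-12))
    z = np.arctanh(np.clip(per_r, -1 + 1e-12, 1 - 1e-12))
    t_stat, p = stats.ttest_1samp(z, 0.0)
    return CorrelationResult(
        roi_label,
        mode,
        float(np.tanh(z.mean())),
        n,
        float(t_stat),
        float(p),
        degenerate,
        per_subject_r=per_r,
    )


@dataclass
class RoiPairComparison:
    roi_a: str
    roi_b: str
    r_a: float
    r_b: float
    r_ab: float  # correlation between the two ROI response vectors
    Z: float
    p: float
    p_bonferroni: float
    n: int


def meng_z(r_a: float, r_b: float, r_ab: float, n: int) -> float:
    """Meng-Rosenthal-Rubin Z for two dependent correlations sharing a variable."""
    if n <= 3:
        raise ValueError("n must exceed 3")
    za, zb = np.arctanh(r_a), np.arctanh(r_b)
    r2bar = (r_a**2 + r_b**2) / 2.0
    f = min(1.0, (1.0 - r_ab) / (2.0 * (1.0 - r2bar)))
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    return float((za - zb) * np.sqrt((n - 3) / (2.0 * (1.0 - r_ab) * h)))


def compare_dependent_correlations(
    result_a: CorrelationResult,
    result_b: CorrelationResult,
    r_ab: float,
    n_comparisons: int = 15,
) -> RoiPairComparison:
    """Z test of two correlations with the rating variable in common.

    ``r_ab`` is the correlation between the two ROI response vectors
    themselves; Bonferroni adjustment defaults to the 15 pairs of 6 ROIs.
    """
    if result_a.n != result_b.n:
        raise ValueError("the two correlations must use the same points")
    n = result_a.n
    Z = meng_z(result_a.r, result_b.r, r_ab, n)
    p = float(2 * stats.norm.sf(abs(Z)))
    return RoiPairComparison(
        roi_a=result_a.roi_label,
        roi_b=result_b.roi_label,
        r_a=result_a.r,
        r_b=result_b.r,
        r_ab=r_ab,
        Z=Z,
        p=p,
        p_bonferroni=float(min(1.0, p * n_comparisons)),
        n=n,
    )


def correlation_analysis(
    bold_tables: dict[str, pd.DataFrame],
    rating_table: pd.DataFrame,
    mode: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI correlations plus all pairwise dependent-correlation tests.

    Pairwise comparisons always use the pooled vectors (they must share
    the rating points); the per-ROI table honours ``mode``.
    """
    rois = list(bold_tables.keys())
    per_roi = {
        roi: neuro_perceptual_correlation(tbl, rating_table, mode=mode, roi_label=roi)
        for roi, tbl in bold_tables.items()
    }
    pooled = {
        roi: neuro_perceptual_correlation(
            tbl, rating_table, mode="pooled", roi_label=roi
        )
        for roi, tbl in bold_tables.items()
    }
    roi_frame = pd.DataFrame(
        [
            {"roi": roi, "r": res.r, "t": res.t, "p": res.p, "n": res.n,
             "mode": res.mode}
            for roi, res in per_roi.items()
        ]
    )
    pairs = list(itertools.combinations(rois, 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(zscore_within_subject(bold_tables[a]), float).ravel()
        xb = np.asarray(zscore_within_subject(bold_tables[b]), float).ravel()
        r_ab = float(stats.pearsonr(xa, xb).statistic)
        cmp_ = compare_dependent_correlations(
            pooled[a], pooled[b], r_ab, n_comparisons=len(pairs)
        )
        rows.append(
            {
                "roi_a": a, "roi_b": b, "r_a": cmp_.r_a, "r_b": cmp_.r_b,
                "r_ab": r_ab, "Z": cmp_.Z, "p": cmp_.p,
                "p_bonferroni": cmp_.p_bonferroni,
            }
        )
    return roi_frame, pd.DataFrame(rows)


def size_stratified_correlation(
    bold_table: pd.DataFrame,
    rating_table: pd.DataFrame,
    size_level: int,
    mode: str = "pooled",
    roi_label: str = "",
) -> CorrelationResult:
    """Correlation restricted to one stimulus size's 6 cells per subject.

    BOLD z-scoring still uses the full 24-condition profile (the
    stratification selects points, not the normalization).
    """
    if size_level not in dz.SIZES_DEG:
        raise ValueError(f"unknown size level {size_level!r}")
    cols = [i for i, c in enumerate(conditions()) if c.size_deg == size_level]
    if len(cols) < 2:
        raise ValueError("a stratum needs at least 2 conditions")
    bz = zscore_within_subject(bold_table)
    x = np.asarray(bz.iloc[:, cols], float).ravel()
    y = np.asarray(rating_table.iloc[:, cols], float).ravel()
    n = len(x)
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:
        return CorrelationResult(roi_label, "pooled", r, n, np.inf, 0.0, True)
    t = float(r_to_t(r, n))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(roi_label, "pooled", r, n, t, p)
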