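"""ROI-averaged condition responses and fully-within repeated-measures ANOVA.

The three-way (motion x size x stereo) repeated-measures ANOVA is computed
by projecting each subject's 24 condition means onto orthonormal contrast
sets (Kronecker products of per-factor Helmert contrasts and mean
vectors). For each effect this yields the classical univariate F test,
the Greenhouse-Geisser epsilon from the contrast covariance, and
Mauchly's sphericity test, whose outcome at alpha = 0.05 gates whether
the corrected degrees of freedom are used — mirroring the convention of
applying the correction only when the deviation from sphericity is
significant. The same machinery serves BOLD percent-signal-change tables
and vection-rating tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import design as dz
from .design import conditions
from .glm import GLMResult, to_percent_signal_change

FACTOR_NAMES = ("motion", "size", "stereo")
FACTOR_LEVELS = (len(dz.MOTIONS), len(dz.SIZES_DEG), len(dz.STEREO))


def roi_condition_means(
    condition_results: dict[str, list],
    roi_columns: dict[str, np.ndarray],
    baselines: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Subject x condition table of ROI-mean percent signal change.

    ``condition_results`` maps subject id to a list of condition-wise
    GLMResults (one per run); betas are scaled to percent signal change,
    then averaged over runs and over the ROI's voxels.
    """
    rows = {}
    for subject, results in condition_results.items():
        if len(results) == 0:
            raise ValueError(f"subject {subject} has no fitted runs")
        cols = roi_columns[subject]
        per_run = []
        for res in results:
            psc = to_percent_signal_change(res, baselines[subject])
            cond_idx = res.design.regressor_info["condition_index"].to_numpy()
            order = np.argsort(cond_idx)
            per_run.append(psc[order][:, cols].mean(axis=1))
        rows[subject] = np.mean(per_run, axis=0)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject"
    table.columns = pd.RangeIndex(len(conditions()), name="condition_index")
    return table


def table_factors() -> pd.DataFrame:
    """Factor levels per condition index of a 24-column response table."""
    recs = [
        {
            "condition_index": i,
            "motion": c.motion,
            "size": c.size_deg,
            "stereo": c.stereo,
        }
        for i, c in enumerate(conditions())
    ]
    return pd.DataFrame(recs).set_index("condition_index")


# ---------------------------------------------------------------------------
# three-way repeated-measures ANOVA


def _helmert(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) contrast basis orthogonal to the mean vector."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


@dataclass
class EffectResult:
    effect: str
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    epsilon: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    mauchly_W: float | None
    mauchly_p: float | None
    sphericity_violated: bool
    p: float  # the reported p (GG-corrected iff Mauchly rejects)


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()]).set_index(
            "effect"
        )


def _mauchly(T: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on contrast scores T (n_subjects, q)."""
    n, q = T.shape
    S = np.cov(T, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 1e-12, None)
    W = float(np.prod(eig) / (eig.mean() ** q))
    d = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * d * np.log(max(W, 1e-300))
    df = q * (q + 1) / 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return W, p


def rm_anova_3way(
    table: pd.DataFrame,
    sphericity_alpha: float = 0.05,
) -> AnovaResult:
    """Three-way fully-within ANOVA of a subject x 24-condition table.

    Effects: 3 main effects, 3 two-way interactions, the three-way
    interaction. Error terms are the corresponding subject x effect
    interactions. Greenhouse-Geisser corrected p values are reported when
    Mauchly's test rejects sphericity at ``sphericity_alpha``.
    """
    Y = np.asarray(table, float)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("at least 3 subjects are required")
    if Y.shape[1] != int(np.prod(FACTOR_LEVELS)):
        raise ValueError("table must have one column per condition (24)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("response table contains non-finite values")

    # columns are ordered motion fastest, then size, then stereo; a cube
    # indexed [subject, stereo, size, motion]
    cube = Y.reshape(n, FACTOR_LEVELS[2], FACTOR_LEVELS[1], FACTOR_LEVELS[0])
    # reorder to [subject, motion, size, stereo]
    cube = np.transpose(cube, (0, 3, 2, 1))

    bases = {
        name: _helmert(k) for name, k in zip(FACTOR_NAMES, FACTOR_LEVELS)
    }
    means = {
        name: np.full((k, 1), 1.0 / np.sqrt(k))
        for name, k in zip(FACTOR_NAMES, FACTOR_LEVELS)
    }

    effects: dict[str, EffectResult] = {}
    flat = cube.reshape(n, -1)  # row-major over (motion, size, stereo)
    for r in (1, 2, 3):
        for combo in itertools.combinations(range(3), r):
            name = " x ".join(FACTOR_NAMES[i] for i in combo)
            mats = [
                bases[FACTOR_NAMES[i]] if i in combo else means[FACTOR_NAMES[i]]
                for i in range(3)
            ]
            M = np.kron(np.kron(mats[0], mats[1]), mats[2])  # (24, q)
            T = flat @ M  # (n, q) contrast scores
            q = T.shape[1]
            tbar = T.mean(axis=0)
            ss_eff = n * float(tbar @ tbar)
            resid = T - tbar
            ss_err = float((resid**2).sum())
            df1, df2 = q, q * (n - 1)
            tol = 1e-12 * n * (float(np.abs(flat).max()) ** 2 + 1.0)
            if ss_err <= tol:  # degenerate: no within-subject error variance
                F = 0.0 if ss_eff <= tol else np.inf
                p_unc = 1.0 if ss_eff <= tol else 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                p_unc = float(stats.f.sf(F, df1, df2))

            if q > 1:
                S = np.cov(T, rowvar=False, ddof=1)
                tr = np.trace(S)
                eps = float(tr**2 / (q * np.trace(S @ S))) if tr > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / q, 1.0))
                W, mp = _mauchly(T)
                violated = mp < sphericity_alpha
            else:
                eps, W, mp, violated = 1.0, None, None, False
            df1_gg, df2_gg = eps * df1, eps * df2
            p_gg = float(stats.f.sf(F, df1_gg, df2_gg))
            effects[name] = EffectResult(
                effect=name,
                F=float(F),
                df1=df1,
                df2=df2,
                p_uncorrected=p_unc,
                epsilon=eps,
                df1_gg=df1_gg,
                df2_gg=df2_gg,
                p_gg=p_gg,
                mauchly_W=W,
                mauchly_p=mp,
                sphericity_violated=bool(violated),
                p=p_gg if violated else p_unc,
            )
    return AnovaResult(effects=effects, n_subjects=n)


# ---------------------------------------------------------------------------
# post-hoc paired tests


@dataclass
class PairedTest:
    level_a: str
    level_b: str
    mean_difference: float
    t: float
    p: float
    p_holm: float


def posthoc_paired_t_holm(
    table: pd.DataFrame, factor: str = "motion"
) -> list[PairedTest]:
    """Holm-adjusted paired t-tests between the levels of one factor.

    Subject-wise means are collapsed over the remaining factors before
    testing; all level pairs are tested.
    """
    if table.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")
    fac = table_factors()
    if factor not in fac.columns:
        raise ValueError(f"unknown factor {factor!r}")
    levels = list(dict.fromkeys(fac[factor]))
    collapsed = {
        lv: table.loc[:, fac.index[fac[factor] == lv]].mean(axis=1) for lv in levels
    }
    pairs = list(itertools.combinations(levels, 2))
    raw = []
    for a, b in pairs:
        diff = collapsed[a] - collapsed[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = 0.0, 1.0
            if not np.allclose(diff, 0.0):  # constant nonzero difference
                t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_rel(collapsed[a], collapsed[b])
        raw.append((a, b, float(diff.mean()), float(t), float(p)))
    adj = multipletests([r[4] for r in raw], method="holm")[1]
    return [
        PairedTest(str(a), str(b), d, t, p, float(ph))
        for (a, b, d, t, p), ph in zip(raw, adj)
    ]


def effects_table(per_roi: dict[str, AnovaResult]) -> pd.DataFrame:
    """Tidy effect x ROI table of reported p values."""
    rows = []
    for roi, res in per_roi.items():
        for eff in res.effects.values():
            rows.append({"roi": roi, "effect": eff.effect, "F": eff.F, "p": eff.p,
                         "epsilon": eff.epsilon,
                         "gg_applied": eff.sphericity_violated})
    return pd.DataFrame(rows)
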