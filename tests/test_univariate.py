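"""ROI condition means, repeated-measures ANOVA and Holm post-hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flowmvpa import pipeline, synth, univariate
from flowmvpa.univariate import (
    posthoc_paired_t_holm,
    rm_anova_3way,
    roi_condition_means,
    table_factors,
)
from tests.conftest import NOISELESS


def brute_force_rm_anova(table: np.ndarray):
    """Independent oracle: marginal-means sums-of-squares decomposition.

    Classical cell-means computation for a fully-within s x A x B x C
    design: every effect's SS from marginal means, error SS from the
    subject x effect interaction means.
    """
    n = table.shape[0]
    cube = table.reshape(n, 2, 4, 3)  # [subject, stereo, size, motion]
    cube = np.transpose(cube, (0, 3, 2, 1))  # [subject, motion, size, stereo]
    a, b, c = 3, 4, 2

    def mean_over(axes):
        return cube.mean(axis=tuple(axes))

    grand = cube.mean()
    # main-effect SS, e.g. A: b*c*n * sum_i (mean_Ai - grand)^2
    mA = mean_over([0, 2, 3])
    mB = mean_over([0, 1, 3])
    mC = mean_over([0, 1, 2])
    mS = mean_over([1, 2, 3])
    ssA = n * b * c * np.sum((mA - grand) ** 2)
    ssB = n * a * c * np.sum((mB - grand) ** 2)
    ssC = n * a * b * np.sum((mC - grand) ** 2)

    mAB = mean_over([0, 3])
    ssAB = n * c * np.sum((mAB - mA[:, None] - mB[None, :] + grand) ** 2)
    mAC = mean_over([0, 2])
    ssAC = n * b * np.sum((mAC - mA[:, None] - mC[None, :] + grand) ** 2)
    mBC = mean_over([0, 1])
    ssBC = n * a * np.sum((mBC - mB[:, None] - mC[None, :] + grand) ** 2)
    mABC = mean_over([0])
    ssABC = n * np.sum(
        (
            mABC
            - mAB[:, :, None]
            - mAC[:, None, :]
            - mBC[None, :, :]
            + mA[:, None, None]
            + mB[None, :, None]
            + mC[None, None, :]
            - grand
        )
        ** 2
    )

    # error terms: subject x effect interactions
    mSA = mean_over([2, 3])
    ssSA = b * c * np.sum((mSA - mS[:, None] - mA[None, :] + grand) ** 2)
    mSB = mean_over([1, 3])
    ssSB = a * c * np.sum((mSB - mS[:, None] - mB[None, :] + grand) ** 2)
    mSC = mean_over([1, 2])
    ssSC = a * b * np.sum((mSC - mS[:, None] - mC[None, :] + grand) ** 2)
    mSAB = mean_over([3])
    ssSAB = c * np.sum(
        (
            mSAB
            - mSA[:, :, None]
            - mSB[:, None, :]
            - mAB[None, :, :]
            + mS[:, None, None]
            + mA[None, :, None]
            + mB[None, None, :]
            - grand
        )
        ** 2
    )
    mSAC = mean_over([2])
    ssSAC = b * np.sum(
        (
            mSAC
            - mSA[:, :, None]
            - mSC[:, None, :]
            - mAC[None, :, :]
            + mS[:, None, None]
            + mA[None, :, None]
            + mC[None, None, :]
            - grand
        )
        ** 2
    )
    mSBC = mean_over([1])
    ssSBC = a * np.sum(
        (
            mSBC
            - mSB[:, :, None]
            - mSC[:, None, :]
            - mBC[None, :, :]
            + mS[:, None, None]
            + mB[None, :, None]
            + mC[None, None, :]
            - grand
        )
        ** 2
    )
    # three-way subject interaction = residual
    total = np.sum((cube - grand) ** 2)
    ssS = a * b * c * np.sum((mS - grand) ** 2)
    ssSABC = total - (
        ssS + ssA + ssB + ssC + ssAB + ssAC + ssBC + ssABC
        + ssSA + ssSB + ssSC + ssSAB + ssSAC + ssSBC
    )

    dfs = {
        "motion": (a - 1, (a - 1) * (n - 1), ssA, ssSA),
        "size": (b - 1, (b - 1) * (n - 1), ssB, ssSB),
        "stereo": (c - 1, (c - 1) * (n - 1), ssC, ssSC),
        "motion x size": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), ssAB, ssSAB),
        "motion x stereo": ((a - 1) * (c - 1), (a - 1) * (c - 1) * (n - 1), ssAC, ssSAC),
        "size x stereo": ((b - 1) * (c - 1), (b - 1) * (c - 1) * (n - 1), ssBC, ssSBC),
        "motion x size x stereo": (
            (a - 1) * (b - 1) * (c - 1),
            (a - 1) * (b - 1) * (c - 1) * (n - 1),
            ssABC,
            ssSABC,
        ),
    }
    return {
        name: (ss_eff / df1) / (ss_err / df2)
        for name, (df1, df2, ss_eff, ss_err) in dfs.items()
    }


@pytest.fixture()
def random_table():
    rng = np.random.default_rng(2024)
    return pd.DataFrame(
        rng.normal(size=(6, 24)) + rng.normal(size=(1, 24)),
        index=[f"s{i}" for i in range(6)],
    )


class TestRoiConditionMeans:
    def test_identical_runs_return_that_value(self):
        ds = synth.make_default_dataset(
            n_subjects=2, n_voxels_per_roi=8, roi_labels=("CSv",),
            noise=NOISELESS, seed=0,
        )
        cond = pipeline.fit_subject_glms(ds, "condition")
        table = univariate.roi_condition_means(
            cond,
            {s.subject_id: s.roi_columns("CSv") for s in ds.subjects},
            {s.subject_id: s.baseline() for s in ds.subjects},
        )
        subj = ds.subjects[0]
        amp = subj.tuning["CSv"].amplitude_table()
        expected = (
            100.0 * amp / subj.baseline()[:, None]
        ).mean(axis=0) * subj.subject_gain
        assert np.allclose(table.loc["sub-01"], expected, atol=1e-8)

    def test_single_voxel_roi(self):
        ds = synth.make_default_dataset(
            n_subjects=2, n_voxels_per_roi=8, roi_labels=("V6",),
            noise=NOISELESS, seed=1,
        )
        cond = pipeline.fit_subject_glms(ds, "condition")
        one = univariate.roi_condition_means(
            cond,
            {s.subject_id: np.array([0]) for s in ds.subjects},
            {s.subject_id: s.baseline() for s in ds.subjects},
        )
        full = univariate.roi_condition_means(
            cond,
            {s.subject_id: np.arange(8) for s in ds.subjects},
            {s.subject_id: s.baseline() for s in ds.subjects},
        )
        assert not np.allclose(one, full)
        subj = ds.subjects[0]
        psc0 = 100.0 * subj.tuning["V6"].amplitude_table()[0] / subj.baseline()[0]
        assert np.allclose(one.loc["sub-01"], psc0 * subj.subject_gain, atol=1e-8)

    def test_noiseless_csv_profile_ordering(self):
        ds = synth.make_default_dataset(
            n_subjects=3, n_voxels_per_roi=12, roi_labels=("CSv",),
            noise=NOISELESS, seed=2,
        )
        cond = pipeline.fit_subject_glms(ds, "condition")
        table = univariate.roi_condition_means(
            cond,
            {s.subject_id: s.roi_columns("CSv") for s in ds.subjects},
            {s.subject_id: s.baseline() for s in ds.subjects},
        )
        fac = table_factors()
        by_motion = {
            m: table.loc[:, fac.index[fac["motion"] == m]].mean().mean()
            for m in ("static", "random", "coherent")
        }
        assert by_motion["coherent"] > by_motion["static"] > by_motion["random"]

    def test_missing_run_rejected(self, small_condition_glms, small_dataset):
        broken = dict(small_condition_glms)
        broken["sub-01"] = []
        with pytest.raises(ValueError, match="no fitted runs"):
            univariate.roi_condition_means(
                broken,
                {s.subject_id: s.roi_columns("CSv") for s in small_dataset.subjects},
                {s.subject_id: s.baseline() for s in small_dataset.subjects},
            )


class TestRmAnova:
    def test_zero_variance_gives_zero_F(self):
        table = pd.DataFrame(np.ones((4, 24)) * np.arange(4)[:, None])
        res = rm_anova_3way(table)
        for eff in res.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    def test_two_level_factor_has_unit_epsilon(self, random_table):
        res = rm_anova_3way(random_table)
        assert res.effects["stereo"].epsilon == 1.0
        assert res.effects["stereo"].mauchly_p is None

    def test_matches_brute_force_oracle(self, random_table):
        res = rm_anova_3way(random_table)
        oracle = brute_force_rm_anova(random_table.to_numpy())
        for name, f_oracle in oracle.items():
            assert res.effects[name].F == pytest.approx(f_oracle, abs=1e-8)

    def test_matches_statsmodels_anova_rm(self, random_table):
        from statsmodels.stats.anova import AnovaRM

        fac = table_factors()
        rows = []
        for subj, row in random_table.iterrows():
            for ci, val in row.items():
                rows.append(
                    {"subject": subj, "y": val, "motion": fac.loc[ci, "motion"],
                     "size": fac.loc[ci, "size"], "stereo": fac.loc[ci, "stereo"]}
                )
        arm = AnovaRM(
            pd.DataFrame(rows), "y", "subject", within=["motion", "size", "stereo"]
        ).fit().anova_table
        res = rm_anova_3way(random_table)
        mapping = {
            "motion": "motion", "size": "size", "stereo": "stereo",
            "motion:size": "motion x size", "motion:stereo": "motion x stereo",
            "size:stereo": "size x stereo",
            "motion:size:stereo": "motion x size x stereo",
        }
        for sm_name, our_name in mapping.items():
            assert res.effects[our_name].F == pytest.approx(
                arm.loc[sm_name, "F Value"], rel=1e-10
            )

    def test_epsilon_bounds_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = pd.DataFrame(rng.normal(size=(5, 24)) * rng.uniform(0.5, 3))
            res = rm_anova_3way(table)
            for eff in res.effects.values():
                assert 1.0 / eff.df1 <= eff.epsilon <= 1.0 or eff.df1 == 1

    def test_epsilon_matches_pingouin(self, random_table):
        import pingouin as pg

        fac = table_factors()
        wide = pd.DataFrame(
            {
                m: random_table.loc[:, fac.index[fac["motion"] == m]].mean(axis=1)
                for m in ("static", "random", "coherent")
            }
        )
        assert rm_anova_3way(random_table).effects["motion"].epsilon == pytest.approx(
            float(pg.epsilon(wide, correction="gg")), abs=1e-9
        )

    def test_input_validation(self, random_table):
        with pytest.raises(ValueError):
            rm_anova_3way(random_table.iloc[:2])
        with pytest.raises(ValueError):
            rm_anova_3way(random_table.iloc[:, :20])
        bad = random_table.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_3way(bad)

    def test_null_p_values_uniform(self):
        """Type-I calibration: uncorrected p uniform on null tables (KS)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            table = pd.DataFrame(rng.normal(size=(9, 24)))
            pvals.append(rm_anova_3way(table).effects["motion"].p_uncorrected)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_for_coherent_gain(self):
        """A 0.3% coherent-motion gain is detected in >80% of simulations."""
        rng = np.random.default_rng(8)
        fac = table_factors()
        coh = (fac["motion"] == "coherent").to_numpy(float)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            table = pd.DataFrame(
                0.3 * coh[None, :] + rng.normal(0, 0.15, size=(9, 24))
            )
            if rm_anova_3way(table).effects["motion"].p < 0.05:
                hits += 1
        assert hits / n_rep > 0.8


class TestPosthoc:
    def test_identical_samples_give_null_result(self):
        table = pd.DataFrame(np.tile(np.arange(4)[:, None], (1, 24)), dtype=float)
        out = posthoc_paired_t_holm(table, "motion")
        assert all(p.t == 0.0 and p.p_holm == 1.0 for p in out)

    def test_holm_step_down_rule(self):
        from flowmvpa.mvpa import holm_adjust

        adj = holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_pair_uncorrected(self, random_table):
        out = posthoc_paired_t_holm(random_table, "stereo")
        assert len(out) == 1
        assert out[0].p_holm == pytest.approx(out[0].p)

    def test_motion_pairs_collapse_over_other_factors(self, random_table):
        out = posthoc_paired_t_holm(random_table, "motion")
        assert len(out) == 3
        fac = table_factors()
        a = random_table.loc[:, fac.index[fac["motion"] == "static"]].mean(axis=1)
        b = random_table.loc[:, fac.index[fac["motion"] == "random"]].mean(axis=1)
        t_manual = stats.ttest_rel(a, b).statistic
        first = [p for p in out if {p.level_a, p.level_b} == {"static", "random"}][0]
        assert first.t == pytest.approx(t_manual)

    def test_too_few_subjects_rejected(self, random_table):
        with pytest.raises(ValueError):
            posthoc_paired_t_holm(random_table.iloc[:1], "motion")
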