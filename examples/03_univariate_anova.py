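"""ROI-averaged condition responses, repeated-measures ANOVA and post-hocs.

Fits condition-wise GLMs to a simulated 9-subject dataset, averages CSv
betas into a subject x condition table of percent signal change, and runs
the three-way repeated-measures ANOVA with Greenhouse-Geisser gating plus
Holm-adjusted paired t-tests on the motion factor.
"""

from flowmvpa import pipeline, synth, univariate

ds = synth.make_default_dataset(n_subjects=9, roi_labels=("CSv",), seed=0)
cond_glms = pipeline.fit_subject_glms(ds, "condition")
table = pipeline.roi_bold_tables(ds, cond_glms)["CSv"]
print(f"condition-response table: {table.shape[0]} subjects x "
      f"{table.shape[1]} conditions (percent signal change)")

anova = univariate.rm_anova_3way(table)
for name in ("motion", "size", "stereo", "motion x size"):
    e = anova.effects[name]
    tag = " (GG-corrected)" if e.sphericity_violated else ""
    print(f"  {name:14s} F({e.df1:.0f},{e.df2:.0f}) = {e.F:7.2f}, p = {e.p:.4g}{tag}")

print("post-hoc paired t-tests on motion (Holm-adjusted):")
for p in univariate.posthoc_paired_t_holm(table, "motion"):
    print(
        f"  {p.level_a:8s} - {p.level_b:8s}: diff {p.mean_difference:+.3f}%, "
        f"t = {p.t:+.2f}, p_holm = {p.p_holm:.4f}"
    )
print(
    "CSv signature: a large coherent-motion effect and a small but "
    "reliable static > random difference (inhibition by self-motion-"
    "incompatible stimulation)."
)
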