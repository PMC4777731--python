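"""Correlate ROI activation with perceived self-motion strength.

Simulates a rating-coupled dataset (ROI condition profiles constructed
with known correlations to the vection-rating profile), recovers the
per-ROI neuro-perceptual correlations, and compares dependent
correlations between ROIs with the Meng-Rosenthal-Rubin Z test.
"""

from flowmvpa import neurocorr, pipeline, synth

couplings = {"V1": 0.0, "hMT+": 0.2, "V6": 0.5, "PcM": 0.55, "CSv": 0.6}
ds, ratings = synth.make_coupled_dataset(couplings=couplings, seed=7)
cond_glms = pipeline.fit_subject_glms(ds, "condition")
tables = pipeline.roi_bold_tables(ds, cond_glms)

roi_frame, pair_frame = neurocorr.correlation_analysis(
    tables, ratings, mode="per_subject"
)
print("per-ROI neuro-perceptual correlation (Fisher-z one-sample t, df=8):")
for _, row in roi_frame.iterrows():
    print(
        f"  {row['roi']:5s} generative rho = {couplings[row['roi']]:.2f}  ->  "
        f"r = {row['r']:+.3f}, t = {row['t']:+6.2f}, p = {row['p']:.2g}"
    )

row = pair_frame[(pair_frame.roi_a == "hMT+") & (pair_frame.roi_b == "CSv")].iloc[0]
print(
    f"CSv vs hMT+ (shared rating variable): Z = {row['Z']:+.2f}, "
    f"Bonferroni p = {row['p_bonferroni']:.2g}"
)
print(
    "The coupled medial regions recover their generative correlations; "
    "the uncoupled V1 stays near zero; the CSv-hMT+ gap of 0.4 is "
    "detected by the dependent-correlation comparison."
)
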