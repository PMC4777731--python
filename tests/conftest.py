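import numpy as np
import pytest

from flowmvpa import pipeline, synth

NOISELESS = synth.NoiseModel(
    ar1=0.0,
    sd=0.0,
    subject_gain_sd=0.0,
    run_gain_sd=0.0,
    trial_jitter_sd=0.0,
    motion_coupling=0.0,
)


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects, 2 ROIs, 16 voxels each — fast shared fixture."""
    return synth.make_default_dataset(
        n_subjects=3, n_voxels_per_roi=16, roi_labels=("CSv", "V6"), seed=11
    )


@pytest.fixture(scope="session")
def small_trial_glms(small_dataset):
    return pipeline.fit_subject_glms(small_dataset, "trial")


@pytest.fixture(scope="session")
def small_condition_glms(small_dataset):
    return pipeline.fit_subject_glms(small_dataset, "condition")


@pytest.fixture(scope="session")
def default_study():
    """The full default 9-subject study-condition simulation with GLM fits.

    Session-scoped: this is the dataset on which the archetype-recovery
    signature is evaluated.
    """
    ds = synth.make_default_dataset(seed=0)
    trial = pipeline.fit_subject_glms(ds, "trial")
    cond = pipeline.fit_subject_glms(ds, "condition")
    samples = {
        roi: pipeline.roi_samples(ds, trial, roi, 112) for roi in ds.roi_labels
    }
    tables = pipeline.roi_bold_tables(ds, cond)
    return {"dataset": ds, "samples": samples, "tables": tables}
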