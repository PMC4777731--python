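"""Synthetic multi-subject BOLD data with ground-truth ROI tuning archetypes.

Each region of interest (V1, hMT+, V6, PcM, CSv, PIVC) is generated from a
voxel tuning archetype whose mean and pattern structure emulate the
qualitative response signatures reported for wide-view optic-flow
stimulation:

* V1 — strong retinotopic (eccentricity) map, random > coherent > static
  mean response, stereo pattern code.
* hMT+ — general motion sensitivity (coherent ~ random > static), size
  pattern code without a mean size effect, strong motion pattern codes.
* V6 — coherent-selective mean response with a strong eccentricity map and
  pattern codes for every motion level.
* PcM — coherent-selective; only the coherent level carries a distinctive
  multi-voxel pattern, and size information rides exclusively on the
  coherent-driven component.
* CSv — coherent-selective with a small *uniform* suppression of the
  random-motion response below static (self-motion-incompatible
  inhibition), a coherent-specific pattern code, and no eccentricity map.
* PIVC — weak coherent selectivity, low pattern signal-to-noise.

Mean amplitudes are in units of percent signal change around a ~100-unit
baseline. Noise is AR(1) Gaussian in the time series plus multiplicative
subject-, run- and trial-level gain variability, which is what limits the
decodability of spatially uniform mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import design as dz
from .design import TrialTable, conditions
from .glm import HRFSpec, build_design_matrix

ROI_LABELS = ("V1", "hMT+", "V6", "PcM", "CSv", "PIVC")

N_SUBJECTS_DEFAULT = 9
N_VOXELS_PER_ROI_DEFAULT = 48
BASELINE_MEAN = 100.0

_STEREO_SIGN = {"nonstereo": -0.5, "stereo": +0.5}


@dataclass(frozen=True)
class ArchetypeParams:
    """Free parameters of one ROI archetype (all in percent-signal units)."""

    motion_gain: tuple[float, float, float]  # (static, random, coherent)
    has_ecc_map: bool = False
    ecc_width_deg: float = 8.0
    map_pattern_scale: float = 1.0  # voxelwise coverage heterogeneity
    map_mean_effect: bool = True  # coverage also drives the ROI mean
    map_gate: tuple[bool, bool, bool] = (True, True, True)  # which motions
    coherent_size_curve: tuple[float, float, float, float] | None = None
    sigma_pattern: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_stereo: float = 0.0
    csv_sparse_fraction: float = 0.0  # optional sparse random-activated voxels
    csv_sparse_gain: float = 0.0


#: Archetype defaults. These are free parameters of the generator, chosen so
#: that the downstream pipeline lands in the qualitative regime reported for
#: real data (decoding accuracies roughly 0.3-0.9, small univariate
#: contrasts detectable at n = 9 subjects).
ARCHETYPES: dict[str, ArchetypeParams] = {
    "V1": ArchetypeParams(
        motion_gain=(1.2, 1.6, 1.35),
        has_ecc_map=True,
        ecc_width_deg=6.0,
        map_pattern_scale=1.0,
        map_mean_effect=True,
        sigma_pattern=(0.25, 0.25, 0.25),
        sigma_stereo=0.25,
    ),
    "hMT+": ArchetypeParams(
        motion_gain=(0.6, 1.5, 1.5),
        has_ecc_map=True,
        ecc_width_deg=12.0,
        map_pattern_scale=0.5,
        map_mean_effect=False,
        sigma_pattern=(0.40, 0.40, 0.40),
        sigma_stereo=0.12,
    ),
    "V6": ArchetypeParams(
        motion_gain=(0.8, 0.8, 1.4),
        has_ecc_map=True,
        ecc_width_deg=6.0,
        map_pattern_scale=1.8,
        map_mean_effect=True,
        sigma_pattern=(0.30, 0.30, 0.30),
        sigma_stereo=0.15,
    ),
    "PcM": ArchetypeParams(
        motion_gain=(0.5, 0.5, 1.05),
        has_ecc_map=True,
        ecc_width_deg=10.0,
        map_pattern_scale=0.4,
        map_mean_effect=False,
        map_gate=(False, False, True),  # size code only via coherent drive
        sigma_pattern=(0.0, 0.0, 0.22),
        sigma_stereo=0.05,
    ),
    "CSv": ArchetypeParams(
        motion_gain=(0.55, 0.51, 1.10),  # random < static: uniform inhibition
        coherent_size_curve=(0.94, 0.98, 1.02, 1.06),
        sigma_pattern=(0.0, 0.0, 0.25),
        sigma_stereo=0.03,
    ),
    "PIVC": ArchetypeParams(
        motion_gain=(0.5, 0.5, 0.65),
        sigma_pattern=(0.04, 0.04, 0.05),
        sigma_stereo=0.03,
    ),
}

_SIZE_RADII = {17: 8.5, 33: 16.5, 67: 33.5, 100: 50.0}  # half horizontal extent


@dataclass
class VoxelTuningModel:
    """Ground-truth voxel tuning for one ROI of one subject.

    The per-condition neural amplitude decomposes as

        A[v, c] = M[motion, size] * (1 + V[v, size] * gate[motion])
                  + P[v, motion] + W[v] * z(stereo) + coupling[c]

    where ``M`` is the mean amplitude surface, ``V`` the zero-mean
    voxelwise size (eccentricity-coverage) pattern, ``P`` the zero-mean
    motion pattern code, ``W`` the zero-mean stereo pattern code and
    ``coupling`` an optional condition profile shared by all voxels
    (used by rating-coupled scenarios).
    """

    roi_label: str
    baseline: np.ndarray  # (n_vox,)
    mean_amplitude: np.ndarray  # (3 motions, 4 sizes)
    size_pattern: np.ndarray  # (n_vox, 4), zero-mean over voxels per size
    size_gate: np.ndarray  # (3,) bool
    motion_pattern: np.ndarray  # (n_vox, 3), zero-mean over voxels
    stereo_pattern: np.ndarray  # (n_vox,), zero-mean
    ecc_pref: np.ndarray | None = None  # (n_vox,) degrees, or None
    coupling_profile: np.ndarray | None = None  # (24,)

    @property
    def n_voxels(self) -> int:
        return len(self.baseline)

    def amplitude_table(self) -> np.ndarray:
        """Noise-free amplitude for every voxel x condition, (n_vox, 24)."""
        A = np.zeros((self.n_voxels, len(conditions())))
        for c, cond in enumerate(conditions()):
            m = dz.MOTIONS.index(cond.motion)
            s = dz.SIZES_DEG.index(cond.size_deg)
            amp = self.mean_amplitude[m, s] * (
                1.0 + self.size_pattern[:, s] * float(self.size_gate[m])
            )
            amp = amp + self.motion_pattern[:, m]
            amp = amp + self.stereo_pattern * _STEREO_SIGN[cond.stereo]
            if self.coupling_profile is not None:
                amp = amp + self.coupling_profile[c]
            A[:, c] = amp
        return A

    def to_dict(self) -> dict:
        d = {
            "roi_label": self.roi_label,
            "baseline": self.baseline.tolist(),
            "mean_amplitude": self.mean_amplitude.tolist(),
            "size_pattern": self.size_pattern.tolist(),
            "size_gate": np.asarray(self.size_gate, bool).tolist(),
            "motion_pattern": self.motion_pattern.tolist(),
            "stereo_pattern": self.stereo_pattern.tolist(),
            "ecc_pref": None if self.ecc_pref is None else self.ecc_pref.tolist(),
            "coupling_profile": None
            if self.coupling_profile is None
            else self.coupling_profile.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelTuningModel":
        return cls(
            roi_label=d["roi_label"],
            baseline=np.asarray(d["baseline"], float),
            mean_amplitude=np.asarray(d["mean_amplitude"], float),
            size_pattern=np.asarray(d["size_pattern"], float),
            size_gate=np.asarray(d["size_gate"], bool),
            motion_pattern=np.asarray(d["motion_pattern"], float),
            stereo_pattern=np.asarray(d["stereo_pattern"], float),
            ecc_pref=None if d["ecc_pref"] is None else np.asarray(d["ecc_pref"], float),
            coupling_profile=None
            if d["coupling_profile"] is None
            else np.asarray(d["coupling_profile"], float),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_roi_archetype(
    roi_label: str,
    n_voxels: int = N_VOXELS_PER_ROI_DEFAULT,
    seed: int | np.random.Generator = 0,
    params: ArchetypeParams | None = None,
) -> VoxelTuningModel:
    """Instantiate one subject's voxel tuning for an ROI archetype.

    Pattern components (eccentricity preferences, motion/stereo codes) are
    drawn per subject: different subjects realize different voxel patterns
    around the same archetype mean structure.
    """
    if params is None:
        if roi_label not in ARCHETYPES:
            raise ValueError(f"unknown ROI label {roi_label!r}")
        params = ARCHETYPES[roi_label]
    if n_voxels < 8:
        raise ValueError("n_voxels must be >= 8")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    baseline = rng.normal(BASELINE_MEAN, 3.0, size=n_voxels)
    gains = np.asarray(params.motion_gain, float)

    sizes = np.array([_SIZE_RADII[s] for s in dz.SIZES_DEG])
    if params.has_ecc_map:
        ecc_pref = rng.uniform(3.0, 55.0, size=n_voxels)
        coverage = _sigmoid(
            (sizes[None, :] - ecc_pref[:, None]) / params.ecc_width_deg
        )  # (n_vox, 4): soft "stimulus covers my preferred eccentricity"
        mean_cov = coverage.mean(axis=0)
        rel_dev = (coverage - mean_cov) / np.maximum(mean_cov, 1e-9)
        size_pattern = params.map_pattern_scale * rel_dev
        size_curve = mean_cov if params.map_mean_effect else np.ones(4)
    else:
        ecc_pref = None
        size_pattern = np.zeros((n_voxels, 4))
        size_curve = np.ones(4)

    mean_amplitude = gains[:, None] * size_curve[None, :]
    if params.coherent_size_curve is not None:
        mean_amplitude[2] = gains[2] * np.asarray(params.coherent_size_curve)

    motion_pattern = np.zeros((n_voxels, 3))
    for m in range(3):
        if params.sigma_pattern[m] > 0:
            p = rng.normal(0.0, params.sigma_pattern[m], size=n_voxels)
            motion_pattern[:, m] = p - p.mean()
    if params.csv_sparse_fraction > 0:
        # alternative inhibition variant: sparse random-motion activators
        k = max(1, int(round(params.csv_sparse_fraction * n_voxels)))
        idx = rng.choice(n_voxels, size=k, replace=False)
        sparse = np.zeros(n_voxels)
        sparse[idx] = params.csv_sparse_gain
        motion_pattern[:, 1] += sparse - sparse.mean()

    if params.sigma_stereo > 0:
        w = rng.normal(0.0, params.sigma_stereo, size=n_voxels)
        stereo_pattern = w - w.mean()
    else:
        stereo_pattern = np.zeros(n_voxels)

    return VoxelTuningModel(
        roi_label=roi_label,
        baseline=baseline,
        mean_amplitude=mean_amplitude,
        size_pattern=size_pattern,
        size_gate=np.asarray(params.map_gate, bool),
        motion_pattern=motion_pattern,
        stereo_pattern=stereo_pattern,
        ecc_pref=ecc_pref,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of the forward model (signal units / fractions)."""

    ar1: float = 0.3
    sd: float = 2.0  # time-series noise SD, ~2% of baseline
    subject_gain_sd: float = 0.15  # multiplicative, per subject
    run_gain_sd: float = 0.05  # multiplicative, per subject x run
    trial_jitter_sd: float = 0.1  # multiplicative, per trial (shared over voxels)
    motion_coupling: float = 0.2  # weight of head-motion nuisance leakage

    def __post_init__(self) -> None:
        for name in ("sd", "subject_gain_sd", "run_gain_sd", "trial_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")


@dataclass
class SubjectData:
    subject_id: str
    schedules: list[TrialTable]
    runs: list[np.ndarray]  # each (n_volumes, n_voxels)
    nuisance: list[np.ndarray]  # each (n_volumes, 6)
    roi_membership: np.ndarray  # (n_voxels,) of ROI labels
    tuning: dict[str, VoxelTuningModel]
    subject_gain: float

    @property
    def n_voxels(self) -> int:
        return len(self.roi_membership)

    def roi_columns(self, roi_label: str) -> np.ndarray:
        return np.flatnonzero(self.roi_membership == roi_label)

    def baseline(self) -> np.ndarray:
        return np.concatenate(
            [self.tuning[r].baseline for r in dict.fromkeys(self.roi_membership)]
        )


@dataclass
class BOLDDataset:
    subjects: list[SubjectData]
    tr: float = dz.TR_S
    n_volumes: int = dz.N_VOLUMES
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int | None = None

    @property
    def roi_labels(self) -> list[str]:
        return list(dict.fromkeys(self.subjects[0].roi_membership))


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int], ar1: float, sd: float
) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=shape)
    if ar1 == 0.0:
        return sd * white
    out = np.empty_like(white)
    out[0] = white[0]
    for t in range(1, shape[0]):
        out[t] = ar1 * out[t - 1] + white[t]
    # rescale to the requested stationary SD
    return sd * out * np.sqrt(1.0 - ar1**2)


def _head_motion_series(
    rng: np.random.Generator, n_volumes: int, drift_sd: float = 0.02
) -> np.ndarray:
    """Six smooth head-motion parameter series (slow random walks)."""
    steps = rng.normal(0.0, drift_sd, size=(n_volumes, 6))
    return np.cumsum(steps, axis=0)


def simulate_bold(
    schedules_per_subject: list[list[TrialTable]],
    tuning_per_subject: list[dict[str, VoxelTuningModel]],
    noise: NoiseModel = NoiseModel(),
    hrf_spec: HRFSpec = HRFSpec(),
    seed: int = 0,
) -> BOLDDataset:
    """Forward-simulate a multi-subject BOLD dataset.

    The clean signal for a run is the trial-wise design matrix (unit-peak
    HRF-convolved regressors) times the per-trial neural amplitudes, so
    with all noise terms at zero the trial-wise GLM recovers the injected
    amplitudes exactly.
    """
    if len(schedules_per_subject) != len(tuning_per_subject):
        raise ValueError("one tuning dict per subject is required")
    root = np.random.SeedSequence(seed)
    subj_seeds = root.spawn(len(schedules_per_subject))

    subjects = []
    for si, (schedules, tuning) in enumerate(
        zip(schedules_per_subject, tuning_per_subject)
    ):
        n_vols = {t.n_volumes for t in schedules}
        if len(n_vols) != 1:
            raise ValueError("all runs of a subject must share the volume count")
        n_volumes = n_vols.pop()
        rng = np.random.default_rng(subj_seeds[si])
        subject_gain = max(0.1, rng.normal(1.0, noise.subject_gain_sd))

        roi_labels = list(tuning.keys())
        amp_tables = [tuning[r].amplitude_table() for r in roi_labels]
        amp_all = np.vstack(amp_tables)  # (n_vox_total, 24)
        baseline = np.concatenate([tuning[r].baseline for r in roi_labels])
        membership = np.concatenate(
            [np.repeat(r, tuning[r].n_voxels) for r in roi_labels]
        )
        n_vox = len(baseline)

        runs, nuis_list = [], []
        for table in schedules:
            run_gain = max(0.1, rng.normal(1.0, noise.run_gain_sd))
            dm = build_design_matrix(
                table, mode="trial", n_volumes=n_volumes, hrf_spec=hrf_spec
            )
            X = dm.matrix[:, dm.task_columns]  # (n_volumes, 48)
            cond_idx = table.condition_indices
            jitter = 1.0 + noise.trial_jitter_sd * rng.normal(size=len(cond_idx))
            trial_amp = (
                amp_all[:, cond_idx] * jitter[None, :] * subject_gain * run_gain
            )  # (n_vox, n_trials)
            clean = X @ trial_amp.T  # (n_volumes, n_vox)

            motion = _head_motion_series(rng, n_volumes)
            if noise.motion_coupling > 0:
                weights = rng.normal(0.0, noise.motion_coupling, size=(6, n_vox))
                clean = clean + motion @ weights
            data = baseline[None, :] + clean
            if noise.sd > 0:
                data = data + _ar1_noise(rng, (n_volumes, n_vox), noise.ar1, noise.sd)
            runs.append(data)
            nuis_list.append(motion)

        subjects.append(
            SubjectData(
                subject_id=f"sub-{si + 1:02d}",
                schedules=schedules,
                runs=runs,
                nuisance=nuis_list,
                roi_membership=membership,
                tuning=tuning,
                subject_gain=subject_gain,
            )
        )
    return BOLDDataset(subjects=subjects, noise=noise, seed=seed)


def make_default_dataset(
    n_subjects: int = N_SUBJECTS_DEFAULT,
    n_voxels_per_roi: int = N_VOXELS_PER_ROI_DEFAULT,
    roi_labels: tuple[str, ...] = ROI_LABELS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    null_mode: bool = False,
    archetype_overrides: dict[str, ArchetypeParams] | None = None,
) -> BOLDDataset:
    """The default 9-subject study-condition dataset.

    ``null_mode`` equalizes all motion gains and removes every pattern
    code, yielding data with no decodable condition information.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    root = np.random.SeedSequence([seed, 424242])
    design_seeds = root.spawn(n_subjects)
    schedules, tunings = [], []
    for si in range(n_subjects):
        rng = np.random.default_rng(design_seeds[si])
        schedules.append(
            dz.generate_subject_schedules(seed=int(rng.integers(2**31)))
        )
        tuning = {}
        for roi in roi_labels:
            params = (archetype_overrides or {}).get(roi, ARCHETYPES[roi])
            if null_mode:
                g = float(np.mean(params.motion_gain))
                params = replace(
                    params,
                    motion_gain=(g, g, g),
                    has_ecc_map=False,
                    coherent_size_curve=None,
                    sigma_pattern=(0.0, 0.0, 0.0),
                    sigma_stereo=0.0,
                )
            tuning[roi] = make_roi_archetype(
                roi, n_voxels_per_roi, seed=np.random.default_rng(rng.integers(2**31)),
                params=params,
            )
        tunings.append(tuning)
    return simulate_bold(schedules, tunings, noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# ratings


@dataclass(frozen=True)
class RatingModel:
    """Magnitude-estimation model of perceived self-motion strength.

    Ratings live on [0, 10]; 10 is anchored to the standard stimulus
    (coherent motion, 100 degrees, stereo). The coherent curve saturates
    between the 67 and 100 degree sizes; random motion yields weak
    self-motion impressions and static stimuli nearly none; stereo has no
    effect by default.
    """

    coherent_by_size: tuple[float, float, float, float] = (3.5, 6.0, 9.3, 9.6)
    random_offset: float = 1.5
    static_offset: float = 0.5
    stereo_effect: float = 0.0
    subject_sd: float = 0.8

    def __post_init__(self) -> None:
        if any(np.diff(self.coherent_by_size) < 0):
            raise ValueError("coherent size-response curve must be non-decreasing")
        if self.random_offset < 0 or self.static_offset < 0:
            raise ValueError("offsets must be >= 0")

    def expected_profile(self) -> np.ndarray:
        """Expected rating per condition index, (24,)."""
        out = np.zeros(len(conditions()))
        for c, cond in enumerate(conditions()):
            if cond.motion == "coherent":
                r = self.coherent_by_size[dz.SIZES_DEG.index(cond.size_deg)]
            elif cond.motion == "random":
                r = self.random_offset
            else:
                r = self.static_offset
            r = r + self.stereo_effect * _STEREO_SIGN[cond.stereo]
            out[c] = r
        return np.clip(out, 0.0, 10.0)

    def expected_observed_profile(self) -> np.ndarray:
        """Mean of the *clipped* observed rating per condition.

        Ratings are clipped to [0, 10] after subject noise, which biases
        cell means near the scale bounds; this closed form (clipped
        normal mean) is what observed cell means converge to.
        """
        from scipy import stats as _st

        mu = self.expected_profile()
        s = self.subject_sd
        if s == 0:
            return mu
        alpha = (0.0 - mu) / s
        beta = (10.0 - mu) / s
        return (
            10.0 * _st.norm.sf(beta)
            + mu * (_st.norm.cdf(beta) - _st.norm.cdf(alpha))
            + s * (_st.norm.pdf(alpha) - _st.norm.pdf(beta))
        )


def simulate_ratings(
    n_subjects: int = N_SUBJECTS_DEFAULT,
    model: RatingModel = RatingModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Subject x condition table of vection ratings, clipped to [0, 10]."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    profile = model.expected_profile()
    data = profile[None, :] + rng.normal(
        0.0, model.subject_sd, size=(n_subjects, len(profile))
    )
    data = np.clip(data, 0.0, 10.0)
    return pd.DataFrame(
        data,
        index=pd.Index([f"sub-{i + 1:02d}" for i in range(n_subjects)], name="subject"),
        columns=pd.RangeIndex(len(profile), name="condition_index"),
    )


# ---------------------------------------------------------------------------
# designated scenarios


def make_coupled_dataset(
    couplings: dict[str, float] | None = None,
    n_subjects: int = N_SUBJECTS_DEFAULT,
    n_voxels_per_roi: int = N_VOXELS_PER_ROI_DEFAULT,
    rating_model: RatingModel = RatingModel(),
    coupling_strength: float = 0.25,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[BOLDDataset, pd.DataFrame]:
    """Rating-coupled scenario for neuro-perceptual correlation recovery.

    Each ROI's condition profile is built to correlate ``couplings[roi]``
    with the standardized expected *observed* rating profile (the
    remainder being a fixed orthogonal profile), on top of otherwise flat
    tuning. Returns the dataset together with a simulated rating table.
    """
    if couplings is None:
        couplings = {
            "V1": 0.0, "hMT+": 0.2, "V6": 0.5, "PcM": 0.55, "CSv": 0.6, "PIVC": 0.4,
        }
    profile = rating_model.expected_observed_profile()
    z = (profile - profile.mean()) / profile.std()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 31337]))
    overrides = {}
    for roi, rho in couplings.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError("couplings must be correlations in [-1, 1]")
        eta = rng.normal(size=len(z))
        eta = eta - eta.mean() - z * (eta @ z) / (z @ z)
        eta = eta / eta.std()
        prof = coupling_strength * (rho * z + np.sqrt(1.0 - rho**2) * eta)
        overrides[roi] = prof

    roi_labels = tuple(couplings.keys())
    flat = {
        roi: replace(
            ARCHETYPES[roi],
            motion_gain=(1.0, 1.0, 1.0),
            has_ecc_map=False,
            coherent_size_curve=None,
            sigma_pattern=(0.0, 0.0, 0.0),
            sigma_stereo=0.0,
        )
        for roi in roi_labels
    }
    ds = make_default_dataset(
        n_subjects=n_subjects,
        n_voxels_per_roi=n_voxels_per_roi,
        roi_labels=roi_labels,
        noise=noise,
        seed=seed,
        archetype_overrides=flat,
    )
    for subj in ds.subjects:
        for roi, prof in overrides.items():
            subj.tuning[roi].coupling_profile = prof.copy()
    # re-run the forward model with the coupling profiles in place
    ds = simulate_bold(
        [s.schedules for s in ds.subjects],
        [s.tuning for s in ds.subjects],
        noise=noise,
        seed=seed,
    )
    ratings = simulate_ratings(n_subjects, rating_model, seed=seed)
    return ds, ratings


def make_null_samples(
    n_voxels: int = 16,
    n_runs: int = dz.N_RUNS,
    n_classes: int = 3,
    samples_per_class_per_run: int = 2,
    seed: int | np.random.Generator = 0,
):
    """Trial-beta samples with no condition coding (pure noise features).

    A fast null scenario for permutation-test calibration: features are
    i.i.d. Gaussian, labels carry no information, the run structure
    matches the leave-one-run-out grid.
    """
    from .mvpa import MultiVoxelSamples  # local import to avoid a cycle

    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n_per_run = n_classes * samples_per_class_per_run
    runs = np.repeat(np.arange(1, n_runs + 1), n_per_run)
    labels = np.tile(
        np.repeat(np.arange(n_classes), samples_per_class_per_run), n_runs
    )
    X = rng.normal(size=(len(runs), n_voxels))
    return MultiVoxelSamples(
        X=X,
        run=runs,
        condition_index=labels,
        voxel_subject=np.repeat("sub-01", n_voxels),
        roi_label="null",
    )
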