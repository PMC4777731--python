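"""HRF-convolved design matrices and ordinary-least-squares beta estimation.

Condition-wise mode fits one regressor per experimental condition (24 task
columns); trial-wise mode fits one regressor per stimulus presentation
(48 task columns per run), which yields the per-trial response patterns
the multi-voxel analysis consumes. Six head-motion nuisance series and an
intercept complete the model. Task regressors are scaled to the peak of an
isolated single-trial response, so betas convert directly to percent
signal change against the voxel baseline and trial-wise betas average to
condition-wise betas.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .design import TRIAL_DURATION_S, TrialTable


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function parameters.

    Difference of two gamma densities (response minus undershoot), the
    convention popularized by SPM: ~5-6 s peak, ~16 s undershoot at a 1/6
    amplitude ratio, 32-s support.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("HRF sampling interval and duration must be positive")
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("HRF delays must be positive")


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Sampled double-gamma kernel, peak-normalized to 1.

    Returns (t, h) with h[0] = 0 and positive integral.
    """
    t = np.arange(0.0, spec.duration_s + spec.dt_s / 2, spec.dt_s)
    peak = stats.gamma.pdf(
        t, a=spec.peak_delay_s / spec.peak_dispersion_s, scale=spec.peak_dispersion_s
    )
    under = stats.gamma.pdf(
        t,
        a=spec.undershoot_delay_s / spec.undershoot_dispersion_s,
        scale=spec.undershoot_dispersion_s,
    )
    h = peak - spec.undershoot_ratio * under
    h = h / h.max()
    return t, h


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    task_columns: list[int]
    regressor_info: pd.DataFrame  # per task column: condition_index, trial, run
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


@lru_cache(maxsize=16)
def _single_trial_peak(duration: float, hrf_spec: HRFSpec) -> float:
    """Peak of the HRF response to one isolated boxcar of ``duration``."""
    dt = hrf_spec.dt_s
    box = np.zeros(int(round((duration + hrf_spec.duration_s) / dt)))
    box[: int(round(duration / dt))] = 1.0
    _, kernel = canonical_hrf(hrf_spec)
    return float(np.convolve(box, kernel).max())


def _convolved_regressor(
    onsets: np.ndarray,
    duration: float,
    n_volumes: int,
    tr: float,
    hrf_spec: HRFSpec,
) -> np.ndarray:
    """Boxcar-convolved, TR-sampled task regressor.

    All task columns are scaled by the peak response of one isolated
    trial, so a beta of 1 means a peak signal excursion of 1 for a single
    event regardless of how trials of a condition overlap; averaging the
    trial-wise betas of a condition then equals its condition-wise beta.
    """
    dt = hrf_spec.dt_s
    n_hi = int(round(n_volumes * tr / dt))
    box = np.zeros(n_hi)
    for onset in onsets:
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + duration) / dt)), n_hi)
        box[i0:i1] = 1.0
    _, kernel = canonical_hrf(hrf_spec)
    sig = np.convolve(box, kernel)[:n_hi]
    # sample at volume acquisition times t = 0, TR, 2*TR, ...
    idx = (np.arange(n_volumes) * tr / dt).round().astype(int)
    return sig[idx] / _single_trial_peak(duration, hrf_spec)


def build_design_matrix(
    events: TrialTable,
    mode: str = "condition",
    nuisance: np.ndarray | None = None,
    n_volumes: int | None = None,
    tr: float | None = None,
    hrf_spec: HRFSpec = HRFSpec(),
) -> DesignMatrix:
    """Task + nuisance + intercept design matrix for one run.

    mode='condition' pools the trials of each condition into a single
    regressor; mode='trial' gives every stimulus presentation its own
    regressor. Nuisance columns are mean-centered; the intercept is last.
    """
    if mode not in ("condition", "trial"):
        raise ValueError(f"unknown design mode {mode!r}")
    n_volumes = n_volumes if n_volumes is not None else events.n_volumes
    tr = tr if tr is not None else events.tr
    ev = events.events
    if ev["onset"].duplicated().any():
        raise ValueError("duplicate event onsets produce collinear regressors")
    if (ev["onset"] + ev["duration"]).max() > n_volumes * tr:
        raise ValueError("events extend beyond the run duration")

    cols, names, info = [], [], []
    if mode == "condition":
        for ci, grp in ev.groupby("condition_index", sort=True):
            cols.append(
                _convolved_regressor(
                    grp["onset"].to_numpy(), TRIAL_DURATION_S, n_volumes, tr, hrf_spec
                )
            )
            names.append(f"cond_{ci:02d}")
            info.append(
                {"condition_index": int(ci), "trial": -1, "run": events.run_id}
            )
    else:
        occurrence: dict[int, int] = {}
        for t, row in enumerate(ev.itertuples(index=False)):
            ci = int(row.condition_index)
            occ = occurrence.get(ci, 0)
            occurrence[ci] = occ + 1
            cols.append(
                _convolved_regressor(
                    np.array([row.onset]), TRIAL_DURATION_S, n_volumes, tr, hrf_spec
                )
            )
            names.append(f"trial_{t:02d}_cond_{ci:02d}_rep{occ}")
            info.append(
                {"condition_index": ci, "trial": t, "run": events.run_id,
                 "occurrence": occ}
            )

    task_columns = list(range(len(cols)))
    if nuisance is not None:
        nuisance = np.asarray(nuisance, float)
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance series length must equal the volume count")
        centered = nuisance - nuisance.mean(axis=0, keepdims=True)
        for j in range(centered.shape[1]):
            cols.append(centered[:, j])
            names.append(f"nuisance_{j}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")

    X = np.column_stack(cols)
    return DesignMatrix(
        matrix=X,
        names=names,
        task_columns=task_columns,
        regressor_info=pd.DataFrame(info),
        tr=tr,
    )


@dataclass
class GLMResult:
    betas: np.ndarray  # (n_regressors, n_voxels), signal units
    residual_variance: np.ndarray  # (n_voxels,)
    design: DesignMatrix

    @property
    def task_betas(self) -> np.ndarray:
        return self.betas[self.design.task_columns]

    def condition_betas(self) -> pd.DataFrame:
        """Task betas indexed by condition (condition-wise fits)."""
        idx = self.design.regressor_info["condition_index"].to_numpy()
        return pd.DataFrame(self.task_betas, index=pd.Index(idx, name="condition_index"))


def fit_ols(design: DesignMatrix, data: np.ndarray) -> GLMResult:
    """Ordinary least squares, one fit shared across voxels.

    ``data`` is (n_volumes, n_voxels). Raises on rank deficiency, naming
    a collinear column.
    """
    X = design.matrix
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] != X.shape[0]:
        raise ValueError("time dimension of data does not match the design")
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer volumes than regressors: design is rank deficient")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a dependent column for the error message
        q, r = np.linalg.qr(X)
        bad = int(np.argmin(np.abs(np.diag(r))))
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"column {design.names[bad]!r} is collinear"
        )
    betas, _, _, _ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ betas
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / max(dof, 1)
    return GLMResult(betas=betas, residual_variance=sigma2, design=design)


def to_percent_signal_change(
    result: GLMResult, baseline: np.ndarray | float
) -> np.ndarray:
    """Task betas as percent of the voxel baseline signal.

    Valid because task regressors are unit-peak normalized, so a beta is
    the peak-to-baseline signal excursion in raw units.
    """
    baseline = np.atleast_1d(np.asarray(baseline, float))
    if np.any(baseline <= 0):
        raise ValueError("baseline signal must be positive")
    return 100.0 * result.task_betas / baseline[None, :]
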