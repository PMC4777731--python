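"""Factorial experimental design and stochastic trial scheduling.

The experiment crosses three stimulus factors — motion pattern (static,
random, coherent), horizontal stimulus size (17, 33, 67, 100 degrees of
visual angle at a fixed 16:9 aspect) and stereoscopic depth (stereo,
non-stereo) — into 24 conditions. Each scanning run presents every
condition twice (48 trials of 3 s) in a rapid event-related sequence with
inter-stimulus intervals drawn from a truncated discrete Poisson law on
[2, 8] s calibrated to a 3.7-s mean, bracketed by 10-s blanks, on a fixed
170-volume grid at TR = 2 s.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

MOTIONS = ("static", "random", "coherent")
SIZES_DEG = (17, 33, 67, 100)
STEREO = ("nonstereo", "stereo")

TRIAL_DURATION_S = 3.0
LEAD_IN_S = 10.0
LEAD_OUT_S = 10.0
TR_S = 2.0
N_VOLUMES = 170
RUN_LENGTH_S = N_VOLUMES * TR_S  # nominal 340 s
N_RUNS = 8
REPEATS_PER_CONDITION = 2

ISI_MIN_S = 2
ISI_MAX_S = 8
ISI_TARGET_MEAN_S = 3.7

FIELD_WIDTH_DEG = 100.0
FIELD_HEIGHT_DEG = 67.7
MAX_DOTS = 800
DOT_SPEED_MIN_DPS = 0.12
DOT_SPEED_MAX_DPS = 3.9
# reference eccentricity: corner of the full 100 x 67.7 degree field
FIELD_CORNER_ECC_DEG = math.hypot(FIELD_WIDTH_DEG / 2.0, FIELD_HEIGHT_DEG / 2.0)


@dataclass(frozen=True, order=True)
class ConditionTriple:
    """One cell of the 3 x 4 x 2 factorial stimulus space."""

    motion: str
    size_deg: int
    stereo: str

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise ValueError(f"unknown motion pattern {self.motion!r}")
        if self.size_deg not in SIZES_DEG:
            raise ValueError(f"unknown stimulus size {self.size_deg!r}")
        if self.stereo not in STEREO:
            raise ValueError(f"unknown stereo level {self.stereo!r}")

    @property
    def label(self) -> str:
        return f"{self.motion}_{self.size_deg}_{self.stereo}"

    @classmethod
    def from_label(cls, label: str) -> "ConditionTriple":
        motion, size, stereo = label.rsplit("_", 2)
        return cls(motion, int(size), stereo)


def build_factorial_conditions(
    levels_per_factor: Sequence[Sequence],
) -> list[tuple]:
    """Cartesian product of factor levels, first factor fastest-varying.

    Returns an ordered list; the position of a tuple is its stable
    condition index.
    """
    if len(levels_per_factor) == 0:
        raise ValueError("at least one factor is required")
    for i, levels in enumerate(levels_per_factor):
        if len(levels) == 0:
            raise ValueError(f"factor {i} has no levels")
    # itertools.product varies the *last* factor fastest; reverse to make
    # the first factor fastest-varying, then restore tuple order.
    out = [
        tuple(reversed(combo))
        for combo in itertools.product(*reversed(list(levels_per_factor)))
    ]
    return out


@lru_cache(maxsize=1)
def conditions() -> tuple[ConditionTriple, ...]:
    """The canonical ordered 24-condition set.

    Index order: motion fastest-varying, then size, then stereo
    (index = 12*stereo_idx + 3*size_idx + motion_idx).
    """
    combos = build_factorial_conditions([MOTIONS, SIZES_DEG, STEREO])
    return tuple(ConditionTriple(m, s, st) for (m, s, st) in combos)


def condition_index(cond: ConditionTriple) -> int:
    return (
        STEREO.index(cond.stereo) * len(SIZES_DEG) * len(MOTIONS)
        + SIZES_DEG.index(cond.size_deg) * len(MOTIONS)
        + MOTIONS.index(cond.motion)
    )


# ---------------------------------------------------------------------------
# stimulus parameterization


@dataclass(frozen=True)
class StimulusSpec:
    """Dot-field parameters for one stimulus size."""

    size_deg: float
    aspect: float = 16.0 / 9.0
    dot_size_deg: float = 0.2
    dot_lifetime_s: float = 0.167
    v_min_dps: float = DOT_SPEED_MIN_DPS
    v_max_dps: float = DOT_SPEED_MAX_DPS
    disparity_gradient_deg: float = 3.77
    fixation_disparity_deg: float = 1.0
    stereo: bool = True

    @property
    def n_dots(self) -> int:
        return dot_count(self.size_deg)

    @property
    def disparity_range_deg(self) -> float:
        return self.disparity_gradient_deg if self.stereo else 0.0


def dot_count(size_deg: float) -> int:
    """Dot count proportional to stimulus area, 800 at the full 100-deg field."""
    if size_deg <= 0:
        raise ValueError("stimulus size must be positive")
    ratio = (size_deg / FIELD_WIDTH_DEG) ** 2  # fixed aspect: area ~ width^2
    return int(np.clip(round(MAX_DOTS * ratio), 0, MAX_DOTS))


def dot_speed(
    eccentricity_deg: float,
    field_max_eccentricity_deg: float = FIELD_CORNER_ECC_DEG,
) -> float:
    """Dot speed in deg/s, linear in eccentricity from 0.12 to 3.9 deg/s.

    The same mapping is used for all stimulus sizes, so the speed at a given
    retinal location is identical across sizes.
    """
    e = float(eccentricity_deg)
    e_max = float(field_max_eccentricity_deg)
    if e < 0:
        raise ValueError("eccentricity must be non-negative")
    if e > e_max:
        raise ValueError("eccentricity exceeds the field maximum")
    return DOT_SPEED_MIN_DPS + (DOT_SPEED_MAX_DPS - DOT_SPEED_MIN_DPS) * e / e_max


# ---------------------------------------------------------------------------
# ISI law


@dataclass(frozen=True)
class TruncatedPoissonISI:
    """Discrete Poisson ISI in whole seconds, truncated to [lo, hi].

    ``rate`` is calibrated so that the truncated mean matches
    ``ISI_TARGET_MEAN_S`` (a one-time numerical computation).
    """

    lo: int = ISI_MIN_S
    hi: int = ISI_MAX_S
    rate: float | None = None  # None -> calibrated for mean 3.7 s

    def __post_init__(self) -> None:
        if self.lo < ISI_MIN_S or self.hi > ISI_MAX_S or self.lo > self.hi:
            raise ValueError(
                f"ISI support [{self.lo}, {self.hi}] must lie within "
                f"[{ISI_MIN_S}, {ISI_MAX_S}] s"
            )

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    @property
    def probabilities(self) -> np.ndarray:
        lam = self.rate if self.rate is not None else calibrate_isi_rate()
        p = stats.poisson.pmf(self.support, lam)
        return p / p.sum()

    @property
    def mean(self) -> float:
        return float(self.support @ self.probabilities)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.probabilities)


def _truncated_poisson_mean(lam: float) -> float:
    k = np.arange(ISI_MIN_S, ISI_MAX_S + 1)
    p = stats.poisson.pmf(k, lam)
    return float((k * p).sum() / p.sum())


@lru_cache(maxsize=8)
def calibrate_isi_rate(target_mean_s: float = ISI_TARGET_MEAN_S) -> float:
    """Poisson rate whose [2, 8]-truncated mean equals ``target_mean_s``."""
    return float(
        optimize.brentq(
            lambda lam: _truncated_poisson_mean(lam) - target_mean_s, 0.05, 30.0
        )
    )


# ---------------------------------------------------------------------------
# trial schedules


@dataclass
class TrialTable:
    """Per-run trial schedule: onsets, durations and condition labels."""

    run_id: int
    events: pd.DataFrame  # columns: onset, duration, trial_type, condition_index
    n_volumes: int = N_VOLUMES
    tr: float = TR_S
    realized_length_s: float = RUN_LENGTH_S

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return self.events["onset"].to_numpy(float)

    @property
    def condition_indices(self) -> np.ndarray:
        return self.events["condition_index"].to_numpy(int)


def _order_without_adjacent_repeats(
    n_conditions: int, repeats: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    base = np.repeat(np.arange(n_conditions), repeats)
    for _ in range(max_tries):
        order = rng.permutation(base)
        if n_conditions == 1 or not np.any(order[1:] == order[:-1]):
            return order
    raise RuntimeError("could not build a schedule without back-to-back repeats")


def generate_run_schedule(
    conds: Sequence[ConditionTriple] | None = None,
    repeats_per_condition: int = REPEATS_PER_CONDITION,
    isi_law: TruncatedPoissonISI | None = None,
    seed: int | np.random.Generator = 0,
    run_id: int = 1,
) -> TrialTable:
    """One seeded event-related run schedule.

    Condition order is a seeded permutation constrained to avoid
    back-to-back repeats of the same condition (an approximation to the
    unspecified counterbalancing scheme). ISIs are redrawn until the run,
    including its 10-s lead-out blank, fits the fixed 170-volume grid.
    """
    if conds is None:
        conds = conditions()
    if len(conds) == 0:
        raise ValueError("need at least one condition")
    if repeats_per_condition < 1:
        raise ValueError("repeats_per_condition must be >= 1")
    isi_law = isi_law or TruncatedPoissonISI()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    n_trials = len(conds) * repeats_per_condition
    order = _order_without_adjacent_repeats(len(conds), repeats_per_condition, rng)

    max_isi_sum = (
        RUN_LENGTH_S - LEAD_IN_S - LEAD_OUT_S - n_trials * TRIAL_DURATION_S
    )
    for _ in range(1000):
        isis = isi_law.sample(n_trials - 1, rng)
        if isis.sum() <= max_isi_sum:
            break
    else:  # pragma: no cover - astronomically unlikely at defaults
        raise RuntimeError("could not fit the trial sequence into the run grid")

    onsets = LEAD_IN_S + np.concatenate(
        [[0.0], np.cumsum(isis + TRIAL_DURATION_S)]
    )
    rows = []
    for onset, ci in zip(onsets, order):
        cond = conds[ci]
        rows.append(
            {
                "onset": float(onset),
                "duration": TRIAL_DURATION_S,
                "trial_type": cond.label,
                "condition_index": condition_index(cond)
                if isinstance(cond, ConditionTriple)
                else int(ci),
            }
        )
    events = pd.DataFrame(rows)
    realized = float(onsets[-1] + TRIAL_DURATION_S + LEAD_OUT_S)
    return TrialTable(
        run_id=run_id, events=events, realized_length_s=realized
    )


def generate_subject_schedules(
    n_runs: int = N_RUNS, seed: int = 0, **kwargs
) -> list[TrialTable]:
    """All runs for one subject, one child seed per run."""
    root = np.random.SeedSequence(seed)
    return [
        generate_run_schedule(
            seed=np.random.default_rng(child), run_id=i + 1, **kwargs
        )
        for i, child in enumerate(root.spawn(n_runs))
    ]


def validate_trial_table(
    table: TrialTable,
    conds: Sequence[ConditionTriple] | None = None,
    repeats_per_condition: int = REPEATS_PER_CONDITION,
) -> None:
    """Raise ValueError if a schedule violates the design invariants."""
    if conds is None:
        conds = conditions()
    ev = table.events
    onsets = ev["onset"].to_numpy(float)
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("onsets must be strictly increasing")
    if not np.allclose(ev["duration"], TRIAL_DURATION_S):
        raise ValueError("all trial durations must be 3 s")
    counts = ev["condition_index"].value_counts()
    expected = {condition_index(c) for c in conds}
    if set(counts.index) != expected or not (counts == repeats_per_condition).all():
        raise ValueError(
            f"each condition must appear exactly {repeats_per_condition} times"
        )
    gaps = onsets[1:] - (onsets[:-1] + TRIAL_DURATION_S)
    if np.any(gaps < ISI_MIN_S) or np.any(gaps > ISI_MAX_S):
        raise ValueError("inter-trial gaps must lie in [2, 8] s")
    if onsets[0] < LEAD_IN_S:
        raise ValueError("first onset must be at or after the 10-s lead-in")
    run_len = table.n_volumes * table.tr
    if onsets[-1] + TRIAL_DURATION_S + LEAD_OUT_S > run_len:
        raise ValueError("run must end with at least 10 s of blank")


def design_manifest(tables: Iterable[TrialTable], seed: int | None = None) -> dict:
    """JSON-serializable summary of a generated design."""
    tables = list(tables)
    return {
        "factors": {
            "motion": list(MOTIONS),
            "size_deg": list(SIZES_DEG),
            "stereo": list(STEREO),
        },
        "condition_order": "motion fastest-varying, then size, then stereo",
        "n_conditions": len(conditions()),
        "repeats_per_condition": REPEATS_PER_CONDITION,
        "tr_s": TR_S,
        "n_volumes": N_VOLUMES,
        "seed": seed,
        "runs": [
            {
                "run_id": t.run_id,
                "n_trials": len(t),
                "realized_length_s": t.realized_length_s,
            }
            for t in tables
        ],
    }
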