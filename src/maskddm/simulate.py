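"""Synthetic participants and cohorts.

Choices and response times are generated by Euler-Maruyama simulation of
the collapsing-bound diffusion, trial by trial: evidence starts at
``z * a``, drifts at the condition's mean rate with unit noise, and is
absorbed at ``+/- a * exp(-tau * t)``.  The response time is the crossing
time plus the condition's non-decision time; a trial with no crossing
before the 2.3 s deadline (net of non-decision time) is a miss.

A cohort draws each participant's true parameters from independent
normal distributions -- by default the group means and SDs of the fitted
full model -- truncated to the parameter space (positive threshold,
collapse rate and non-decision times; starting point strictly inside the
boundaries in both conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import em_sample
from .design import DEADLINE_S, build_design
from .models import DDMParams, GROUP_MEANS, GROUP_SDS, drift_rate, nondecision, start_point

__all__ = [
    "CohortSpec",
    "simulate_trial",
    "simulate_condition",
    "simulate_participant",
    "draw_cohort_params",
    "simulate_cohort",
]

TRIAL_COLUMNS = ["participant", "block", "mask", "emotion", "filler", "choice", "rt_s"]

_CHOICE_LABEL = {1: "unfriendly", 0: "friendly", -1: "miss"}


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_condition(params: DDMParams, mask: int, emotion: int, n: int,
                       rng: np.random.Generator, dt: float = 0.001,
                       deadline: float = DEADLINE_S) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` trials of one mask-by-emotion cell.

    Returns ``(choice, rt)`` where choice is 1 ('unfriendly'), 0
    ('friendly') or -1 (miss) and rt is in seconds from stimulus onset
    (nan for misses).
    """
    if dt <= 0:
        raise ValueError("Euler-Maruyama step size must be positive")
    params.validate()
    k = emotion / 100.0
    v = drift_rate(params, k, mask)
    z = start_point(params, mask)
    ter = nondecision(params, mask)
    t_budget = deadline - ter
    if t_budget <= 0:
        return np.full(n, -1, dtype=np.int8), np.full(n, np.nan)
    choice, t_dec = em_sample(float(v), float(params.a), float(params.tau),
                              float(z * params.a), float(dt), float(t_budget),
                              int(n), _subseed(rng))
    rt = t_dec + ter
    rt[choice == -1] = np.nan
    return choice, rt


def simulate_trial(params: DDMParams, mask: int, emotion: int,
                   rng: np.random.Generator, dt: float = 0.001) -> tuple[str, float]:
    """One trial; returns (choice label, rt in s or nan)."""
    choice, rt = simulate_condition(params, mask, emotion, 1, rng, dt=dt)
    return _CHOICE_LABEL[int(choice[0])], float(rt[0])


def simulate_participant(params: DDMParams, design: pd.DataFrame, seed: int,
                         participant_id: int = 1, dt: float = 0.001) -> pd.DataFrame:
    """One trial record per design row, in design order."""
    rng = np.random.default_rng(seed)
    choice = np.empty(len(design), dtype=np.int8)
    rt = np.empty(len(design))
    # cells are simulated vectorized in a fixed order so results are
    # reproducible regardless of the shuffle within the design
    cells = sorted(set(zip(design["mask"], design["emotion"])))
    for mask, emo in cells:
        idx = ((design["mask"] == mask) & (design["emotion"] == emo)).to_numpy()
        c, r = simulate_condition(params, int(mask), int(emo), int(idx.sum()), rng, dt=dt)
        choice[idx] = c
        rt[idx] = r
    out = design[["block", "mask", "emotion", "filler"]].copy()
    out.insert(0, "participant", participant_id)
    out["choice"] = [_CHOICE_LABEL[int(c)] for c in choice]
    out["rt_s"] = rt
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Population model for a synthetic cohort.

    Defaults reproduce the study conditions: 136 analyzable participants
    whose true parameters scatter around the group-mean full-model fit.
    """

    n_participants: int = 136
    means: DDMParams = field(default_factory=lambda: GROUP_MEANS)
    sds: DDMParams = field(default_factory=lambda: GROUP_SDS)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(s < 0 for s in self.sds.to_array()):
            raise ValueError("population SDs must be >= 0")


def _valid_params(p: DDMParams) -> bool:
    return (p.a > 0 and p.tau > 0 and p.ter0 > 0
            and p.ter0 + p.ter_mask >= 0
            and abs(p.z0) < 1 and abs(p.z0 + p.z_mask) < 1)


def draw_cohort_params(spec: CohortSpec, max_tries: int = 1000) -> list[DDMParams]:
    """Truncated-normal draws of per-participant true parameters."""
    rng = np.random.default_rng(spec.seed)
    mu = spec.means.to_array()
    sd = spec.sds.to_array()
    out: list[DDMParams] = []
    for _ in range(spec.n_participants):
        for attempt in range(max_tries):
            p = DDMParams.from_array(rng.normal(mu, sd))
            if _valid_params(p):
                out.append(p)
                break
        else:
            raise RuntimeError(
                "could not draw valid cohort parameters; the truncation "
                "region is (nearly) infeasible for the given means/SDs")
    return out


def simulate_cohort(spec: CohortSpec, dt: float = 0.001
                    ) -> tuple[pd.DataFrame, list[DDMParams]]:
    """Full synthetic cohort: trials for every participant + true params.

    Every participant gets their own session design (fresh shuffle) and
    their own simulation stream, all derived from ``spec.seed``.
    Returns the concatenated trial table and the list of true parameters.
    """
    rng = np.random.default_rng(spec.seed)
    truths = draw_cohort_params(spec)
    tables = []
    for pid, params in enumerate(truths, start=1):
        design = build_design(_subseed(rng))
        tables.append(simulate_participant(params, design, _subseed(rng),
                                           participant_id=pid, dt=dt))
    return pd.concat(tables, ignore_index=True), truths
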