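"""Model family for the masked-face friendliness judgment task.

A single parameter vector maps each experimental condition -- mask C in
{0, 1} and signed stimulus emotion k (a fraction in [-1, 1], negative =
happy, positive = angry) -- onto the generic diffusion-process parameters
(v, a, tau, z, Ter):

    v   = vc0 + C*vc_mask + k*(v_slope0 + C*v_slope_mask)
    Ter = ter0 + C*ter_mask
    z   = z0  + C*z_mask

with a single decision threshold ``a`` and collapse rate ``tau`` shared
between the masked and unmasked conditions.  The upper threshold is the
'unfriendly' response; positive drift, starting point or drift criterion
push choices toward 'unfriendly'.

The starting point z is a signed *fraction* of the initial threshold:
the accumulator starts at x0 = z * a, so |z| < 1.

Four nested models differ only in which mask-bias terms are free:

    null        vc_mask = z_mask = 0  (no bias effect of the mask)
    reduced_vc  z_mask = 0            (perceptual, drift-criterion bias)
    reduced_z   vc_mask = 0           (preconceptual, starting-point bias)
    full_vc_z   both free
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "DDMParams",
    "ModelSpec",
    "MODEL_FAMILY",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "GROUP_MEANS",
    "GROUP_SDS",
    "MAIN_EMOTIONS",
    "FILLER_EMOTIONS",
    "drift_rate",
    "nondecision",
    "start_point",
    "condition_table",
]

#: the six analyzable signed emotion levels, in raw percent units
MAIN_EMOTIONS = (-60, -40, -10, 10, 40, 60)
#: filler levels, present in the design but excluded from model fitting
FILLER_EMOTIONS = (-20, 20)


@dataclass(frozen=True)
class DDMParams:
    """The ten free parameters of the full model.

    Times are in seconds; ``z0``/``z_mask`` are fractions of the initial
    threshold; drift terms are in evidence units per second with the
    diffusion (noise) coefficient fixed at 1.
    """

    a: float = 1.08          # initial decision threshold (+/- a)
    tau: float = 1.29        # exponential bound-collapse rate, 1/s
    ter0: float = 0.380      # non-decision time, unmasked, s
    ter_mask: float = 0.014  # additive mask effect on Ter, s
    vc0: float = 0.17        # drift criterion (intercept), unmasked
    vc_mask: float = -0.28   # mask effect on the drift criterion
    v_slope0: float = 5.68   # drift per unit emotion fraction, unmasked
    v_slope_mask: float = -1.78  # mask effect on the slope
    z0: float = -0.06        # starting-point fraction, unmasked
    z_mask: float = 0.10     # mask effect on the starting point

    def validate(self) -> None:
        if not self.a > 0:
            raise ValueError(f"threshold a must be positive, got {self.a}")
        if self.tau < 0:
            raise ValueError(f"collapse rate tau must be >= 0, got {self.tau}")
        if not self.ter0 > 0:
            raise ValueError(f"ter0 must be positive, got {self.ter0}")
        if self.ter0 + self.ter_mask < 0:
            raise ValueError("masked non-decision time ter0 + ter_mask is negative")
        if abs(self.z0) >= 1 or abs(self.z0 + self.z_mask) >= 1:
            raise ValueError("starting-point fraction must satisfy |z| < 1 in both conditions")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "DDMParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


PARAM_NAMES = tuple(f.name for f in fields(DDMParams))

#: group means (SDs) of the full-model fits that the synthetic cohort emulates
GROUP_MEANS = DDMParams()
GROUP_SDS = DDMParams(
    a=0.23, tau=0.50, ter0=0.061, ter_mask=0.026,
    vc0=0.36, vc_mask=0.53, v_slope0=0.11, v_slope_mask=1.10,
    z0=0.08, z_mask=0.11,
)

#: fitting box constraints; generous brackets around plausible values
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (0.3, 5.0),
    "tau": (0.0, 10.0),
    "ter0": (0.1, 1.0),
    "ter_mask": (-0.2, 0.2),
    "vc0": (-5.0, 5.0),
    "vc_mask": (-5.0, 5.0),
    "v_slope0": (-20.0, 20.0),
    "v_slope_mask": (-20.0, 20.0),
    "z0": (-0.9, 0.9),
    "z_mask": (-0.9, 0.9),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free; the rest are pinned to zero.

    All four members of the family share the eight null-model parameters;
    they differ in whether the mask may shift the drift criterion
    (``vc_mask``) and/or the starting point (``z_mask``).
    """

    name: str
    pinned: tuple[str, ...] = ()

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.pinned)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def pin(self, params: DDMParams) -> DDMParams:
        """Return a copy with the pinned fields forced to zero."""
        return replace(params, **{n: 0.0 for n in self.pinned})

    def params_from_free(self, x: np.ndarray) -> DDMParams:
        d = dict.fromkeys(self.pinned, 0.0)
        d.update(zip(self.free_names, map(float, x)))
        return DDMParams(**d)

    def free_bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[n] for n in self.free_names]


MODEL_FAMILY: dict[str, ModelSpec] = {
    "null": ModelSpec("null", pinned=("vc_mask", "z_mask")),
    "reduced_vc": ModelSpec("reduced_vc", pinned=("z_mask",)),
    "reduced_z": ModelSpec("reduced_z", pinned=("vc_mask",)),
    "full_vc_z": ModelSpec("full_vc_z", pinned=()),
}


def drift_rate(p: DDMParams, k: float, mask: int) -> float:
    """Mean drift for emotion fraction ``k`` under mask condition ``mask``.

    ``k`` must already be on the fraction scale (raw percent / 100), so the
    six main levels are +/-0.10, +/-0.40, +/-0.60.
    """
    if abs(k) > 1:
        raise ValueError(f"emotion k must be a fraction in [-1, 1], got {k}")
    c = int(mask)
    return p.vc0 + c * p.vc_mask + k * (p.v_slope0 + c * p.v_slope_mask)


def nondecision(p: DDMParams, mask: int) -> float:
    """Non-decision time in seconds for the given mask condition."""
    ter = p.ter0 + int(mask) * p.ter_mask
    if ter < 0:
        raise ValueError(f"negative non-decision time {ter}")
    return ter


def start_point(p: DDMParams, mask: int) -> float:
    """Starting-point fraction (of the initial threshold) for the condition."""
    z = p.z0 + int(mask) * p.z_mask
    if abs(z) >= 1:
        raise ValueError(f"|starting-point fraction| must be < 1, got {z}")
    return z


@dataclass(frozen=True)
class ConditionCell:
    mask: int
    emotion: int            # raw percent label
    v: float
    a: float
    tau: float
    z: float
    ter: float


def condition_table(p: DDMParams, spec: ModelSpec | None = None,
                    emotions: tuple[int, ...] = MAIN_EMOTIONS) -> list[ConditionCell]:
    """Engine parameterizations for every analyzable mask-by-emotion cell.

    Threshold ``a`` and collapse rate ``tau`` are shared across all cells.
    If a :class:`ModelSpec` is given, its pinned fields must already be zero
    in ``p`` (the fit parameterization owns the pinning).
    """
    if spec is not None:
        for n in spec.pinned:
            if getattr(p, n) != 0.0:
                raise ValueError(f"{spec.name} model requires {n} == 0, got {getattr(p, n)}")
    cells = []
    for mask in (0, 1):
        for emo in emotions:
            k = emo / 100.0
            cells.append(ConditionCell(
                mask=mask, emotion=emo,
                v=drift_rate(p, k, mask), a=p.a, tau=p.tau,
                z=start_point(p, mask), ter=nondecision(p, mask),
            ))
    return cells
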