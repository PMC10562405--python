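"""First-passage-time machinery for the collapsing-bound diffusion.

The decision process is a one-dimensional diffusion with constant drift v
and unit noise, started at ``x0 = z * a`` between absorbing boundaries at
``+/- a * exp(-tau * t)``.  The upper boundary is the 'unfriendly'
response.  :func:`solve_fptd` forward-evolves the evidence distribution
with a Crank-Nicolson scheme and harvests boundary flux into discretized
first-passage-time densities; :func:`analytic_fptd_constant_bounds`
evaluates the classical infinite-series solution for the ``tau = 0`` case
and serves as an independent oracle.

All times are in seconds, measured from the start of evidence
accumulation; adding non-decision time is the caller's business (see
:func:`trial_loglik`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import cn_fptd

__all__ = [
    "EngineConfig",
    "FPTD",
    "bound",
    "solve_fptd",
    "analytic_fptd_constant_bounds",
    "upper_absorption_probability",
    "trial_loglik",
    "LIKELIHOOD_FLOOR",
]

#: density floor (per second) for RTs outside the representable support
LIKELIHOOD_FLOOR = 1e-10


@dataclass(frozen=True)
class EngineConfig:
    """Discretization of the Fokker-Planck solve.

    dt and dx trade accuracy for speed; t_max must cover the longest
    decision time the deadline allows (2.3 s response window minus the
    smallest admissible non-decision time).
    """

    dt: float = 0.005    # time step, s
    dx: float = 0.005    # evidence-space step per unit threshold (h = a*dx)
    t_max: float = 2.3   # horizon of the solve, s
    scheme: str = "crank-nicolson"

    def __post_init__(self):
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("EngineConfig: dt and dx must be positive")
        if self.t_max <= 0:
            raise ValueError("EngineConfig: t_max must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def time_grid(self) -> np.ndarray:
        """Bin centers of the absorbed-mass histogram."""
        return (np.arange(self.n_steps) + 0.5) * self.dt


@dataclass(frozen=True)
class FPTD:
    """Discretized first-passage-time densities for both boundaries.

    ``upper_density[i]`` is the probability density (per second) of
    crossing the upper ('unfriendly') boundary at ``time_grid[i]``;
    likewise for ``lower_density``.  ``undecided_mass`` is the probability
    of no crossing before ``time_grid[-1] + dt/2``.
    """

    time_grid: np.ndarray
    upper_density: np.ndarray
    lower_density: np.ndarray
    undecided_mass: float

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def prob_upper(self) -> float:
        return float(self.upper_density.sum() * self.dt)

    def prob_lower(self) -> float:
        return float(self.lower_density.sum() * self.dt)

    def total_probability(self) -> float:
        return self.prob_upper() + self.prob_lower() + self.undecided_mass


def bound(a: float, tau: float, t) -> np.ndarray | float:
    """Collapsing threshold ``a * exp(-tau * t)`` at time(s) t."""
    if a <= 0:
        raise ValueError("threshold a must be positive")
    if tau < 0:
        raise ValueError("collapse rate tau must be >= 0")
    return a * np.exp(-tau * np.asarray(t, dtype=float))


def solve_fptd(v: float, a: float, tau: float, z: float,
               config: EngineConfig | None = None) -> FPTD:
    """Crank-Nicolson solve of the first-passage problem.

    Parameters are the per-condition diffusion parameters; ``z`` is the
    starting point as a signed fraction of the initial threshold.  Raises
    if the start lies within one spatial cell of a boundary, where the
    discretized initial condition cannot be represented.
    """
    if config is None:
        config = EngineConfig()
    if abs(z) >= 1:
        raise ValueError(f"|z| must be < 1, got {z}")
    bound(a, tau, 0.0)  # validates a, tau
    n_cells = max(int(round(2.0 / config.dx)), 8)
    h = 2.0 * a / n_cells
    x0 = z * a
    if x0 - (-a) < h or a - x0 < h:
        raise ValueError(
            f"starting point {x0:.4f} is within one grid cell ({h:.4f}) of a "
            "boundary; refine dx or move z")
    upper, lower, undecided = cn_fptd(
        float(v), float(a), float(tau), float(x0),
        float(config.dt), float(config.dx), config.n_steps)
    # tiny negative masses from the CN transient are clipped into the
    # undecided remainder, preserving total probability exactly
    undecided += upper[upper < 0].sum() + lower[lower < 0].sum()
    return FPTD(
        time_grid=config.time_grid,
        upper_density=np.maximum(upper, 0.0) / config.dt,
        lower_density=np.maximum(lower, 0.0) / config.dt,
        undecided_mass=float(undecided),
    )


def upper_absorption_probability(v: float, a: float, z: float) -> float:
    """Closed-form P(hit +a before -a) for constant bounds, unit noise."""
    if v == 0:
        return 0.5 * (1.0 + z)
    y = (z + 1.0) * a          # start measured from the lower boundary
    length = 2.0 * a
    return float(np.expm1(-2.0 * v * y) / np.expm1(-2.0 * v * length))


def analytic_fptd_constant_bounds(v: float, a: float, z: float,
                                  t_grid: np.ndarray,
                                  n_terms: int = 400,
                                  tol: float = 1e-12) -> FPTD:
    """Infinite-series first-passage densities for constant bounds (tau=0).

    Uses the classical large-time eigenfunction expansion for a drifted
    Brownian motion on (0, L) with absorbing ends, truncated once the
    remaining terms are below ``tol`` at the smallest requested time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise ValueError("t_grid must be strictly positive")
    L = 2.0 * a
    y = (z + 1.0) * a  # distance from the lower boundary

    def one_sided(mu: float, y0: float) -> np.ndarray:
        # density of absorption at 0 for drift mu, start y0 on (0, L)
        n = np.arange(1, n_terms + 1)[:, None]
        t = t_grid[None, :]
        series = n * np.sin(np.pi * n * y0 / L) * np.exp(-(n ** 2) * np.pi ** 2 * t / (2 * L ** 2))
        tail = np.abs(series[-1]).max()
        if tail > tol:
            raise ValueError(
                f"series not converged with {n_terms} terms (tail {tail:.2e}); "
                "increase n_terms or start t_grid later")
        pref = (np.pi / L ** 2) * np.exp(-mu * y0 - mu ** 2 * t_grid / 2.0)
        return np.clip(pref * series.sum(axis=0), 0.0, None)

    lower = one_sided(v, y)                 # hit the lower boundary (-a)
    upper = one_sided(-v, L - y)            # reflect: hit the upper (+a)
    dt = float(t_grid[1] - t_grid[0]) if t_grid.size > 1 else float(t_grid[0])
    undecided = max(0.0, 1.0 - (upper.sum() + lower.sum()) * dt)
    return FPTD(time_grid=t_grid, upper_density=upper,
                lower_density=lower, undecided_mass=undecided)


def trial_loglik(fptd: FPTD, ter: float, choice: int, rt: float) -> float:
    """Log-density of one observed (choice, rt) pair.

    ``choice`` is 1 for 'unfriendly' (upper boundary), 0 for 'friendly'.
    The decision-time density is interpolated at ``rt - ter``; RTs at or
    below the non-decision time, or beyond the solver horizon, score the
    floor density rather than -inf.
    """
    dens = fptd.upper_density if choice else fptd.lower_density
    td = rt - ter
    if td <= 0 or td > fptd.time_grid[-1] + 0.5 * fptd.dt:
        return float(np.log(LIKELIHOOD_FLOOR))
    d = float(np.interp(td, fptd.time_grid, dens))
    return float(np.log(max(d, LIKELIHOOD_FLOOR)))


def trials_loglik(fptd: FPTD, ter: float, choices: np.ndarray,
                  rts: np.ndarray) -> float:
    """Vectorized sum of :func:`trial_loglik` over one condition cell."""
    td = np.asarray(rts, dtype=float) - ter
    choices = np.asarray(choices)
    dens = np.where(
        choices == 1,
        np.interp(td, fptd.time_grid, fptd.upper_density),
        np.interp(td, fptd.time_grid, fptd.lower_density),
    )
    out_of_support = (td <= 0) | (td > fptd.time_grid[-1] + 0.5 * fptd.dt)
    dens = np.where(out_of_support, LIKELIHOOD_FLOOR, np.maximum(dens, LIKELIHOOD_FLOOR))
    return float(np.log(dens).sum())
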