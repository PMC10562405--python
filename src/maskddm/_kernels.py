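"""Compiled numerical kernels.

Two hot loops live here, both jit-compiled:

* a Crank-Nicolson forward solver for the Fokker-Planck equation of a
  constant-drift diffusion between two exponentially collapsing absorbing
  boundaries, returning the probability mass absorbed at each boundary per
  time step (the first-passage-time densities up to a 1/dt factor);
* a Euler-Maruyama path sampler for the same process.

Everything upstream (parameter mapping, likelihoods, fitting) is plain
numpy/scipy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DIFFUSION = 1.0  # noise coefficient sigma; the scaling convention is sigma = 1


@njit(cache=True)
def cn_fptd(v, a, tau, x0, dt, dx, n_steps):  # pragma: no cover - compiled
    """Crank-Nicolson first-passage solve.

    Evidence mass lives on a fixed grid of N+1 nodes spanning [-a, a];
    nodes outside the current bound +/- a*exp(-tau*t) are absorbing.  Mass
    leaving the active window within a step is harvested into that step's
    absorbed-mass entry; interior loss through the Dirichlet edges is split
    between the two boundaries in proportion to the discrete outgoing flux
    and rescaled so that total probability is conserved exactly.

    Returns (upper, lower, undecided): mass absorbed at the unfriendly
    (upper) and friendly (lower) boundary during each step, and the mass
    still in play after the last step.
    """
    # grid size depends on dx only (dx is the spacing per unit threshold),
    # so the cell count -- and with it the discretization texture of the
    # likelihood -- does not jump as the threshold parameter varies
    N = int(round(2.0 / dx))
    if N < 8:
        N = 8
    h = 2.0 * a / N
    D = 0.5 * DIFFUSION * DIFFUSION

    p = np.zeros(N + 1)
    # linear split of the point mass at x0 over its two neighbouring nodes
    pos = (x0 + a) / h
    j0 = int(np.floor(pos))
    frac = pos - j0
    p[j0] += 1.0 - frac
    p[j0 + 1] += frac

    upper = np.zeros(n_steps)
    lower = np.zeros(n_steps)

    alpha = D * dt / (h * h)
    beta = v * dt / (2.0 * h)

    # Thomas-algorithm work arrays (outer and inner window solves)
    cp = np.zeros(N + 1)
    rhs = np.zeros(N + 1)
    rhs_in = np.zeros(N + 1)
    q_in = np.zeros(N + 1)

    lo = 1
    hi = N - 1
    for s in range(n_steps):
        # Rannacher startup: the first output step runs as four fully
        # implicit quarter-steps, killing the delta's checkerboard mode
        # that Crank-Nicolson barely damps; later steps are plain CN
        if s == 0:
            nsub, theta = 4, 1.0
        else:
            nsub, theta = 1, 0.5
        a_s = alpha / nsub
        b_s = beta / nsub
        cl = theta * (a_s + b_s)      # implicit coupling to the left
        cr = theta * (a_s - b_s)      # implicit coupling to the right
        el = (1.0 - theta) * (a_s + b_s)  # explicit counterparts
        er = (1.0 - theta) * (a_s - b_s)
        ed = (1.0 - theta) * 2.0 * a_s
        diag = 1.0 + theta * 2.0 * a_s
        t_new = (s + 1) * dt
        # distance of the bound from the domain edge, in (fractional) cells;
        # independent of a, so the collapse path does not snap with the grid
        g = (a - a * np.exp(-tau * t_new)) / h
        m = int(np.floor(g))
        w = g - m
        lo_new = m + 1
        hi_new = N - 1 - m
        if lo_new < 1:
            lo_new = 1
            hi_new = N - 1
            w = 0.0
        # harvest nodes the collapsing bound has swallowed
        for j in range(lo, lo_new):
            lower[s] += p[j]
            p[j] = 0.0
        for j in range(hi_new + 1, hi + 1):
            upper[s] += p[j]
            p[j] = 0.0
        lo = lo_new
        hi = hi_new
        if hi < lo:
            break

        mass_before = 0.0
        for j in range(lo, hi + 1):
            mass_before += p[j]
        if mass_before <= 0.0:
            continue

        # outgoing-flux weights from the pre-step edge values (clamped:
        # transient CN oscillations can leave tiny negative edge values)
        w_lo = max(D * p[lo] / h + max(-v, 0.0) * p[lo], 0.0)
        w_up = max(D * p[hi] / h + max(v, 0.0) * p[hi], 0.0)

        for _ in range(nsub):
            # outer window [lo, hi]: explicit part, Dirichlet zero outside
            for j in range(lo, hi + 1):
                left = p[j - 1] if j - 1 >= lo else 0.0
                right = p[j + 1] if j + 1 <= hi else 0.0
                rhs[j] = p[j] + el * left - ed * p[j] + er * right
            # implicit part: tridiagonal Thomas sweep
            cp[lo] = -cr / diag
            rhs[lo] = rhs[lo] / diag
            for j in range(lo + 1, hi + 1):
                mm = diag + cl * cp[j - 1]
                cp[j] = -cr / mm
                rhs[j] = (rhs[j] + cl * rhs[j - 1]) / mm
            for j in range(hi - 1, lo - 1, -1):
                rhs[j] = rhs[j] - cp[j] * rhs[j + 1]
            # rhs[lo..hi] now holds the outer-window solution

            if w > 0.0 and hi - 1 >= lo + 1:
                # inner window [lo+1, hi-1]: the bound sits a fraction w
                # past the outer node layer; blending the two Dirichlet
                # solutions makes the solve continuous in the bound position
                li = lo + 1
                hii = hi - 1
                for j in range(li, hii + 1):
                    left = p[j - 1] if j - 1 >= li else 0.0
                    right = p[j + 1] if j + 1 <= hii else 0.0
                    rhs_in[j] = p[j] + el * left - ed * p[j] + er * right
                cp[li] = -cr / diag
                q_in[li] = rhs_in[li] / diag
                for j in range(li + 1, hii + 1):
                    mm = diag + cl * cp[j - 1]
                    cp[j] = -cr / mm
                    q_in[j] = (rhs_in[j] + cl * q_in[j - 1]) / mm
                for j in range(hii - 1, li - 1, -1):
                    q_in[j] = q_in[j] - cp[j] * q_in[j + 1]
                p[lo] = (1.0 - w) * rhs[lo]
                p[hi] = (1.0 - w) * rhs[hi]
                for j in range(li, hii + 1):
                    p[j] = (1.0 - w) * rhs[j] + w * q_in[j]
            else:
                for j in range(lo, hi + 1):
                    p[j] = rhs[j]

        mass_after = 0.0
        for j in range(lo, hi + 1):
            mass_after += p[j]
        loss = mass_before - mass_after
        if loss != 0.0:
            wsum = w_lo + w_up
            if wsum > 0.0:
                upper[s] += loss * w_up / wsum
                lower[s] += loss * w_lo / wsum
            else:
                upper[s] += 0.5 * loss
                lower[s] += 0.5 * loss

    undecided = 0.0
    for j in range(N + 1):
        undecided += p[j]
    return upper, lower, undecided


@njit(cache=True)
def em_sample(v, a, tau, x0, dt, t_max, n, seed):  # pragma: no cover - compiled
    """Euler-Maruyama paths between collapsing absorbing bounds.

    Returns (choice, t_decide): choice is 1 for the upper (unfriendly)
    boundary, 0 for the lower, -1 if the path never crossed before t_max;
    t_decide is the crossing time (nan for non-crossers).
    """
    np.random.seed(seed)
    n_steps = int(np.ceil(t_max / dt))
    sqdt = np.sqrt(dt) * DIFFUSION
    var = dt * DIFFUSION * DIFFUSION
    choice = np.full(n, -1, dtype=np.int8)
    t_dec = np.full(n, np.nan)
    for i in range(n):
        x = x0
        b_old = a
        for s in range(n_steps):
            x_new = x + v * dt + sqdt * np.random.normal()
            t = (s + 1) * dt
            b = a * np.exp(-tau * t)
            if x_new >= b:
                choice[i] = 1
                t_dec[i] = t
                break
            elif x_new <= -b:
                choice[i] = 0
                t_dec[i] = t
                break
            # Brownian-bridge correction: the path may have touched a
            # boundary inside the step even though both endpoints are
            # interior; without it absorption is biased late by O(sqrt(dt))
            p_up = np.exp(-2.0 * (b_old - x) * (b - x_new) / var)
            p_lo = np.exp(-2.0 * (x + b_old) * (x_new + b) / var)
            u = np.random.random()
            if u < p_up:
                choice[i] = 1
                t_dec[i] = t
                break
            elif u > 1.0 - p_lo:
                choice[i] = 0
                t_dec[i] = t
                break
            x = x_new
            b_old = b
    return choice, t_dec
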