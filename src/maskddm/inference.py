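"""Per-participant maximum-likelihood fitting, model selection, recovery.

Each model in the family is fitted to one participant's analyzable
trials (main emotion levels, responded, not flagged invalid) by
maximizing the summed log first-passage densities over the 12
mask-by-emotion cells.  The search is a seeded differential-evolution
global stage followed by a bounded Nelder-Mead polish, so fits are
deterministic given the seed.  AIC/BIC model selection and the
simulate-and-refit parameter-recovery harness sit on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DEADLINE_S, balanced_design
from .engine import EngineConfig, FPTD, LIKELIHOOD_FLOOR, solve_fptd
from .models import (DDMParams, MODEL_FAMILY, ModelSpec, PARAM_BOUNDS,
                     PARAM_NAMES, condition_table, drift_rate, nondecision,
                     start_point, MAIN_EMOTIONS)
from .simulate import simulate_participant

__all__ = [
    "FitSettings",
    "FitResult",
    "fit_mle",
    "fit_all_models",
    "select_models",
    "goodness_of_fit",
    "parameter_recovery",
]

_BAD_LOGLIK = -1e9  # objective value for parameter sets outside the model space


@dataclass(frozen=True)
class FitSettings:
    """Optimizer and solver settings for one MLE fit.

    The search is a block-coordinate Nelder-Mead cascade from a
    data-informed start (empirical-logit psychometric slope and bias,
    fast-RT quantile for the non-decision time).  Most of the work runs
    on a coarsened solver grid -- the arg-max moves very little between
    grids -- with final polish cycles at full resolution.  The likelihood
    valley couples the drift-criterion and starting-point terms, so the
    cascade alternates full-space moves with dedicated searches over the
    bias block (vc0, vc_mask, z0, z_mask) and the shape block (a, tau,
    Ter terms).  Deterministic given ``seed`` (which only jitters the
    starting point).  Defaults keep one ten-parameter fit at 24,000
    trials around a minute on one core.
    """

    engine: EngineConfig = field(default_factory=EngineConfig)
    coarse_engine: EngineConfig = field(
        default_factory=lambda: EngineConfig(dt=0.01, dx=0.01))
    prestage_engine: EngineConfig = field(
        default_factory=lambda: EngineConfig(dt=0.02, dx=0.04))
    seed: int = 0
    coarse_cycles: int = 5       # block/full cycles on the prestage grid
    nm_full_maxiter: int = 1000
    nm_block_maxiter: int = 200
    cycle_tol: float = 2.0       # log-likelihood gain to keep cycling
    nm_fine_maxiter: int = 200   # single full-resolution polish

    def with_seed(self, seed: int) -> "FitSettings":
        return replace(self, seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "FitSettings":
        """Cheap preset for smoke runs and small demo cohorts."""
        return cls(seed=seed,
                   engine=EngineConfig(dt=0.01, dx=0.02),
                   coarse_engine=EngineConfig(dt=0.02, dx=0.04),
                   prestage_engine=EngineConfig(dt=0.02, dx=0.04),
                   coarse_cycles=2, nm_full_maxiter=400,
                   nm_block_maxiter=120, cycle_tol=5.0, nm_fine_maxiter=150)


@dataclass(frozen=True)
class FitResult:
    participant_id: int
    model: str
    params: DDMParams
    loglik: float
    n_free_params: int
    n_trials: int
    aic: float
    bic: float
    seed: int
    n_evaluations: int
    converged: bool

    def to_row(self) -> dict:
        row = {"participant": self.participant_id, "model": self.model,
               "loglik": self.loglik, "n_free": self.n_free_params,
               "n_trials": self.n_trials, "aic": self.aic, "bic": self.bic,
               "seed": self.seed, "n_evaluations": self.n_evaluations,
               "converged": self.converged}
        row.update(self.params.to_dict())
        return row


def _analyzable(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials[~trials["filler"].astype(bool)]
    if "valid" in t.columns:
        t = t[t["valid"]]
    else:
        t = t[t["choice"].ne("miss")]
    return t


class _Cell:
    """Pre-digested trial data for one mask-by-emotion cell.

    RTs are collapsed to unique values with multiplicities per response,
    which makes each likelihood evaluation O(unique RTs) instead of
    O(trials).
    """

    __slots__ = ("mask", "k", "rt_up", "cnt_up", "rt_lo", "cnt_lo", "n")

    def __init__(self, mask: int, k: float, choices: np.ndarray, rts: np.ndarray):
        self.mask = mask
        self.k = k
        self.rt_up, self.cnt_up = np.unique(rts[choices == 1], return_counts=True)
        self.rt_lo, self.cnt_lo = np.unique(rts[choices == 0], return_counts=True)
        self.n = int(len(rts))


def _cell_data(trials: pd.DataFrame) -> list[_Cell]:
    cells = []
    for mask in (0, 1):
        for emo in MAIN_EMOTIONS:
            sub = trials[(trials["mask"] == mask) & (trials["emotion"] == emo)]
            if len(sub) < 1:
                raise ValueError(f"no valid trials in cell mask={mask}, emotion={emo}")
            choices = sub["choice"].eq("unfriendly").to_numpy(dtype=np.int8)
            rts = sub["rt_s"].to_numpy(dtype=float)
            cells.append(_Cell(mask, emo / 100.0, choices, rts))
    return cells


def _weighted_loglik(fptd: FPTD, ter: float, rt_u: np.ndarray, cnt: np.ndarray,
                     dens: np.ndarray) -> float:
    if len(rt_u) == 0:
        return 0.0
    td = rt_u - ter
    d = np.interp(td, fptd.time_grid, dens)
    bad = (td <= 0) | (td > fptd.time_grid[-1] + 0.5 * fptd.dt)
    d = np.where(bad, LIKELIHOOD_FLOOR, np.maximum(d, LIKELIHOOD_FLOOR))
    return float((cnt * np.log(d)).sum())


def _dataset_loglik(x: np.ndarray, spec: ModelSpec, cells, engine: EngineConfig) -> float:
    p = spec.params_from_free(x)
    try:
        p.validate()
    except ValueError:
        return _BAD_LOGLIK
    # one FPTD per distinct (drift, start); a and tau are shared across cells
    total = 0.0
    cache: dict[tuple[float, float], FPTD] = {}
    for cell in cells:
        v = drift_rate(p, cell.k, cell.mask)
        z = start_point(p, cell.mask)
        ter = nondecision(p, cell.mask)
        key = (v, z)
        f = cache.get(key)
        if f is None:
            try:
                f = solve_fptd(v, p.a, p.tau, z, engine)
            except ValueError:
                return _BAD_LOGLIK
            cache[key] = f
        total += _weighted_loglik(f, ter, cell.rt_up, cell.cnt_up, f.upper_density)
        total += _weighted_loglik(f, ter, cell.rt_lo, cell.cnt_lo, f.lower_density)
    return total


#: strongly coupled parameter pairs, each refined by its own 2-d search
_BLOCKS = (("vc0", "z0"), ("vc_mask", "z_mask"), ("a", "tau"),
           ("ter0", "ter_mask"), ("vc0", "vc_mask", "z0", "z_mask"))

#: seeded-jitter scale for the informed start, per parameter
_START_JITTER = {"a": 0.08, "tau": 0.2, "ter0": 0.01, "ter_mask": 0.005,
                 "vc0": 0.05, "vc_mask": 0.05, "v_slope0": 0.3,
                 "v_slope_mask": 0.15, "z0": 0.02, "z_mask": 0.02}


def _informed_start(cells: list[_Cell], spec: ModelSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Data-driven starting vector for the free parameters.

    The choice fractions give empirical-logit slope/bias per condition;
    with roughly constant bounds the choice logit is about 2*a*v, which
    converts them into drift starts.  The non-decision time starts just
    below the fastest responses.  A small seeded jitter decorrelates
    starts across replicate fits.
    """
    a0, tau0 = 1.1, 1.0
    logit = {0: ([], []), 1: ([], [])}
    rt_all = []
    for c in cells:
        n_up = c.cnt_up.sum()
        n_lo = c.cnt_lo.sum()
        logit[c.mask][0].append(c.k)
        logit[c.mask][1].append(np.log((n_up + 0.5) / (n_lo + 0.5)))
        rt_all.append(np.repeat(c.rt_up, c.cnt_up))
        rt_all.append(np.repeat(c.rt_lo, c.cnt_lo))
    b = {}
    for mask in (0, 1):
        ks, ls = map(np.asarray, logit[mask])
        b1, b0 = np.polyfit(ks, ls, 1)
        b[mask] = (b0, b1)
    ter0 = float(np.clip(np.quantile(np.concatenate(rt_all), 0.01) - 0.05,
                         *PARAM_BOUNDS["ter0"]))
    start = DDMParams(
        a=a0, tau=tau0, ter0=ter0, ter_mask=0.0,
        vc0=b[0][0] / (2 * a0), vc_mask=(b[1][0] - b[0][0]) / (2 * a0),
        v_slope0=b[0][1] / (2 * a0), v_slope_mask=(b[1][1] - b[0][1]) / (2 * a0),
        z0=0.0, z_mask=0.0)
    x = np.array([getattr(start, n) for n in spec.free_names])
    x += rng.normal(0.0, [_START_JITTER[n] for n in spec.free_names])
    lo, hi = zip(*spec.free_bounds())
    return np.clip(x, np.array(lo) + 1e-3, np.array(hi) - 1e-3)


def fit_mle(trials: pd.DataFrame, spec: ModelSpec,
            settings: FitSettings | None = None,
            participant_id: int | None = None,
            extra_starts: tuple[DDMParams, ...] = ()) -> FitResult:
    """Maximum-likelihood fit of one model to one participant's trials.

    ``trials`` may be raw or preprocessed; fillers, misses and invalid
    trials are dropped here.  Deterministic given ``settings.seed``.
    ``extra_starts`` (e.g. the fitted parameters of a nested model) are
    tried as additional polish starts, which guarantees the nested-model
    likelihood ordering when fits are chained with :func:`fit_all_models`.
    """
    if settings is None:
        settings = FitSettings()
    t = _analyzable(trials)
    if participant_id is None:
        pid = int(t["participant"].iloc[0]) if "participant" in t.columns and len(t) else 0
    else:
        pid = participant_id
    cells = _cell_data(t)
    n_trials = int(sum(c.n for c in cells))
    bounds = spec.free_bounds()
    names = list(spec.free_names)
    n_eval = 0

    def make_nll(engine: EngineConfig):
        def nll(x: np.ndarray) -> float:
            nonlocal n_eval
            n_eval += 1
            return -_dataset_loglik(x, spec, cells, engine)
        return nll

    nm_opts = {"xatol": 1e-5, "fatol": 1e-7, "adaptive": True}

    def nm(nll, x, maxiter):
        res = optimize.minimize(nll, x, method="Nelder-Mead", bounds=bounds,
                                options={"maxiter": maxiter, **nm_opts})
        return (res.x, float(res.fun), res.success)

    def nm_block(nll, x, block, maxiter):
        idx = [names.index(n) for n in block if n in names]
        if not idx:
            return x, nll(x)
        xx = x.copy()

        def sub_nll(sub):
            xx[idx] = sub
            return nll(xx)

        res = optimize.minimize(sub_nll, x[idx], method="Nelder-Mead",
                                bounds=[bounds[i] for i in idx],
                                options={"maxiter": maxiter, **nm_opts})
        xx[idx] = res.x
        return xx, float(res.fun)

    rng = np.random.default_rng(settings.seed)
    nll_c = make_nll(settings.coarse_engine)
    nll_f = make_nll(settings.engine)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nll_p = make_nll(settings.prestage_engine)
        x = _informed_start(cells, spec, rng)
        x, fun, _ = nm(nll_p, x, settings.nm_full_maxiter)
        for _ in range(settings.coarse_cycles):
            for block in _BLOCKS:
                x, _ = nm_block(nll_p, x, block, settings.nm_block_maxiter)
            x, f2, _ = nm(nll_p, x, settings.nm_full_maxiter)
            gain, fun = fun - f2, f2
            if gain < settings.cycle_tol:
                break
        # consolidate on the coarse grid before the final polish
        fun = nll_c(x)
        coarse_conv = False
        for _ in range(2):
            for block in _BLOCKS:
                x, _ = nm_block(nll_c, x, block, settings.nm_block_maxiter)
            x, f2, _ = nm(nll_c, x, settings.nm_full_maxiter)
            gain, fun = fun - f2, f2
            if gain < settings.cycle_tol:
                coarse_conv = True
                break
        # the coarse arg-max sits within ~0.01 of the full-resolution one;
        # a single short polish at full resolution finishes the job
        x, fun, success = nm(nll_f, x, settings.nm_fine_maxiter)
        for start in extra_starts:
            xs = np.array([getattr(spec.pin(start), n) for n in names])
            fs = nll_f(xs)
            if fs < fun:
                for block in _BLOCKS:
                    xs, _ = nm_block(nll_c, xs, block, settings.nm_block_maxiter)
                xs, fs, s_ok = nm(nll_f, xs, settings.nm_fine_maxiter)
                if fs < fun:
                    x, fun, success = xs, fs, s_ok or success
    loglik = -float(fun)
    k = spec.n_free
    return FitResult(
        participant_id=pid, model=spec.name,
        params=spec.params_from_free(x), loglik=loglik,
        n_free_params=k, n_trials=n_trials,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * float(np.log(n_trials)) - 2.0 * loglik,
        seed=settings.seed, n_evaluations=n_eval,
        converged=bool(success or coarse_conv),
    )


def fit_all_models(trials: pd.DataFrame, settings: FitSettings | None = None,
                   models: tuple[str, ...] = tuple(MODEL_FAMILY),
                   participant_id: int | None = None) -> list[FitResult]:
    """Fit the requested family members, simplest first.

    Each model receives the fitted parameters of its already-fitted
    nested submodels as extra polish starts, so the maximized
    log-likelihood is monotone along the nesting chain by construction.
    """
    order = sorted(models, key=lambda m: MODEL_FAMILY[m].n_free)
    done: dict[str, FitResult] = {}
    for m in order:
        spec = MODEL_FAMILY[m]
        nested = tuple(
            f.params for name, f in done.items()
            if set(MODEL_FAMILY[name].free_names) < set(spec.free_names))
        done[m] = fit_mle(trials, spec, settings, participant_id,
                          extra_starts=nested)
    return [done[m] for m in models]


def select_models(fits: list[FitResult] | pd.DataFrame) -> pd.DataFrame:
    """Cohort model-selection table: mean AIC/BIC and winner percentages.

    Per participant and criterion the winning model is the argmin; ties
    go to the model with fewest free parameters.  Participants missing
    any model fit, or with any non-converged fit, are excluded with a
    warning.
    """
    df = pd.DataFrame([f.to_row() for f in fits]) if isinstance(fits, list) else fits.copy()
    models = [m for m in MODEL_FAMILY if m in set(df["model"])]
    keep = []
    for pid, sub in df.groupby("participant"):
        if set(sub["model"]) != set(models) or not sub["converged"].all():
            warnings.warn(f"participant {pid} excluded from model selection")
            continue
        keep.append(sub)
    if not keep:
        raise ValueError("no participant has a complete set of converged fits")
    df = pd.concat(keep, ignore_index=True)
    n_free = {m: MODEL_FAMILY[m].n_free for m in models}

    rows = []
    for crit in ("aic", "bic"):
        wins = dict.fromkeys(models, 0)
        for _, sub in df.groupby("participant"):
            sub = sub.set_index("model")
            vals = sub[crit]
            best = vals.min()
            tied = [m for m in models if vals[m] <= best + 1e-9]
            winner = min(tied, key=lambda m: n_free[m])
            wins[winner] += 1
        n_pp = df["participant"].nunique()
        for m in models:
            rows.append({"criterion": crit.upper(), "model": m,
                         "mean": float(df[df["model"] == m][crit].mean()),
                         "pct_best": 100.0 * wins[m] / n_pp})
    return pd.DataFrame(rows)


RT_QUANTILES = (0.05, 0.10, 0.30, 0.50, 0.70, 0.90)


def goodness_of_fit(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Predicted vs. empirical choice proportions and RT quantiles.

    Cells are collapsed over intensity into happy/angry x masked/unmasked;
    within each collapsed cell the table reports, per response, the
    empirical and model-predicted 'unfriendly' proportion and the
    5/10/30/50/70/90% RT quantiles.  Predictions come from the fitted
    model's first-passage densities, pooled across intensities with the
    cell's empirical trial counts as weights and renormalized over
    decided trials (misses are not modelled in the likelihood).
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    t = _analyzable(trials)
    engine = EngineConfig()
    p = fit.params
    rows = []
    for mask in (0, 1):
        for sign, valence in ((-1, "happy"), (1, "angry")):
            emos = [e for e in MAIN_EMOTIONS if np.sign(e) == sign]
            sub = t[(t["mask"] == mask) & (t["emotion"].isin(emos))]
            n = len(sub)
            if n == 0:
                rows.append({"mask": mask, "valence": valence, "n": 0})
                continue
            # count-weighted mixture of the per-intensity densities
            up = np.zeros(engine.n_steps)
            lo = np.zeros(engine.n_steps)
            for emo in emos:
                w = int((sub["emotion"] == emo).sum())
                if w == 0:
                    continue
                f = solve_fptd(drift_rate(p, emo / 100.0, mask), p.a, p.tau,
                               start_point(p, mask), engine)
                up += w * f.upper_density
                lo += w * f.lower_density
            dt = engine.dt
            decided = (up.sum() + lo.sum()) * dt
            pred_p_up = float(up.sum() * dt / decided) if decided > 0 else np.nan
            ter = nondecision(p, mask)
            grid = engine.time_grid + ter
            emp_up = sub[sub["choice"].eq("unfriendly")]["rt_s"].to_numpy()
            emp_lo = sub[sub["choice"].eq("friendly")]["rt_s"].to_numpy()
            for resp, dens, emp in (("unfriendly", up, emp_up), ("friendly", lo, emp_lo)):
                row = {"mask": mask, "valence": valence, "response": resp, "n": len(emp),
                       "p_unfriendly_emp": float(len(emp_up) / n) if resp == "unfriendly" else 1 - len(emp_up) / n,
                       "p_unfriendly_pred": pred_p_up if resp == "unfriendly" else 1 - pred_p_up}
                mass = dens.sum() * dt
                cdf = np.cumsum(dens) * dt / mass if mass > 0 else None
                for q in RT_QUANTILES:
                    row[f"emp_q{int(q*100)}"] = float(np.quantile(emp, q)) if len(emp) else np.nan
                    row[f"pred_q{int(q*100)}"] = (
                        float(np.interp(q, cdf, grid)) if cdf is not None else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def parameter_recovery(truth: DDMParams, n_per_cell: int = 2000,
                       n_reps: int = 10, seed: int = 0,
                       settings: FitSettings | None = None,
                       model: str = "full_vc_z"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit validation of the fitting pipeline.

    For each replicate, one synthetic participant with ``truth`` as true
    parameters and ``n_per_cell`` trials per mask-by-emotion cell is
    simulated and refitted with ``model``.  Returns (summary, per_rep):
    the summary has one row per parameter with the truth, mean/median
    recovered value, bias, RMSE, the replicate standard deviation
    (``sd`` -- the recovery standard error of a single fit) and the
    standard error of the replicate mean (``se``), over the converged
    replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if settings is None:
        settings = FitSettings()
    rng = np.random.default_rng(seed)
    spec = MODEL_FAMILY[model]
    rep_rows = []
    for rep in range(n_reps):
        s_design = int(rng.integers(0, 2**31 - 1))
        s_sim = int(rng.integers(0, 2**31 - 1))
        s_fit = int(rng.integers(0, 2**31 - 1))
        design = balanced_design(n_per_cell, seed=s_design)
        trials = simulate_participant(truth, design, s_sim, participant_id=rep + 1)
        fit = fit_mle(trials, spec, settings.with_seed(s_fit), participant_id=rep + 1)
        row = {"rep": rep + 1, "converged": fit.converged, "loglik": fit.loglik}
        row.update(fit.params.to_dict())
        rep_rows.append(row)
    per_rep = pd.DataFrame(rep_rows)
    conv = per_rep[per_rep["converged"]]
    if len(conv) == 0:
        raise RuntimeError("no replicate converged; cannot summarize recovery")
    rows = []
    for name in PARAM_NAMES:
        est = conv[name].to_numpy()
        true_val = getattr(truth, name)
        sd = float(est.std(ddof=1)) if len(est) > 1 else np.nan
        rows.append({
            "parameter": name, "truth": true_val,
            "mean": float(est.mean()), "median": float(np.median(est)),
            "bias": float(est.mean() - true_val),
            "rmse": float(np.sqrt(np.mean((est - true_val) ** 2))),
            "sd": sd,
            "se": sd / np.sqrt(len(est)) if len(est) > 1 else np.nan,
            "n_reps": len(est),
        })
    return pd.DataFrame(rows), per_rep
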