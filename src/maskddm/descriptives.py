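"""Descriptive layer: RT preprocessing, psychometric fits, summaries.

The psychometric function is a logistic in the signed emotion fraction S,

    p_unfriendly(S) = 1 / (1 + exp(-(b0 + b1 * S))),

fitted per participant and per mask condition by Bernoulli maximum
likelihood.  b0 is a choice bias (logit units), b1 the sensitivity to
the stimulus (logit units per unit emotion fraction; S uses the same
-0.60..0.60 scale as the drift regressor).  Participants whose deviance
against the saturated per-level model exceeds the chi-square 95th
percentile for its degrees of freedom are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PsychometricFit",
    "preprocess_rt",
    "fit_psychometric",
    "fit_psychometric_cohort",
    "bias_and_sensitivity_tests",
    "condition_medians",
]

_SLOPE_CAP = 100.0  # bounded slope reported under complete separation


def preprocess_rt(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Flag valid trials; return (trials + ``valid`` column, removal fraction).

    Misses are invalid.  Within each mask-by-emotion cell, response times
    are log-transformed and those beyond 3 SD from the cell mean are
    flagged invalid.  The removal fraction counts only the 3-SD removals,
    as a fraction of non-miss trials.
    """
    out = trials.copy()
    responded = out["choice"].ne("miss") & out["rt_s"].notna()
    valid = responded.copy()
    for (_, _), idx in out.groupby(["mask", "emotion"]).groups.items():
        cell = out.loc[idx]
        cell_resp = cell.index[responded.loc[idx]]
        if len(cell_resp) == 0:
            warnings.warn("empty cell in RT preprocessing; skipped")
            continue
        logrt = np.log(out.loc[cell_resp, "rt_s"].to_numpy(dtype=float))
        sd = logrt.std(ddof=1) if len(logrt) > 1 else 0.0
        if sd == 0.0:
            continue
        bad = np.abs(logrt - logrt.mean()) > 3.0 * sd
        valid.loc[cell_resp[bad]] = False
    out["valid"] = valid
    n_resp = int(responded.sum())
    removed = int((responded & ~valid).sum())
    frac = removed / n_resp if n_resp else 0.0
    return out, frac


@dataclass(frozen=True)
class PsychometricFit:
    b0: float          # bias, logit units
    b1: float          # sensitivity, logit units per unit emotion fraction
    deviance: float    # vs. the saturated per-level model
    df: int            # distinct S levels - 2
    excluded: bool     # deviance beyond the chi-square 95th percentile
    separated: bool    # complete separation; slope is the reported cap


def fit_psychometric(trials: pd.DataFrame, condition: int | None = None,
                     include_fillers: bool = True) -> PsychometricFit:
    """Logistic fit of choice against emotion fraction for one condition.

    ``condition`` is 0 (unmasked), 1 (masked) or None (pool).  Fillers
    carry choice information, so they are kept by default; misses and
    trials flagged invalid are always dropped.
    """
    t = trials
    if condition is not None:
        t = t[t["mask"] == condition]
    if not include_fillers:
        t = t[~t["filler"].astype(bool)]
    if "valid" in t.columns:
        t = t[t["valid"]]
    else:
        t = t[t["choice"].ne("miss")]
    if len(t) == 0:
        raise ValueError("no analyzable trials for the psychometric fit")

    s = t["emotion"].to_numpy(dtype=float) / 100.0
    y = t["choice"].eq("unfriendly").to_numpy(dtype=float)
    grouped = pd.DataFrame({"s": s, "y": y}).groupby("s")["y"].agg(["sum", "count"])
    n_levels = len(grouped)
    df = max(n_levels - 2, 0)

    endog = np.c_[grouped["sum"], grouped["count"] - grouped["sum"]]
    exog = sm.add_constant(grouped.index.to_numpy())
    separated = False
    b0 = b1 = deviance = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=200)
            b0, b1 = map(float, res.params)
            deviance = float(res.deviance)
        except Exception:
            res = None
        if res is None or not np.isfinite([b0, b1]).all() or abs(b1) > _SLOPE_CAP:
            # complete (or quasi-) separation: report a bounded slope
            separated = True
            p_up = y.mean()
            b0 = float(np.clip(stats.norm.ppf(np.clip(p_up, 1e-6, 1 - 1e-6)), -10, 10))
            b1 = _SLOPE_CAP if np.corrcoef(s, y)[0, 1] >= 0 else -_SLOPE_CAP
            deviance = np.nan

    crit = stats.chi2.ppf(0.95, df) if df > 0 else np.inf
    excluded = bool(np.isfinite(deviance) and deviance > crit)
    return PsychometricFit(b0=b0, b1=b1, deviance=deviance, df=df,
                           excluded=excluded, separated=separated)


def fit_psychometric_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition psychometric fits as a tidy table."""
    rows = []
    for pid, t in trials.groupby("participant"):
        for cond in (0, 1):
            f = fit_psychometric(t, condition=cond)
            rows.append({"participant": pid, "mask": cond, **f.__dict__})
    return pd.DataFrame(rows)


def bias_and_sensitivity_tests(fits: pd.DataFrame) -> dict:
    """Cohort medians of b0/b1 with signed-rank tests.

    One-sample Wilcoxon signed-rank per condition for b0 = 0; paired
    signed-rank for the masked-vs-unmasked sensitivity difference.
    """
    if fits["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    out: dict = {}
    for cond, label in ((0, "unmasked"), (1, "masked")):
        sub = fits[fits["mask"] == cond].sort_values("participant")
        b0 = sub["b0"].to_numpy()
        b1 = sub["b1"].to_numpy()
        res = stats.wilcoxon(b0) if np.any(b0 != 0) else None
        out[label] = {
            "b0_median": float(np.median(b0)),
            "b1_median": float(np.median(b1)),
            "b0_wilcoxon_p": float(res.pvalue) if res else 1.0,
        }
    un = fits[fits["mask"] == 0].sort_values("participant")["b1"].to_numpy()
    ma = fits[fits["mask"] == 1].sort_values("participant")["b1"].to_numpy()
    diff = ma - un
    res = stats.wilcoxon(diff) if np.any(diff != 0) else None
    out["b1_masked_vs_unmasked_p"] = float(res.pvalue) if res else 1.0
    return out


def condition_medians(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant median RT per mask-by-emotion cell + cohort means.

    Expects preprocessed trials (``valid`` column).  Returns a tidy table
    with one row per participant x cell, with the cohort mean-of-medians
    joined per cell as ``cohort_mean``.
    """
    t = trials[trials["valid"]] if "valid" in trials.columns else trials[trials["choice"].ne("miss")]
    med = (t.groupby(["participant", "mask", "emotion"])["rt_s"]
             .median().rename("median_rt").reset_index())
    cohort = (med.groupby(["mask", "emotion"])["median_rt"]
                 .mean().rename("cohort_mean").reset_index())
    return med.merge(cohort, on=["mask", "emotion"])
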