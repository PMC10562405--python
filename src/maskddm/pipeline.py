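"""End-to-end orchestration: simulate -> describe -> fit -> select.

One seeded configuration drives the whole analysis; every stage writes
flat CSV/JSON artifacts into the run directory and a manifest records
the seeds, sizes and content hashes that produced them, so two runs of
the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .descriptives import (bias_and_sensitivity_tests, condition_medians,
                           fit_psychometric_cohort, preprocess_rt)
from .inference import FitSettings, fit_all_models, parameter_recovery, select_models
from .io import write_params, write_trials
from .models import DDMParams, MODEL_FAMILY, GROUP_MEANS
from .simulate import CohortSpec, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("maskddm")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int
    out_dir: str
    n_participants: int = 8
    models: tuple[str, ...] = tuple(MODEL_FAMILY)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    recovery_reps: int = 0          # 0 disables the recovery stage
    recovery_trials_per_cell: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "fit_settings" in raw:
            raw["fit_settings"] = FitSettings(**raw["fit_settings"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, out: Path) -> pd.DataFrame:
    spec = CohortSpec(n_participants=cfg.n_participants, seed=cfg.seed)
    trials, truths = simulate_cohort(spec)
    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    for pid, sub in trials.groupby("participant"):
        write_trials(sub, data_dir / f"participant_{pid:03d}.csv")
    with open(data_dir / "true_params.json", "w") as fh:
        json.dump({str(i + 1): p.to_dict() for i, p in enumerate(truths)}, fh, indent=2)
    return trials


@_stage("describe")
def _describe(trials: pd.DataFrame, out: Path) -> pd.DataFrame:
    pieces = []
    for pid, sub in trials.groupby("participant"):
        pre, frac = preprocess_rt(sub)
        pre["removed_fraction"] = frac
        pieces.append(pre)
    pre_all = pd.concat(pieces, ignore_index=True)
    fits = fit_psychometric_cohort(pre_all)
    fits.to_csv(out / "psychometric_fits.csv", index=False)
    condition_medians(pre_all).to_csv(out / "condition_medians.csv", index=False)
    if fits["participant"].nunique() >= 2:
        with open(out / "descriptive_tests.json", "w") as fh:
            json.dump(bias_and_sensitivity_tests(fits), fh, indent=2)
    kept = fits.groupby("participant")["excluded"].any()
    keep_ids = kept[~kept].index
    log.info("describe: %d/%d participants pass the deviance criterion",
             len(keep_ids), fits["participant"].nunique())
    if len(keep_ids) == 0:
        raise ValueError("every participant failed the deviance criterion; "
                         "nothing left to fit")
    return pre_all[pre_all["participant"].isin(keep_ids)]


@_stage("fit")
def _fit(cfg: RunConfig, trials: pd.DataFrame, out: Path) -> pd.DataFrame:
    rows = []
    for pid, sub in trials.groupby("participant"):
        settings = cfg.fit_settings.with_seed(cfg.seed + int(pid))
        for res in fit_all_models(sub, settings, models=cfg.models,
                                  participant_id=int(pid)):
            rows.append(res.to_row())
            log.info("fit: participant %s model %s logL=%.2f", pid, res.model, res.loglik)
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "fits.csv", index=False)
    return fits


@_stage("select")
def _select(fits: pd.DataFrame, out: Path) -> pd.DataFrame:
    table = select_models(fits)
    table.to_csv(out / "selection.csv", index=False)
    return table


@_stage("recover")
def _recover(cfg: RunConfig, out: Path) -> pd.DataFrame:
    summary, per_rep = parameter_recovery(
        GROUP_MEANS, n_per_cell=cfg.recovery_trials_per_cell,
        n_reps=cfg.recovery_reps, seed=cfg.seed,
        settings=cfg.fit_settings)
    summary.to_csv(out / "recovery_summary.csv", index=False)
    per_rep.to_csv(out / "recovery_replicates.csv", index=False)
    return summary


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Partial outputs are preserved on failure; the manifest is written
    last, so its presence marks a complete run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        trials = _simulate(cfg, out)
        analyzable = _describe(trials, out)
        fits = _fit(cfg, analyzable, out)
        _select(fits, out)
        if cfg.recovery_reps > 0:
            _recover(cfg, out)
        manifest = {
            "package_version": __version__,
            "seed": cfg.seed,
            "config": {**asdict(cfg), "fit_settings": asdict(cfg.fit_settings),
                       "models": list(cfg.models)},
            "artifacts": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
            "data_files": {p.name: _sha256(p) for p in sorted((out / "data").glob("*"))},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
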