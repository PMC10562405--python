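# maskddm

Drift–diffusion decomposition of **perceptual** versus **preconceptual**
bias in friendly/unfriendly judgments of emotionally ambiguous faces
shown with or without a surgical face mask.

A mask can make a face look less friendly in two distinct ways that
produce identical signatures in raw choice counts:

* a **perceptual (stimulus-driven) bias** — the mask changes how the
  facial evidence itself is evaluated, shifting the *drift-rate
  criterion* `vc`;
* a **preconceptual (top-down) bias** — the observer expects masked
  faces to be unfriendly before any evidence arrives, shifting the
  accumulator's *starting point* `z` toward the unfriendly threshold.

The two are separable only by modelling choices **and** response times
jointly. This package implements that analysis end to end for a
2AFC masked-face experiment (608 trials per participant: six signed
emotion levels −60…+60 % plus ±20 % fillers, half masked, 2.3 s response
deadline), together with a synthetic-cohort generator that stands in for
behavioral data.

## Model

Evidence `x(t)` accumulates with unit noise between two exponentially
collapsing absorbing thresholds `±a·exp(−τt)` (urgency under the
deadline). For mask condition `C ∈ {0,1}` and signed emotion fraction
`k ∈ {−0.6 … 0.6}`:

    v   = vc0 + C·vc_mask + k·(v_slope0 + C·v_slope_mask)   (drift)
    Ter = Ter0 + C·Ter_mask                                  (non-decision time)
    z   = z0 + C·z_mask                                      (start, fraction of a)

The upper threshold is the *unfriendly* response; RT = first-passage
time + `Ter`. Four nested models differ in which mask-bias terms are
free: `null` (`vc_mask = z_mask = 0`), `reduced_vc`, `reduced_z`, and
`full_vc_z`. Each is fitted per participant by maximum likelihood —
first-passage densities come from a Crank–Nicolson Fokker–Planck solver
with fractional-boundary handling — and compared by AIC/BIC. A logistic
psychometric function `p_unfriendly = 1/(1+e^{−(β0+β1·S)})` provides the
descriptive layer, with deviance-based participant exclusion.

## Worked example

```python
from maskddm import (GROUP_MEANS, MODEL_FAMILY, balanced_design,
                     simulate_participant)
from maskddm.inference import FitSettings, fit_mle

# one synthetic participant, 2000 trials per mask-by-emotion cell,
# generated at the group-mean full-model parameters
design = balanced_design(2000, seed=3)
trials = simulate_participant(GROUP_MEANS, design, seed=7)
fit = fit_mle(trials, MODEL_FAMILY["full_vc_z"], FitSettings(seed=5))
for name, value in fit.params.to_dict().items():
    print(f"{name:14s} {value:8.3f}")
```

prints (about one minute on one core):

```
a                 1.044
tau               1.234
ter0              0.385
ter_mask          0.016
vc0               0.177
vc_mask          -0.273
v_slope0          5.723
v_slope_mask     -1.814
z0               -0.061
z_mask            0.097
```

The generating values were `vc_mask = −0.28` (perceptual bias toward
*friendly*) and `z_mask = +0.10` (preconceptual bias toward
*unfriendly*): the fit separates the two opposing biases and recovers
the drift slope (5.68), non-decision time (380 ms) and the mask's RT
cost (+14 ms).

The numbered scripts under `analysis/` run the full study pipeline on a
synthetic cohort — `01_simulate_cohort.py` → `02_descriptives.py` →
`03_fit_models.py` → `04_model_selection.py` → `05_goodness_of_fit.py`
→ `06_parameter_recovery.py` — writing flat CSV/JSON tables under
`results/`. `maskddm.pipeline.run_pipeline` drives the same stages from
a single seeded config with a hash manifest.

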