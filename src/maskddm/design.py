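"""Trial design of the masked-face 2AFC experiment.

The task shows morphed face stimuli at six signed emotion levels
(percent angry minus happy: -60, -40, -10, 10, 40, 60), each with and
without a surgical mask, plus filler morphs at +/-20.  A session has 608
trials in 8 blocks of 76: per block, every main mask-by-emotion cell
appears 6 times and every filler cell once, in randomly alternating
order.  Responses must arrive within 2.3 s of stimulus onset; the
fixation cross before each stimulus is jittered uniformly on 600-1200 ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import FILLER_EMOTIONS, MAIN_EMOTIONS

__all__ = [
    "DEADLINE_S",
    "N_TRIALS",
    "N_BLOCKS",
    "TRIALS_PER_BLOCK",
    "build_design",
    "balanced_design",
    "validate_design",
]

DEADLINE_S = 2.3
N_BLOCKS = 8
TRIALS_PER_BLOCK = 76
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK  # 608
_MAIN_PER_CELL_PER_BLOCK = 6            # -> 96 per emotion, 48 masked
_FILLER_PER_CELL_PER_BLOCK = 1          # -> 32 fillers, 16 masked

DESIGN_COLUMNS = ["block", "mask", "emotion", "filler", "fixation_ms"]


def build_design(seed: int) -> pd.DataFrame:
    """The full 608-trial session design, shuffled deterministically.

    Returns a DataFrame with columns ``block`` (1-8), ``mask`` (0/1),
    ``emotion`` (signed percent), ``filler`` (bool) and ``fixation_ms``.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(1, N_BLOCKS + 1):
        rows = []
        for mask in (0, 1):
            for emo in MAIN_EMOTIONS:
                rows += [(b, mask, emo, False)] * _MAIN_PER_CELL_PER_BLOCK
            for emo in FILLER_EMOTIONS:
                rows += [(b, mask, emo, True)] * _FILLER_PER_CELL_PER_BLOCK
        block = pd.DataFrame(rows, columns=DESIGN_COLUMNS[:4])
        block = block.sample(frac=1.0, random_state=rng).reset_index(drop=True)
        blocks.append(block)
    design = pd.concat(blocks, ignore_index=True)
    design["fixation_ms"] = rng.integers(600, 1201, size=len(design))
    validate_design(design)
    return design


def balanced_design(n_per_cell: int, seed: int = 0,
                    include_fillers: bool = False) -> pd.DataFrame:
    """A flat design with ``n_per_cell`` trials per mask-by-emotion cell.

    Used for simulation studies (parameter recovery) where the session
    structure is irrelevant but cell sizes beyond the real session's 48
    are needed.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for mask in (0, 1):
        for emo in MAIN_EMOTIONS:
            rows += [(1, mask, emo, False)] * n_per_cell
        if include_fillers:
            for emo in FILLER_EMOTIONS:
                rows += [(1, mask, emo, True)] * n_per_cell
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS[:4])
    design = design.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    design["fixation_ms"] = rng.integers(600, 1201, size=len(design))
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Assert every count constraint of the session design."""
    if len(design) != N_TRIALS:
        raise ValueError(f"expected {N_TRIALS} trials, got {len(design)}")
    main = design[~design.filler]
    for emo in MAIN_EMOTIONS:
        cell = main[main.emotion == emo]
        if len(cell) != 96 or int((cell["mask"] == 1).sum()) != 48:
            raise ValueError(f"emotion {emo}: expected 96 trials (48 masked)")
    fillers = design[design.filler]
    if len(fillers) != 32 or int((fillers["mask"] == 1).sum()) != 16:
        raise ValueError("expected 32 filler trials (16 masked)")
    counts = design.groupby("block").size()
    if len(counts) != N_BLOCKS or not (counts == TRIALS_PER_BLOCK).all():
        raise ValueError(f"expected {N_BLOCKS} blocks of {TRIALS_PER_BLOCK}")
    if design.fixation_ms.min() < 600 or design.fixation_ms.max() > 1200:
        raise ValueError("fixation jitter outside 600-1200 ms")
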