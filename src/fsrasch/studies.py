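"""Replicated simulation studies over the district presets.

These drive the package's calibration checks: parameter recovery of the
preset easiness values, outfit mean-square behaviour under a correctly
specified model, and the size of the median-split homogeneity test.  Each
replicate derives its own seed from (base_seed, replicate index) through a
``SeedSequence``, so studies are reproducible and replicates independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cml import fit_cml
from .diagnostics import graphical_model_check, outfit
from .persons import score_households
from .simulate import SimulationConfig, simulate

__all__ = [
    "replicate_seed",
    "recovery_study",
    "outfit_study",
    "outfit_mean_msq",
    "homogeneity_size_study",
]


def replicate_seed(base_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    return int(np.random.SeedSequence([int(base_seed), int(rep)]).generate_state(1)[0] % (2**31))


def recovery_study(preset: str, n_reps: int, base_seed: int = 1) -> pd.DataFrame:
    """CML easiness estimates for ``n_reps`` datasets from a district preset.

    Returns one row per replicate, one column per item.
    """
    rows = []
    cfg0 = SimulationConfig.from_preset(preset)
    for rep in range(n_reps):
        cfg = SimulationConfig.from_preset(preset, seed=replicate_seed(base_seed, rep))
        ds = simulate(cfg)
        fit = fit_cml(ds.matrix)
        rows.append(fit.params.beta)
    return pd.DataFrame(rows, columns=list(cfg0.item_id))


def outfit_study(preset: str, seed: int):
    """One preset dataset through the full pipeline; returns its ItemFitStats."""
    ds = simulate(SimulationConfig.from_preset(preset, seed=seed))
    fit = fit_cml(ds.matrix)
    scores = score_households(ds.matrix, fit.params)
    return outfit(ds.matrix, fit.params, scores)


def outfit_mean_msq(preset: str, n_reps: int, base_seed: int = 1) -> pd.DataFrame:
    """Outfit MSQ per item for ``n_reps`` model-true replicates."""
    rows = []
    cfg0 = SimulationConfig.from_preset(preset)
    for rep in range(n_reps):
        stats = outfit_study(preset, replicate_seed(base_seed, rep))
        rows.append(stats.frame["outfit_msq"].to_numpy())
    return pd.DataFrame(rows, columns=list(cfg0.item_id))


def homogeneity_size_study(
    preset: str, n_reps: int, base_seed: int = 1, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the median-split LR test on model-true data."""
    rejections = 0
    for rep in range(n_reps):
        ds = simulate(
            SimulationConfig.from_preset(preset, seed=replicate_seed(base_seed, rep))
        )
        check = graphical_model_check(ds.matrix, alpha=alpha)
        rejections += int(check.p_value < alpha)
    return rejections / n_reps
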