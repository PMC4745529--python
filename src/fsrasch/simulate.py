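"""Synthetic household-by-item response generator.

Generates binary matrices from the latent-trait law the analysis assumes:
household abilities are drawn Normal(mu, sigma^2) and responses are
independent Bernoulli with ``logit P = a_i (theta_v + beta_i)`` — slope
``a_i = 1`` for every item under the Rasch model, with optional per-item
discriminations to manufacture misfit for power studies.

Two presets reproduce the study conditions of the two-district survey the
package's reference calibration comes from: ``tororo`` (n = 577, abilities
Normal(0.137, 2.040^2)) and ``busia`` (n = 598, Normal(0.768, 2.078^2)), each
with its published 18-item easiness vector.  All draws flow from a single
integer seed through one PCG64 generator stream in household-major order, so
a (config, seed) pair reproduces its matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .coding import (
    BinaryResponseMatrix,
    FREQUENCY_ITEMS,
    GATE_OF,
    HOW_OFTEN_ITEMS,
)
from .errors import UserInputError
from . import presets as _presets

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "simulate_misfit",
    "raw_survey_from_binary",
]


@dataclass
class SimulationConfig:
    """Generator truth for one synthetic dataset.

    ``beta`` is recentered to sum zero on construction (the identification
    convention of the calibration it feeds).  ``sigma`` is the ability SD —
    the square root of the latent variance of the trait law, generalized to a
    nonzero mean because observed district score distributions are not
    centered at the scale origin.
    """

    n: int
    beta: np.ndarray
    mu: float = 0.0
    sigma: float = 1.0
    seed: int = 0
    discriminations: np.ndarray | None = None
    preset: str | None = None
    item_id: tuple = field(default=None)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1 or self.beta.size < 1:
            raise UserInputError("beta must be a 1-d vector")
        self.beta = self.beta - self.beta.mean()  # enforce sum-zero
        if self.sigma < 0:
            raise UserInputError("sigma must be nonnegative")
        if self.n < 1:
            raise UserInputError("n must be positive")
        if self.item_id is None:
            self.item_id = tuple(f"E{i + 1}" for i in range(self.beta.size))
        if len(self.item_id) != self.beta.size:
            raise UserInputError("item_id length does not match beta")
        if self.discriminations is not None:
            self.discriminations = np.asarray(self.discriminations, dtype=float)
            if self.discriminations.shape != self.beta.shape:
                raise UserInputError("discriminations must match beta in length")
            if not np.all(self.discriminations > 0):
                raise UserInputError("discriminations must be positive")

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, n: int | None = None) -> "SimulationConfig":
        """The ``tororo`` or ``busia`` study conditions, optionally overriding n."""
        name = name.lower()
        if name not in _presets.DISTRICT_MOMENTS:
            raise UserInputError(f"unknown preset {name!r}")
        mom = _presets.DISTRICT_MOMENTS[name]
        return cls(
            n=n if n is not None else mom["n"],
            beta=_presets.beta_vector(name),
            mu=mom["mu"],
            sigma=mom["sigma"],
            seed=seed,
            preset=name,
            item_id=_presets.ITEM_IDS,
        )

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "beta": [float(b) for b in self.beta],
            "mu": float(self.mu),
            "sigma": float(self.sigma),
            "seed": int(self.seed),
            "discriminations": None
            if self.discriminations is None
            else [float(a) for a in self.discriminations],
            "preset": self.preset,
            "item_id": list(self.item_id),
            "generator": "numpy.random.Generator(PCG64)",
        }


@dataclass
class SimulatedDataset:
    """A generated matrix together with its generating truth."""

    matrix: BinaryResponseMatrix
    true_theta: np.ndarray
    true_beta: np.ndarray
    config: SimulationConfig

    def truth_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "true_beta": [float(b) for b in self.true_beta],
            "true_theta": [float(t) for t in self.true_theta],
        }


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the configured trait law.

    Ability draws come first, then the n x k response uniforms, all from one
    generator stream; identical (config, seed) pairs therefore give identical
    matrices.
    """
    rng = np.random.default_rng(config.seed)
    theta = config.mu + config.sigma * rng.standard_normal(config.n)
    a = (
        np.ones_like(config.beta)
        if config.discriminations is None
        else config.discriminations
    )
    P = expit(a[None, :] * (theta[:, None] + config.beta[None, :]))
    X = (rng.random((config.n, config.beta.size)) < P).astype(float)
    district = [config.preset or "sim"] * config.n
    matrix = BinaryResponseMatrix(
        X=X,
        household_id=[f"H{v + 1:05d}" for v in range(config.n)],
        item_id=list(config.item_id),
        district=district,
    )
    return SimulatedDataset(
        matrix=matrix, true_theta=theta, true_beta=config.beta.copy(), config=config
    )


def simulate_misfit(
    config: SimulationConfig, misfit_items, slope: float
) -> SimulatedDataset:
    """Simulate with the listed items generated at a non-unit discrimination.

    ``slope > 1`` makes an item over-discriminating (outfit MSQ below 1);
    ``slope < 1`` under-discriminating (MSQ above 1).  ``slope = 1`` is
    distributionally — and, under a fixed seed, exactly — the Rasch
    generator.
    """
    if slope <= 0:
        raise UserInputError("slope must be positive")
    item_index = {i: j for j, i in enumerate(config.item_id)}
    unknown = [i for i in misfit_items if i not in item_index]
    if unknown:
        raise UserInputError(f"unknown misfit item ids: {unknown}")
    a = np.ones(config.beta.size)
    for i in misfit_items:
        a[item_index[i]] = slope
    return simulate(replace(config, discriminations=a))


_AFFIRM = {"frequency": "sometimes_true", "yes_no": "yes", "how_often": "some_months"}
_NEGATE = {"frequency": "never_true", "yes_no": "no", "how_often": "one_or_two_months"}


def _item_class(item: str) -> str:
    if item in FREQUENCY_ITEMS:
        return "frequency"
    if item in HOW_OFTEN_ITEMS:
        return "how_often"
    return "yes_no"


def raw_survey_from_binary(dataset: SimulatedDataset) -> pd.DataFrame:
    """Emit a raw categorical survey table that codes back to the matrix.

    Each 1 becomes a representative affirmative level of its item class and
    each 0 the negative level; a how-often follow-up whose gate item is 0
    becomes ``not_applicable``, and an affirmative follow-up forces its gate
    to ``yes`` (gate logic).  For gate-consistent matrices the round trip
    through the binary coder is exact.
    """
    m = dataset.matrix
    items = list(m.item_id)
    X = m.X.copy()
    pos = {i: j for j, i in enumerate(items)}
    # gate logic: an affirmed follow-up implies an affirmative gate answer
    for fu, gate in GATE_OF.items():
        if fu in pos and gate in pos:
            X[X[:, pos[fu]] == 1, pos[gate]] = 1.0
    out = {"household_id": list(m.household_id)}
    if m.district is not None:
        out["district"] = list(m.district)
    for j, item in enumerate(items):
        cls = _item_class(item)
        col = []
        for v in range(m.n):
            x = X[v, j]
            if np.isnan(x):
                col.append("")
            elif x == 1:
                col.append(_AFFIRM[cls])
            elif cls == "how_often" and item in GATE_OF and _gate_value(X, pos, item, v) == 0:
                col.append("not_applicable")
            else:
                col.append(_NEGATE[cls])
        out[item] = col
    return pd.DataFrame(out)


def _gate_value(X, pos, item, v):
    gate = GATE_OF.get(item)
    if gate is None or gate not in pos:
        return 1
    return X[v, pos[gate]]
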