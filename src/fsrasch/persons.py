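"""Household ability estimation, food-security classification, summaries.

Given a calibrated item set, the maximum-likelihood ability for raw score
``r`` solves the monotone score equation ``sum_i P_i(theta) = r`` with
``P_i(theta) = expit(theta + beta_i)``.  Raw-score sufficiency means every
household with the same raw score receives the same theta, so scoring reduces
to a small score -> theta table.  Extreme scores (0 or k) have no finite ML
estimate; by default those households are excluded from theta statistics,
optionally they are scored at r +- 0.5.

A household with theta >= 0 is classified food secure, theta < 0 food
insecure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cml import ItemParameters
from .coding import as_binary_matrix
from .errors import ExtremeScoreError, UserInputError

__all__ = [
    "ScoreThetaMap",
    "PersonScores",
    "DescriptiveSummary",
    "solve_theta",
    "score_theta_map",
    "score_households",
    "district_summary",
    "standard_error_of_mean",
]

_Z975 = 1.959963984540054  # standard-normal 97.5% quantile


def standard_error_of_mean(sd: float, n_used: int) -> float:
    """SE of the mean household score: sd / sqrt(n_used)."""
    return float(sd) / np.sqrt(n_used)


def _theta_root(r: float, beta: np.ndarray, tol=1e-12):
    """Solve sum_i expit(theta + beta_i) = r by bracketed root finding."""
    k = beta.shape[0]
    if not 0 < r < k:
        raise ExtremeScoreError(
            f"raw score {r} of {k} items has no finite ML ability estimate"
        )

    def f(theta):
        return expit(theta + beta).sum() - r

    lo, hi = -40.0 - np.abs(beta).max(), 40.0 + np.abs(beta).max()
    theta = brentq(f, lo, hi, xtol=tol, rtol=8.881784197001252e-16)
    p = expit(theta + beta)
    info = float(np.sum(p * (1 - p)))
    return float(theta), 1.0 / np.sqrt(info)


def solve_theta(r, params: ItemParameters, tol=1e-12):
    """ML ability estimate and its SE for raw score ``r`` (0 < r < k).

    The SE is the inverse square root of the test information
    ``sum_i P_i (1 - P_i)`` at the estimate.  Fractional r (from the
    half-adjusted extreme policy) is accepted.
    """
    return _theta_root(float(r), np.asarray(params.beta, dtype=float), tol)


@dataclass
class ScoreThetaMap:
    """Lookup table raw score -> (theta, SE) for one calibration."""

    table: pd.DataFrame  # columns: raw_score, theta, se

    def lookup(self, r: float):
        row = self.table.loc[self.table["raw_score"] == r]
        if row.empty:
            raise KeyError(f"raw score {r} not in map")
        return float(row["theta"].iloc[0]), float(row["se"].iloc[0])


def score_theta_map(params: ItemParameters, scores=None) -> ScoreThetaMap:
    """Build the score -> theta table for raw scores 1..k-1 (or ``scores``)."""
    k = params.k
    rs = list(scores) if scores is not None else list(range(1, k))
    rows = []
    for r in rs:
        theta, se = solve_theta(r, params)
        rows.append((float(r), theta, se))
    df = pd.DataFrame(rows, columns=["raw_score", "theta", "se"])
    if not df["theta"].is_monotonic_increasing:  # pragma: no cover - safety net
        raise UserInputError("theta map is not increasing; calibration is corrupt")
    return ScoreThetaMap(df)


@dataclass
class PersonScores:
    """Per-household scores, abilities and food-security classes."""

    frame: pd.DataFrame
    # columns: household_id, district, raw_score, theta, se, extreme, classification

    @property
    def theta(self) -> np.ndarray:
        return self.frame["theta"].to_numpy(dtype=float)

    @property
    def n_used(self) -> int:
        """Households with a finite ability estimate."""
        return int(np.isfinite(self.theta).sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def score_households(
    data, params: ItemParameters, extreme_policy: str = "exclude"
) -> PersonScores:
    """Score every household through the score -> theta map and classify it.

    Parameters
    ----------
    extreme_policy : ``exclude`` (default) leaves extreme-score households
        unscored (theta NaN, no class); ``half_adjust`` scores them at
        r = 0.5 and k - 0.5.

    Households with missing items (possible under the as_missing don't-know
    policy) are scored on their answered subset via a reduced calibration and
    flagged in the ``partial`` column.
    """
    if extreme_policy not in ("exclude", "half_adjust"):
        raise UserInputError(f"unknown extreme_policy {extreme_policy!r}")
    m = as_binary_matrix(data)
    if list(m.item_id) != list(params.item_id):
        raise UserInputError("item ids of data and calibration disagree")
    k = m.k
    beta = np.asarray(params.beta, dtype=float)

    complete = ~np.isnan(m.X).any(axis=1)
    r_all = m.raw_scores()
    k_answered = (~np.isnan(m.X)).sum(axis=1)

    # effective score used for theta: extremes shifted under half_adjust
    theta = np.full(m.n, np.nan)
    se = np.full(m.n, np.nan)
    cache: dict = {}
    partial = ~complete
    for v in range(m.n):
        row = m.X[v]
        answered = ~np.isnan(row)
        k_v = int(answered.sum())
        r_v = float(np.nansum(row))
        key = (r_v, tuple(np.flatnonzero(answered)) if not complete[v] else None)
        if r_v <= 0 or r_v >= k_v:
            if extreme_policy == "exclude":
                continue
            r_v = 0.5 if r_v <= 0 else k_v - 0.5
            key = (r_v, key[1])
        if key not in cache:
            cache[key] = _theta_root(r_v, beta[answered])
        theta[v], se[v] = cache[key]

    classification = np.where(
        np.isnan(theta), None, np.where(theta >= 0, "secure", "insecure")
    )
    frame = pd.DataFrame(
        {
            "household_id": list(m.household_id),
            "district": list(m.district) if m.district is not None else "",
            "raw_score": r_all,
            "theta": theta,
            "se": se,
            "extreme": (r_all <= 0) | (r_all >= k_answered),
            "partial": partial,
            "classification": classification,
        }
    )
    return PersonScores(frame)


@dataclass
class DescriptiveSummary:
    """Distributional summary of household ability in one district."""

    mean: float
    standard_error: float
    median: float
    mode: float
    sd: float
    variance: float
    kurtosis: float  #: excess kurtosis (normal = 0), small-sample corrected
    skewness: float
    range: float
    min: float
    max: float
    ci95_halfwidth: float
    n_used: int

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n_used" else float(v)) for k, v in vars(self).items()}


def district_summary(scores) -> DescriptiveSummary:
    """Summary statistics over households with finite ability estimates.

    ``scores`` is a :class:`PersonScores` or a 1-d array of theta values.
    The standard error is sd/sqrt(n_used) and the 95% half-width uses the
    normal quantile.  Because theta is constant within a raw score, the mode
    (most frequent value, smallest on ties) is well defined.
    """
    theta = scores.theta if isinstance(scores, PersonScores) else np.asarray(scores, float)
    theta = theta[np.isfinite(theta)]
    n = theta.size
    if n < 2:
        raise UserInputError("need at least 2 scored households to summarize")
    s = pd.Series(theta)
    sd = float(s.std(ddof=1))
    sem = sd / np.sqrt(n)
    return DescriptiveSummary(
        mean=float(s.mean()),
        standard_error=sem,
        median=float(s.median()),
        mode=float(s.mode().iloc[0]),
        sd=sd,
        variance=sd**2,
        kurtosis=float(s.kurt()),
        skewness=float(s.skew()),
        range=float(s.max() - s.min()),
        min=float(s.min()),
        max=float(s.max()),
        ci95_halfwidth=_Z975 * sem,
        n_used=n,
    )
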