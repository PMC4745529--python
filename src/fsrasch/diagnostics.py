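"""Item-fit statistics, subgroup homogeneity check, item characteristic curves.

Outfit is the unweighted item chi-square ``sum_v z_vi^2`` of standardized
residuals ``z_vi = (X_vi - P_vi) / sqrt(P_vi (1 - P_vi))`` over non-extreme
households, divided by its degrees of freedom to give a mean-square (MSQ)
with expectation near 1 under the model; the conventional acceptable band is
0.5-1.5.  A standardized (Wilson-Hilferty cube-root) form is reported
alongside.

The subgroup homogeneity check splits households at the median raw score
(ties to the lower group), recalibrates each subgroup by CML, and compares
twice the gain in conditional log-likelihood to a chi-square reference with
(number of jointly estimable items - 1) degrees of freedom — the classical
likelihood-ratio test of item-parameter invariance across score groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .cml import ItemParameters, fit_cml
from .coding import BinaryResponseMatrix, as_binary_matrix
from .errors import InestimableItemError, UserInputError
from .persons import PersonScores

__all__ = [
    "ItemFitStats",
    "ModelCheckResult",
    "ICCData",
    "standardized_residuals",
    "outfit",
    "graphical_model_check",
    "icc",
]

_PCLIP = 1e-12


@dataclass
class ItemFitStats:
    """Per-item outfit statistics (chi-square, mean-square, standardized)."""

    frame: pd.DataFrame  # columns: item, outfit_chisq, df, outfit_msq, outfit_t
    average_msq: float
    average_t: float

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        avg = pd.DataFrame(
            [{"item": "average", "outfit_msq": self.average_msq, "outfit_t": self.average_t}]
        )
        pd.concat([df, avg], ignore_index=True).to_csv(path, index=False)


def _probabilities(theta, beta):
    """P_vi = expit(theta_v + beta_i), clipped away from 0/1."""
    P = expit(theta[:, None] + beta[None, :])
    if np.any(P <= _PCLIP) or np.any(P >= 1 - _PCLIP):
        warnings.warn("response probabilities clipped at 1e-12", RuntimeWarning)
    return np.clip(P, _PCLIP, 1 - _PCLIP)


def standardized_residuals(data, params: ItemParameters, thetas: PersonScores):
    """Standardized residual matrix over households with finite theta.

    Returns ``(Z, mask)`` where ``mask`` selects the scored (non-extreme,
    complete) households of ``data`` and ``Z`` has one row per such household.
    """
    m = as_binary_matrix(data)
    theta = thetas.theta
    if theta.shape[0] != m.n:
        raise UserInputError("thetas do not match the data rows")
    mask = np.isfinite(theta) & ~np.isnan(m.X).any(axis=1)
    X = m.X[mask]
    P = _probabilities(theta[mask], np.asarray(params.beta, float))
    return (X - P) / np.sqrt(P * (1 - P)), mask


def outfit(data, params: ItemParameters, thetas: PersonScores) -> ItemFitStats:
    """Outfit chi-square, mean-square and standardized form per item.

    The chi-square sums ``z^2`` over the ``n_used`` scored households; its
    degrees of freedom are taken as ``n_used - 1``.  The standardized form is
    the Wilson-Hilferty transform of the mean-square using the model-implied
    variance of the statistic.
    """
    m = as_binary_matrix(data)
    Z, mask = standardized_residuals(data, params, thetas)
    n_used = int(mask.sum())
    if n_used < 10:
        warnings.warn(f"only {n_used} scored households; outfit is unstable", RuntimeWarning)
    df = n_used - 1
    chisq = (Z**2).sum(axis=0)
    msq = chisq / df

    P = _probabilities(thetas.theta[mask], np.asarray(params.beta, float))
    # Var(z^2) per cell = (1 - 3PQ)/(PQ) - 1; variance of the mean-square
    PQ = P * (1 - P)
    var_u = ((1 - 3 * PQ) / PQ - 1).sum(axis=0) / df**2
    q = np.sqrt(var_u)
    t = (np.cbrt(msq) - 1) * (3 / q) + q / 3

    frame = pd.DataFrame(
        {
            "item": list(m.item_id),
            "outfit_chisq": chisq,
            "df": df,
            "outfit_msq": msq,
            "outfit_t": t,
        }
    )
    return ItemFitStats(frame=frame, average_msq=float(msq.mean()), average_t=float(t.mean()))


@dataclass
class ModelCheckResult:
    """Median-split likelihood-ratio homogeneity check."""

    split_rule: str
    median_score: float
    items_used: list
    items_dropped: list
    params_low: ItemParameters
    params_high: ItemParameters
    params_full: ItemParameters
    lr_stat: float
    df: int
    p_value: float
    band_halfwidth: np.ndarray = field(repr=False, default=None)
    #: 1.96 * sqrt(se_low^2 + se_high^2) per item, for the scatter plot

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "split_rule": self.split_rule,
            "median_score": float(self.median_score),
            "items_used": list(self.items_used),
            "items_dropped": list(self.items_dropped),
            "lr_stat": float(self.lr_stat),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "beta_low": {i: float(b) for i, b in zip(self.items_used, self.params_low.beta)},
            "beta_high": {i: float(b) for i, b in zip(self.items_used, self.params_high.beta)},
            "beta_full": {i: float(b) for i, b in zip(self.items_used, self.params_full.beta)},
        }


def _subset_matrix(m: BinaryResponseMatrix, row_mask, items) -> BinaryResponseMatrix:
    cols = [m.item_id.index(i) if isinstance(m.item_id, list) else list(m.item_id).index(i) for i in items]
    return BinaryResponseMatrix(
        X=m.X[np.ix_(row_mask, cols)],
        household_id=[h for h, keep in zip(m.household_id, row_mask) if keep],
        item_id=list(items),
        district=None
        if m.district is None
        else [d for d, keep in zip(m.district, row_mask) if keep],
    )


def _estimable_items(m: BinaryResponseMatrix, items):
    """Items with non-extreme totals among this group's non-extreme households."""
    sub = _subset_matrix(m, np.ones(m.n, bool), items)
    Xc = sub.X[~np.isnan(sub.X).any(axis=1)].astype(int)
    r = Xc.sum(axis=1)
    ne = (r > 0) & (r < len(items))
    s = Xc[ne].sum(axis=0)
    n_used = int(ne.sum())
    return [i for i, si in zip(items, s) if 0 < si < n_used]


def graphical_model_check(data, alpha: float = 0.05) -> ModelCheckResult:
    """Likelihood-ratio test of item-parameter invariance across score halves.

    Households are split at the median raw score — strictly above the median
    versus at or below it — and items are recalibrated within each subgroup.
    Items inestimable in either subgroup are dropped from all three fits.
    Under homogeneity ``2 (l_low + l_high - l_full)`` is chi-square with
    ``k_used - 1`` degrees of freedom.
    """
    m = as_binary_matrix(data)
    r = m.raw_scores()
    med = float(np.median(r))
    high = r > med
    low = ~high
    if high.sum() == 0 or low.sum() == 0:
        raise UserInputError("median split produced an empty subgroup")

    items = list(m.item_id)
    dropped: list = []
    # iterate: dropping items changes subgroup scores, which can change
    # estimability; stops quickly in practice
    for _ in range(len(items)):
        est_low = set(_estimable_items(_subset_matrix(m, low, items), items))
        est_high = set(_estimable_items(_subset_matrix(m, high, items), items))
        keep = [i for i in items if i in est_low and i in est_high]
        if keep == items:
            break
        dropped += [i for i in items if i not in keep]
        items = keep
        if len(items) < 2:
            raise InestimableItemError(
                dropped, message="fewer than 2 items estimable in both subgroups"
            )

    fit_low = fit_cml(_subset_matrix(m, low, items))
    fit_high = fit_cml(_subset_matrix(m, high, items))
    fit_full = fit_cml(_subset_matrix(m, np.ones(m.n, bool), items))

    lr = 2.0 * (fit_low.cond_loglik + fit_high.cond_loglik - fit_full.cond_loglik)
    lr = max(lr, 0.0)
    df = len(items) - 1
    p = float(chi2.sf(lr, df))
    band = 1.959963984540054 * np.sqrt(
        fit_low.params.se_beta**2 + fit_high.params.se_beta**2
    )
    return ModelCheckResult(
        split_rule="raw score > median vs <= median (ties low)",
        median_score=med,
        items_used=items,
        items_dropped=dropped,
        params_low=fit_low.params,
        params_high=fit_high.params,
        params_full=fit_full.params,
        lr_stat=float(lr),
        df=df,
        p_value=p,
        band_halfwidth=band,
    )


@dataclass
class ICCData:
    """Item characteristic curves P_i(theta) on a common ability grid."""

    theta_grid: np.ndarray
    curves: pd.DataFrame  # one column per item, indexed by grid position
    item_order: list  #: items sorted left-to-right by increasing difficulty

    def to_csv(self, path) -> None:
        out = self.curves.copy()
        out.insert(0, "theta", self.theta_grid)
        out.to_csv(path, index=False)


def icc(params: ItemParameters, theta_grid=None) -> ICCData:
    """Evaluate each item's response curve on an ability grid.

    ``P_i(theta) = expit(theta - eta_i)`` rises from 0 to 1, crosses 0.5 at
    ``theta = eta_i``, and shifts right as difficulty increases; under the
    Rasch model all curves share the unit slope and never cross.
    """
    if theta_grid is None:
        span = np.abs(params.eta).max() + 4.0
        theta_grid = np.linspace(-span, span, 201)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if not np.all(np.isfinite(theta_grid)):
        raise UserInputError("theta grid must be finite")
    P = expit(theta_grid[:, None] - params.eta[None, :])
    curves = pd.DataFrame(P, columns=list(params.item_id))
    order = [params.item_id[j] for j in np.argsort(params.eta)]
    return ICCData(theta_grid=theta_grid, curves=curves, item_order=order)


def plot_model_check(result: ModelCheckResult, path=None):
    """Scatter of subgroup easiness estimates with identity line and bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = result.params_low.beta, result.params_high.beta
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(x, y, yerr=result.band_halfwidth, fmt="o", ms=4, lw=0.8, capsize=2)
    lim = [min(x.min(), y.min()) - 0.5, max(x.max(), y.max()) + 0.5]
    ax.plot(lim, lim, "k--", lw=1)
    for i, item in enumerate(result.items_used):
        ax.annotate(item, (x[i], y[i]), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("easiness, raw score <= median")
    ax.set_ylabel("easiness, raw score > median")
    ax.set_title(f"LR = {result.lr_stat:.2f}, df = {result.df}, p = {result.p_value:.3f}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_icc(data: ICCData, path=None):
    """Item characteristic curves, labeled in difficulty order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for item in data.item_order:
        ax.plot(data.theta_grid, data.curves[item], lw=1, label=item)
    ax.set_xlabel("household ability (logits)")
    ax.set_ylabel("P(affirmative)")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
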