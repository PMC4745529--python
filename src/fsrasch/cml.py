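"""Conditional maximum likelihood (CML) calibration of dichotomous Rasch items.

The Rasch model puts ``logit P(X_vi = 1) = theta_v + beta_i`` with household
ability ``theta_v`` and item easiness ``beta_i`` (difficulty is
``eta_i = -beta_i``).  Because the raw score ``r_v = sum_i X_vi`` is sufficient
for ``theta_v``, conditioning on it removes the person parameters entirely:
with ``eps_i = exp(beta_i)`` and ``gamma_r`` the elementary symmetric
functions of ``eps``, the conditional log-likelihood is

    l(beta) = sum_i s_i beta_i - sum_r n_r log gamma_r(eps)

where ``s_i`` is the item total and ``n_r`` the number of households with raw
score ``r``, both over non-extreme households (r = 0 and r = k patterns have
conditional probability one and contribute nothing).  ``l`` is invariant to a
common shift of ``beta``; the scale origin is fixed by the sum-zero
normalization ``sum_i beta_i = 0``, and the Newton iteration runs in the
orthonormal (Helmert) basis of that subspace with the analytic gradient and
observed-information Hessian assembled from ESF derivatives.  Standard errors
are taken from the inverse information projected onto the same subspace and
are identical whether the item is reported as easiness or difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, helmert, LinAlgError

from .coding import as_binary_matrix
from .errors import ConvergenceError, InestimableItemError, UserInputError
from .esf import _log_esf, _log_esf_loo, _log_esf_pairs

__all__ = [
    "ItemParameters",
    "CMLFitResult",
    "conditional_loglik",
    "fit_cml",
    "standard_errors",
    "report_eta_beta",
]


@dataclass
class ItemParameters:
    """Calibrated item locations under sum-zero normalization.

    ``beta`` is easiness (large = readily affirmed, i.e. an item endorsed even
    by relatively food-secure households); ``eta = -beta`` is difficulty.
    """

    item_id: list
    beta: np.ndarray
    se_beta: np.ndarray | None = None
    normalization: str = "sum_zero"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.se_beta is not None:
            self.se_beta = np.asarray(self.se_beta, dtype=float)

    @property
    def k(self) -> int:
        return self.beta.shape[0]

    @property
    def eta(self) -> np.ndarray:
        """Difficulty, eta_i = -beta_i exactly."""
        return -self.beta

    @property
    def se_eta(self) -> np.ndarray | None:
        return self.se_beta

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"item": self.item_id, "eta": self.eta, "beta": self.beta})
        df["se"] = self.se_beta if self.se_beta is not None else np.nan
        return df[["item", "eta", "se", "beta"]]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ItemParameters":
        df = pd.read_csv(path)
        se = df["se"].to_numpy() if "se" in df.columns else None
        return cls(item_id=df["item"].tolist(), beta=df["beta"].to_numpy(), se_beta=se)


@dataclass
class CMLFitResult:
    """Converged CML fit: parameters plus the sufficient statistics used."""

    params: ItemParameters
    cond_loglik: float
    item_totals: np.ndarray  #: s_i over non-extreme households
    score_freqs: np.ndarray  #: n_r for r = 0..k over all households
    n_used: int  #: households with non-extreme raw score
    n_iter: int
    grad_norm: float
    hessian: np.ndarray = field(repr=False, default=None)  #: full-space observed info (negated)

    def to_report(self) -> dict:
        return {
            "cond_loglik": float(self.cond_loglik),
            "n_used": int(self.n_used),
            "n_households": int(self.score_freqs.sum()),
            "score_freqs": {str(r): int(c) for r, c in enumerate(self.score_freqs)},
            "item_totals": {i: int(s) for i, s in zip(self.params.item_id, self.item_totals)},
            "convergence": {"iterations": int(self.n_iter), "grad_norm": float(self.grad_norm)},
            "normalization": self.params.normalization,
        }


def _suffstats(data):
    """Item totals s_i, score frequencies n_r and complete-case mask.

    Households with any missing item are dropped from calibration (the
    conditional likelihood assumes a complete 0/1 matrix); person scoring
    handles partial response separately.
    """
    m = as_binary_matrix(data)
    X = m.X
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete].astype(int)
    k = m.k
    r = Xc.sum(axis=1)
    nonextreme = (r > 0) & (r < k)
    s = Xc[nonextreme].sum(axis=0).astype(float)
    n_r = np.bincount(r, minlength=k + 1).astype(int)
    return m, Xc, s, n_r, int(nonextreme.sum()), complete


def _check_estimable(s, n_used, item_id):
    bad = [i for i, si in zip(item_id, s) if si <= 0 or si >= n_used]
    if bad:
        raise InestimableItemError(bad)


def _negloglik_parts(beta, s, n_r, want_grad=False, want_hess=False):
    """Conditional log-likelihood and derivatives from sufficient statistics."""
    k = beta.shape[0]
    r_pos = np.flatnonzero(n_r[1:k]) + 1  # non-extreme scores actually observed
    nr = n_r[r_pos].astype(float)
    logg = _log_esf(beta)
    ll = float(s @ beta - nr @ logg[r_pos])
    if not (want_grad or want_hess):
        return ll, None, None
    logd = _log_esf_loo(beta)
    # pi[t, i] = E[X_i | r = r_pos[t]] = eps_i * gamma_{r-1}^{(i)} / gamma_r
    pi = np.exp(beta[None, :] + logd[:, r_pos - 1].T - logg[r_pos][:, None])
    grad = s - nr @ pi
    hess = None
    if want_hess:
        logp = _log_esf_pairs(beta)
        bsum = beta[:, None] + beta[None, :]
        hess = np.zeros((k, k))
        for t, r in enumerate(r_pos):
            if r >= 2:
                m2 = np.exp(bsum + logp[:, :, r - 2] - logg[r])
            else:
                m2 = np.zeros((k, k))
            np.fill_diagonal(m2, pi[t])
            hess -= nr[t] * (m2 - np.outer(pi[t], pi[t]))
    return ll, grad, hess


def conditional_loglik(beta, data) -> float:
    """Conditional log-likelihood of easiness vector ``beta`` on ``data``.

    Extreme-score households contribute zero.  ``beta`` need not be centered
    (the value is invariant to a common shift, which callers may exploit to
    check the normalization).
    """
    beta = np.asarray(beta, dtype=float)
    m, _, s, n_r, n_used, _ = _suffstats(data)
    if beta.shape[0] != m.k:
        raise UserInputError(f"beta has {beta.shape[0]} entries for {m.k} items")
    ll, _, _ = _negloglik_parts(beta, s, n_r)
    return ll


def _newton_cml(s, n_r, k, gtol=1e-6, max_iter=100):
    """Maximize the conditional likelihood in the sum-zero subspace."""
    B = helmert(k).T  # (k, k-1), orthonormal columns spanning {beta: sum beta = 0}
    delta = np.zeros(k - 1)
    beta = B @ delta
    ll, grad, hess = _negloglik_parts(beta, s, n_r, True, True)
    for it in range(1, max_iter + 1):
        gd = B.T @ grad
        gnorm = float(np.linalg.norm(gd))
        if gnorm < gtol:
            return beta, ll, hess, it - 1, gnorm
        Hd = B.T @ hess @ B
        try:
            step = cho_solve(cho_factor(-Hd), gd)
        except LinAlgError:
            step = np.linalg.solve(-Hd + 1e-8 * np.eye(k - 1), gd)
        # damped step: halve until the conditional likelihood does not
        # deteriorate beyond its own roundoff scale (near the optimum the
        # true gain falls below float resolution of ll)
        t = 1.0
        ll_tol = 1e-9 * (1.0 + abs(ll))
        for _ in range(40):
            cand = B @ (delta + t * step)
            ll_new, _, _ = _negloglik_parts(cand, s, n_r)
            if ll_new > ll - ll_tol:
                break
            t *= 0.5
        delta = delta + t * step
        beta = B @ delta
        ll, grad, hess = _negloglik_parts(beta, s, n_r, True, True)
    gnorm = float(np.linalg.norm(B.T @ grad))
    if gnorm >= gtol:
        raise ConvergenceError(gnorm, max_iter)
    return beta, ll, hess, max_iter, gnorm


def _se_from_hessian(hess, k):
    """SEs from the observed information projected onto the sum-zero subspace."""
    B = helmert(k).T
    Hd = B.T @ hess @ B
    try:
        cov_d = np.linalg.inv(-Hd)
    except LinAlgError as exc:  # pragma: no cover - singular info is pathological
        raise InestimableItemError([], message=f"singular information matrix: {exc}")
    cov = B @ cov_d @ B.T
    return np.sqrt(np.diag(cov)), cov


def fit_cml(data, gtol=1e-6, max_iter=100) -> CMLFitResult:
    """Calibrate item easiness by CML under sum-zero normalization.

    Parameters
    ----------
    data : BinaryResponseMatrix, DataFrame or (n, k) 0/1 array.
    gtol : gradient-norm convergence tolerance (the score equations
        ``s_i = sum_r n_r eps_i gamma_{r-1}^{(i)} / gamma_r`` hold to this
        accuracy at the solution).
    max_iter : Newton iteration cap.

    Raises
    ------
    InestimableItemError : an item affirmed by none or all non-extreme
        households has no finite estimate.
    ConvergenceError : the gradient tolerance was not reached.
    """
    m, _, s, n_r, n_used, _ = _suffstats(data)
    if m.k < 2:
        raise UserInputError("CML calibration needs at least 2 items")
    if n_used < 1:
        raise UserInputError("no households with non-extreme raw scores")
    _check_estimable(s, n_used, m.item_id)
    beta, ll, hess, n_iter, gnorm = _newton_cml(s, n_r, m.k, gtol, max_iter)
    se, _ = _se_from_hessian(hess, m.k)
    params = ItemParameters(item_id=list(m.item_id), beta=beta, se_beta=se)
    return CMLFitResult(
        params=params,
        cond_loglik=ll,
        item_totals=s,
        score_freqs=n_r,
        n_used=n_used,
        n_iter=n_iter,
        grad_norm=gnorm,
        hessian=hess,
    )


def standard_errors(result: CMLFitResult) -> ItemParameters:
    """(Re)compute SEs from a converged fit's observed information."""
    se, _ = _se_from_hessian(result.hessian, result.params.k)
    result.params.se_beta = se
    return result.params


def report_eta_beta(params: ItemParameters) -> dict:
    """Two-table reporting convention for a sum-zero calibration.

    Returns a dict with a ``difficulty`` frame listing eta (and SE) for items
    2..k only — the first item's location being implied by the normalization —
    and an ``easiness`` frame listing beta for all k items.  The redundancy is
    exposed as ``beta_first_from_eta = -sum_{i>=2} beta_i = sum_{i>=2} eta_i``,
    which equals ``beta_1`` exactly under sum-zero.
    """
    full = params.to_frame()[["item", "eta", "se", "beta"]]
    difficulty = full.iloc[1:][["item", "eta", "se"]].reset_index(drop=True)
    easiness = full[["item", "beta", "se"]]
    return {
        "difficulty": difficulty,
        "easiness": easiness,
        "beta_first_from_eta": float(difficulty["eta"].sum()),
    }
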