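"""Elementary symmetric functions (ESFs) of item easiness transforms.

The conditional likelihood of the dichotomous Rasch model normalises each
response-pattern probability by ``gamma_r``, the order-``r`` elementary
symmetric function of ``eps_i = exp(beta_i)``::

    gamma_r = sum over all size-r item subsets S of  prod_{i in S} eps_i

with ``gamma_0 = 1`` and ``gamma_k = prod_i eps_i``.  The score equations and
the conditional information additionally need the first partial derivatives
``d gamma_r / d eps_i = gamma_{r-1}^{(i)}``, i.e. the ESFs of order ``r-1``
over the items excluding ``i``, and (for the Hessian) the pairwise-excluded
ESFs ``gamma^{(i,j)}``.

Everything is computed with the summation recursion

    gamma_r(eps_1..eps_m) = gamma_r(eps_1..eps_{m-1}) + eps_m * gamma_{r-1}(eps_1..eps_{m-1})

carried out in log space (``logaddexp``), which is stable for easiness values
far beyond anything a survey scale produces (|beta| up to several hundred).
The difference recursion, which is cheaper but catastrophically cancels, is
deliberately not used at any derivative order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UserInputError

__all__ = ["ESFTable", "esf", "esf_derivatives"]


def _log_esf(log_eps: np.ndarray) -> np.ndarray:
    """Log ESFs of all orders 0..k for the items in ``log_eps``."""
    k = log_eps.shape[0]
    logg = np.full(k + 1, -np.inf)
    logg[0] = 0.0
    for le in log_eps:
        logg[1:] = np.logaddexp(logg[1:], le + logg[:-1])
    return logg


def _log_esf_loo(log_eps: np.ndarray) -> np.ndarray:
    """Leave-one-out log ESFs.

    Returns an array of shape ``(k, k)`` whose row ``i`` holds the log ESFs of
    orders ``0..k-1`` over the items excluding ``i``.
    """
    k = log_eps.shape[0]
    out = np.empty((k, k))
    idx = np.arange(k)
    for i in range(k):
        out[i] = _log_esf(log_eps[idx != i])
    return out


def _log_esf_pairs(log_eps: np.ndarray) -> np.ndarray:
    """Pairwise-excluded log ESFs.

    Returns shape ``(k, k, k-1)``: entry ``[i, j, r]`` is the log ESF of order
    ``r`` over the items excluding both ``i`` and ``j`` (``i != j``; the
    diagonal is left as -inf and must not be read).
    """
    k = log_eps.shape[0]
    out = np.full((k, k, k - 1), -np.inf)
    idx = np.arange(k)
    for i in range(k):
        for j in range(i + 1, k):
            g = _log_esf(log_eps[(idx != i) & (idx != j)])
            out[i, j] = g
            out[j, i] = g
    return out


@dataclass
class ESFTable:
    """ESFs and first derivatives for one easiness vector.

    Values are stored on the log scale; the ``gamma`` / ``dgamma`` properties
    exponentiate on access (and may overflow for extreme inputs — the log
    attributes are the primary representation).
    """

    log_eps: np.ndarray  #: log eps_i = beta_i, shape (k,)
    log_gamma: np.ndarray  #: log gamma_r, r = 0..k, shape (k+1,)
    log_dgamma: np.ndarray | None = None  #: row i: log gamma_r^{(i)}, r = 0..k-1

    @property
    def k(self) -> int:
        return self.log_eps.shape[0]

    @property
    def epsilons(self) -> np.ndarray:
        return np.exp(self.log_eps)

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)

    @property
    def dgamma(self) -> np.ndarray | None:
        return None if self.log_dgamma is None else np.exp(self.log_dgamma)


def esf(epsilons) -> ESFTable:
    """Compute ``gamma_0..gamma_k`` for a vector of positive ``eps`` values.

    Parameters
    ----------
    epsilons : array-like of shape (k,)
        Strictly positive values ``eps_i = exp(beta_i)``.

    Returns
    -------
    ESFTable with ``log_gamma`` filled (``log_dgamma`` is ``None`` until
    :func:`esf_derivatives` is called).
    """
    eps = np.asarray(epsilons, dtype=float)
    if eps.ndim != 1 or eps.size < 1:
        raise UserInputError("epsilons must be a 1-d vector with k >= 1")
    if not np.all(eps > 0) or not np.all(np.isfinite(eps)):
        raise UserInputError("all epsilons must be finite and strictly positive")
    log_eps = np.log(eps)
    return ESFTable(log_eps=log_eps, log_gamma=_log_esf(log_eps))


def esf_derivatives(table: ESFTable) -> ESFTable:
    """Fill the first partial derivatives ``gamma_r^{(i)}`` on an ESF table.

    Row ``i`` of ``log_dgamma`` holds the log ESFs of orders ``0..k-1`` over
    the items excluding ``i``, so that
    ``d gamma_r / d eps_i = exp(log_dgamma[i, r-1])`` and the identity
    ``sum_i eps_i * gamma_{r-1}^{(i)} = r * gamma_r`` holds to relative 1e-10.
    """
    if table.log_gamma is None:
        raise UserInputError("esf() must be run before esf_derivatives()")
    table.log_dgamma = _log_esf_loo(table.log_eps)
    return table
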