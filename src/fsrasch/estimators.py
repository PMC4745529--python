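"""scikit-learn style estimators wrapping the Rasch pipeline.

:class:`RaschCML` is the central object: ``fit`` calibrates item easiness by
conditional maximum likelihood, ``transform`` maps households to ability
estimates, and ``predict`` classifies them food secure / insecure by the sign
of the ability.  :class:`ResponseCoder` turns raw categorical survey tables
into 0/1 matrices so the two compose in a sklearn ``Pipeline``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import cml as _cml
from . import persons as _persons
from .coding import as_binary_matrix, build_binary_matrix, DEFAULT_ITEM_IDS

__all__ = ["RaschCML", "ResponseCoder"]


class ResponseCoder(BaseEstimator, TransformerMixin):
    """Stateless transformer: raw categorical survey table -> 0/1 matrix.

    Parameters
    ----------
    dk_policy : "as_negative" (default) or "as_missing" — how don't-know
        answers on yes/no items are coded.
    level_map : optional mapping of bespoke level spellings to canonical ones.

    After ``transform`` the coding log of the last call is available as
    ``coding_log_``.
    """

    def __init__(self, dk_policy="as_negative", level_map=None):
        self.dk_policy = dk_policy
        self.level_map = level_map

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X, columns=list(DEFAULT_ITEM_IDS))
        item_ids = [c for c in X.columns if c not in ("household_id", "district")]
        matrix, log = build_binary_matrix(
            X, dk_policy=self.dk_policy, level_map=self.level_map, item_ids=item_ids
        )
        self.coding_log_ = log
        return matrix.to_frame()


class RaschCML(BaseEstimator, TransformerMixin):
    """Dichotomous Rasch measurement by conditional maximum likelihood.

    Parameters
    ----------
    extreme_policy : "exclude" (default) or "half_adjust" — extreme raw
        scores (0 or k) either stay unscored (theta = NaN, predict = -1) or
        are scored at r = 0.5 / k - 0.5.
    gtol, max_iter : Newton convergence controls for the calibration.

    Attributes (after ``fit``)
    --------------------------
    easiness_, difficulty_, se_ : per-item location estimates (sum-zero
        normalization) and standard errors; ``difficulty_ = -easiness_``.
    item_id_, n_items_ : item labels and k.
    cond_loglik_, n_iter_, grad_norm_ : calibration diagnostics.
    item_totals_, score_freqs_, n_used_ : sufficient statistics.
    result_ : the full :class:`fsrasch.cml.CMLFitResult`.
    """

    def __init__(self, extreme_policy="exclude", gtol=1e-6, max_iter=100):
        self.extreme_policy = extreme_policy
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        m = as_binary_matrix(X)
        res = _cml.fit_cml(m, gtol=self.gtol, max_iter=self.max_iter)
        self.result_ = res
        self.params_ = res.params
        self.item_id_ = list(res.params.item_id)
        self.n_items_ = res.params.k
        self.easiness_ = res.params.beta
        self.difficulty_ = res.params.eta
        self.se_ = res.params.se_beta
        self.cond_loglik_ = res.cond_loglik
        self.n_iter_ = res.n_iter
        self.grad_norm_ = res.grad_norm
        self.item_totals_ = res.item_totals
        self.score_freqs_ = res.score_freqs
        self.n_used_ = res.n_used
        self.score_theta_map_ = _persons.score_theta_map(res.params)
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise NotFittedError("RaschCML is not fitted; call fit first")

    def score_households(self, X) -> _persons.PersonScores:
        """Full per-household scoring table (raw score, theta, SE, class)."""
        self._check_fitted()
        return _persons.score_households(
            as_binary_matrix(X), self.params_, extreme_policy=self.extreme_policy
        )

    def transform(self, X) -> np.ndarray:
        """Ability estimates as an (n, 1) column; NaN for excluded extremes."""
        return self.score_households(X).theta.reshape(-1, 1)

    def predict(self, X) -> np.ndarray:
        """1 = food secure (theta >= 0), 0 = insecure, -1 = excluded extreme."""
        theta = self.score_households(X).theta
        out = np.where(theta >= 0, 1, 0)
        out[np.isnan(theta)] = -1
        return out.astype(int)

    def score(self, X, y=None) -> float:
        """Conditional log-likelihood of the fitted easiness on ``X``."""
        self._check_fitted()
        return _cml.conditional_loglik(self.easiness_, as_binary_matrix(X))
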