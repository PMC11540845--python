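"""Cumulative-logit model with an analytic score.

``statsmodels``' :class:`OrderedModel` evaluates gradients by finite
differences, which is slow once school indicators and 20 principal
components enter the design (~70 parameters).  This subclass supplies the
closed-form score of the proportional-odds likelihood (Greene-style, with
the chain rule through the incremental-exponential threshold
parameterization statsmodels uses) and a Hessian from central differences
of that score.  The likelihood, parameterization and estimates are
unchanged -- only the derivative evaluation is exact and fast.
"""

from __future__ import annotations

import numpy as np
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_fprime

__all__ = ["FastOrderedLogit"]


class FastOrderedLogit(OrderedModel):
    """OrderedModel(distr='logit') with analytic first derivatives."""

    def __init__(self, endog, exog, **kwargs):
        kwargs.setdefault("distr", "logit")
        super().__init__(endog, exog, **kwargs)

    def score_obs(self, params):
        params = np.asarray(params, dtype=float)
        k = self.exog.shape[1] if self.exog is not None else 0
        low, upp = self._bounds(params)
        with np.errstate(over="ignore", under="ignore"):
            prob = self.prob(low, upp) + 1e-20
            pdf_upp = np.where(np.isfinite(upp), self.pdf(upp), 0.0)
            pdf_low = np.where(np.isfinite(low), self.pdf(low), 0.0)
        n = prob.shape[0]
        c = np.asarray(self.endog, dtype=int).reshape(-1)
        rows = np.arange(n)
        sf = (pdf_upp - pdf_low) / prob
        so_beta = -sf[:, None] * self.exog if k else np.empty((n, 0))
        n_thresh = self.k_levels - 1
        dll_dt = np.zeros((n, n_thresh))
        has_upper = c <= n_thresh - 1
        dll_dt[rows[has_upper], c[has_upper]] += (
            pdf_upp[has_upper] / prob[has_upper])
        has_lower = c >= 1
        dll_dt[rows[has_lower], c[has_lower] - 1] -= (
            pdf_low[has_lower] / prob[has_lower])
        # t_j = q_0 + sum_{m<=j, m>=1} exp(q_m)  =>  d l / d q_m =
        # jac_m * sum_{j >= m} d l / d t_j
        tail = np.cumsum(dll_dt[:, ::-1], axis=1)[:, ::-1]
        jac = np.ones(n_thresh)
        if n_thresh > 1:
            jac[1:] = np.exp(params[k + 1:])
        return np.column_stack([so_beta, tail * jac[None, :]])

    def score(self, params):
        return self.score_obs(params).sum(axis=0)

    def hessian(self, params):
        h = approx_fprime(np.asarray(params, dtype=float), self.score,
                          centered=True)
        return (h + h.T) / 2.0
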