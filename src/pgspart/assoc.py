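"""Per-wave association models.

School grades (4 ordered categories, D < C < B < A, coded 0..3) are
modelled with a proportional-odds (cumulative logit) model: one slope per
predictor shifts all category thresholds, and ``exp(beta)`` is the odds of
a *better* grade per unit of predictor (one SD for a standardized PGS).
Continuous symptom scales are square-root transformed (they are skewed,
nonnegative counts) and modelled with ordinary least squares.

Variance explained by a PGS is the increase in Nagelkerke's pseudo-R²
between nested ordinal models with and without the score,

    R²_N = [1 - exp(2 (l0 - l1) / n)] / [1 - exp(2 l0 / n)],

with ``l0`` the intercept-only log-likelihood.

The multilevel school structure is approximated with fixed school
indicators (or omitted for thin strata) rather than a random intercept;
on simulated cohorts with modest between-school variance the two agree to
second order, and the approximation keeps the ordinal likelihood exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from ._ordinal_fast import FastOrderedLogit
from .exceptions import (ConvergenceError, DegenerateDataError,
                         InputDataError, StructureError)

log = logging.getLogger(__name__)

__all__ = ["AssocResult", "fit_ordinal", "fit_linear_scale",
           "delta_nagelkerke", "nagelkerke_r2", "quintile_contrast",
           "predicted_probabilities", "make_quintiles"]

Z95 = stats.norm.ppf(0.975)

#: minimum observations per school before fixed school indicators are used
SCHOOL_MODE_MIN_OBS = 20


@dataclass
class AssocResult:
    """One fitted effect on the linear-predictor scale."""

    term: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    or_: float | None = None
    ci: tuple[float, float] | None = None
    llf: float = np.nan
    ll_null: float = np.nan
    delta_r2: float | None = None
    wave: object = None
    exog_names: tuple[str, ...] = ()
    covariate_estimates: dict = field(default_factory=dict)
    kind: str = "ordinal"
    categories: tuple = ()
    _fit: object = field(default=None, repr=False, compare=False)

    def to_row(self) -> dict:
        lo, hi = self.ci if self.ci else (None, None)
        return {
            "term": self.term, "wave": self.wave, "beta": self.beta,
            "se": self.se, "z": self.z, "p": self.p, "OR": self.or_,
            "ci_low": lo, "ci_high": hi, "delta_R2": self.delta_r2,
            "n": self.n,
        }


def _school_design(school: np.ndarray | None, mode: str) -> tuple[pd.DataFrame | None, str]:
    if school is None or mode == "none":
        return None, "none"
    school = np.asarray(school)
    if mode == "auto":
        counts = pd.Series(school).value_counts()
        mode = ("fixed-indicators"
                if counts.min() >= SCHOOL_MODE_MIN_OBS else "none")
        log.info("school_mode auto -> %s (min obs/school = %d)",
                 mode, int(counts.min()))
    if mode == "none":
        return None, "none"
    if mode != "fixed-indicators":
        raise InputDataError(f"unknown school_mode {mode!r}")
    dummies = pd.get_dummies(pd.Series(school).astype(str), prefix="school",
                             drop_first=True, dtype=float)
    return dummies.reset_index(drop=True), "fixed-indicators"


def _assemble_exog(pgs: np.ndarray | None, covariates: pd.DataFrame | None,
                   school: np.ndarray | None, school_mode: str,
                   term_name: str) -> pd.DataFrame:
    parts = []
    if pgs is not None:
        parts.append(pd.DataFrame({term_name: np.asarray(pgs, dtype=float)}))
    if covariates is not None and covariates.shape[1]:
        cov = covariates.reset_index(drop=True).astype(float)
        const = cov.columns[cov.nunique() <= 1]
        if len(const):
            log.info("dropping constant covariate columns: %s", list(const))
            cov = cov.drop(columns=const)
        parts.append(cov)
    sch, _ = _school_design(school, school_mode)
    if sch is not None:
        parts.append(sch)
    if not parts:
        raise InputDataError("no predictors supplied")
    return pd.concat(parts, axis=1)


def _complete_cases(endog: pd.Series, exog: pd.DataFrame,
                    ) -> tuple[pd.Series, pd.DataFrame]:
    ok = endog.notna().to_numpy() & ~exog.isna().any(axis=1).to_numpy()
    ndrop = int((~ok).sum())
    if ndrop:
        log.info("dropping %d incomplete cases", ndrop)
    return endog[ok].reset_index(drop=True), exog[ok].reset_index(drop=True)


def intercept_only_loglike(grades: np.ndarray) -> float:
    """Log-likelihood of the saturated-margins (intercept-only) ordinal
    model: ``sum_k n_k log(n_k / n)``."""
    counts = pd.Series(grades).value_counts().to_numpy(dtype=float)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def nagelkerke_r2(llf: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs)


def delta_nagelkerke(fit_with: AssocResult, fit_without: AssocResult) -> float:
    """Increase in Nagelkerke pseudo-R² between nested models (same data)."""
    if fit_with.n != fit_without.n:
        raise StructureError("models fit on different data (n differs)")
    if not set(fit_without.exog_names) <= set(fit_with.exog_names):
        raise StructureError("models are not nested")
    if abs(fit_with.ll_null - fit_without.ll_null) > 1e-6 * max(
            1.0, abs(fit_with.ll_null)):
        raise StructureError("models have different null likelihoods")
    delta = (nagelkerke_r2(fit_with.llf, fit_with.ll_null, fit_with.n)
             - nagelkerke_r2(fit_without.llf, fit_without.ll_null,
                             fit_without.n))
    if delta < -1e-8:
        raise StructureError(
            f"nested model has higher likelihood (delta R2 = {delta:.3g})")
    return max(delta, 0.0)


def fit_ordinal(grades, pgs=None, covariates: pd.DataFrame | None = None,
                school=None, school_mode: str = "auto",
                term_name: str = "pgs", wave=None,
                compute_delta_r2: bool = False) -> AssocResult:
    """Maximum-likelihood proportional-odds fit of ordered grades.

    Positive ``beta`` on the reported term means higher odds of a better
    grade.  ``compute_delta_r2`` refits without the term and stores the
    Nagelkerke increase.  Complete cases only; thresholds are checked to be
    strictly increasing; quasi-separation and non-convergence raise
    :class:`ConvergenceError`.
    """
    endog = pd.Series(np.asarray(grades), name="grade")
    exog = _assemble_exog(pgs, covariates, school, school_mode, term_name)
    endog, exog = _complete_cases(endog, exog)
    observed = np.sort(endog.unique())
    if observed.size < 2:
        raise DegenerateDataError("fewer than 2 observed outcome categories")
    cat = pd.Categorical(endog, categories=list(observed), ordered=True)
    model = FastOrderedLogit(pd.Series(cat), exog)
    with np.errstate(over="ignore"):
        res = model.fit(method="bfgs", maxiter=500, disp=0)
    if not res.mle_retvals.get("converged", False):
        gnorm = float(np.linalg.norm(res.model.score(res.params)))
        res = model.fit(method="nm", maxiter=20000, disp=0, start_params=res.params)
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(
                f"ordinal fit did not converge (gradient norm {gnorm:.3g})")
    k = exog.shape[1]
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.isfinite(bse[:k]).all() or np.abs(params[:k]).max() > 30:
        raise ConvergenceError("quasi-separation: unbounded slope estimate")
    thresholds = model.transform_threshold_params(params)[1:-1]
    if not np.all(np.diff(thresholds) > 0):
        raise ConvergenceError("thresholds not strictly increasing")

    names = list(exog.columns)
    if pgs is not None:
        i = names.index(term_name)
        beta, se = float(params[i]), float(bse[i])
    else:
        beta, se = np.nan, np.nan
        term_name = "(none)"
    ll_null = intercept_only_loglike(endog.to_numpy())
    z = beta / se if se and np.isfinite(se) else np.nan
    result = AssocResult(
        term=term_name, beta=beta, se=se, z=z,
        p=float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        or_=float(np.exp(beta)) if np.isfinite(beta) else None,
        ci=(float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
        if np.isfinite(beta) else None,
        n=len(endog), llf=float(res.llf), ll_null=ll_null, wave=wave,
        exog_names=tuple(names),
        covariate_estimates={nm: float(params[j]) for j, nm in enumerate(names)},
        kind="ordinal", categories=tuple(observed.tolist()), _fit=res,
    )
    if compute_delta_r2 and pgs is not None:
        if exog.shape[1] > 1:
            reduced = fit_ordinal(
                endog.to_numpy(), pgs=None,
                covariates=exog.drop(columns=result.term),
                school=None, school_mode="none", wave=wave)
            result.delta_r2 = delta_nagelkerke(result, reduced)
        else:
            result.delta_r2 = max(
                nagelkerke_r2(result.llf, ll_null, result.n), 0.0)
    return result


def fit_linear_scale(values, pgs, covariates: pd.DataFrame | None = None,
                     school=None, school_mode: str = "auto",
                     term_name: str = "pgs", wave=None,
                     sqrt_transform: bool = True) -> AssocResult:
    """OLS fit of a (square-root transformed) nonnegative symptom scale."""
    y = np.asarray(values, dtype=float)
    if sqrt_transform:
        if np.nanmin(y) < 0:
            raise InputDataError("scale values must be nonnegative")
        y = np.sqrt(y)
    exog = _assemble_exog(pgs, covariates, school, school_mode, term_name)
    endog, exog = _complete_cases(pd.Series(y), exog)
    design = sm.add_constant(exog)
    res = sm.OLS(endog, design).fit()
    i = list(design.columns).index(term_name)
    beta, se = float(res.params.iloc[i]), float(res.bse.iloc[i])
    z = beta / se
    null_llf = float(sm.OLS(endog, np.ones((len(endog), 1))).fit().llf)
    return AssocResult(
        term=term_name, beta=beta, se=se, z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        n=len(endog), llf=float(res.llf), ll_null=null_llf, wave=wave,
        exog_names=tuple(design.columns),
        covariate_estimates={nm: float(res.params.iloc[j])
                             for j, nm in enumerate(design.columns)},
        kind="linear", _fit=res,
    )


def make_quintiles(pgs: np.ndarray, labels=(1, 2, 3, 4, 5)) -> np.ndarray:
    """Quintile membership with deterministic tie-break: stable sort on
    (value, position), then equal-size split."""
    pgs = np.asarray(pgs, dtype=float)
    n = len(pgs)
    if np.unique(pgs).size < 5:
        raise DegenerateDataError("ties prevent quintiles")
    order = np.lexsort((np.arange(n), pgs))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    edges = (np.arange(1, 5) * n) // 5
    return np.asarray(labels)[np.searchsorted(edges, ranks, side="right")]


def quintile_contrast(grades, pgs, covariates: pd.DataFrame | None = None,
                      school=None, school_mode: str = "auto",
                      wave=None) -> pd.DataFrame:
    """Ordinal model with quintile indicators replacing the continuous PGS;
    ORs for Q2..Q5 against the lowest quintile."""
    q = make_quintiles(pgs)
    dummies = pd.get_dummies(pd.Series(q), prefix="Q", dtype=float)
    dummies = dummies.drop(columns="Q_1")
    cov = (dummies if covariates is None
           else pd.concat([dummies,
                           covariates.reset_index(drop=True)], axis=1))
    fit = fit_ordinal(grades, pgs=None, covariates=cov, school=school,
                      school_mode=school_mode, wave=wave)
    res = fit._fit
    names = list(fit.exog_names)
    rows = []
    for qlab in (2, 3, 4, 5):
        nm = f"Q_{qlab}"
        i = names.index(nm)
        b = float(np.asarray(res.params)[i])
        se = float(np.asarray(res.bse)[i])
        z = b / se
        rows.append({
            "quintile": qlab, "beta": b, "se": se, "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "OR": float(np.exp(b)),
            "ci_low": float(np.exp(b - Z95 * se)),
            "ci_high": float(np.exp(b + Z95 * se)),
            "n": fit.n, "wave": wave,
        })
    return pd.DataFrame(rows)


def predicted_probabilities(result: AssocResult,
                            pgs_grid: np.ndarray) -> pd.DataFrame:
    """Per-category probability curves along a PGS grid.

    Covariates are fixed at their reference values: the sample mean, or the
    modal value for binary (0/1) indicator columns.
    """
    if result._fit is None or result.kind != "ordinal":
        raise StructureError("predicted_probabilities needs an ordinal fit")
    res = result._fit
    exog = pd.DataFrame(res.model.exog, columns=list(result.exog_names))
    ref = {}
    for col in exog.columns:
        vals = exog[col]
        uniq = np.unique(vals)
        if len(uniq) <= 2 and set(np.round(uniq, 12)) <= {0.0, 1.0}:
            ref[col] = float(vals.mode().iloc[0])
        else:
            ref[col] = float(vals.mean())
    grid = np.asarray(pgs_grid, dtype=float)
    design = pd.DataFrame({c: np.full(len(grid), ref[c]) for c in exog.columns})
    design[result.term] = grid
    probs = res.model.predict(np.asarray(res.params), exog=design.to_numpy())
    cats = result.categories or tuple(range(probs.shape[1]))
    out = pd.DataFrame(probs, columns=[f"P(grade={k})" for k in cats])
    out.insert(0, "pgs", grid)
    return out
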