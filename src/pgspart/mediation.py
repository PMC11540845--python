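"""Three-model mediation of PGS effects on school performance via symptoms.

The procedure fits, per wave, four effects on the linear-predictor scale
and pools each across waves by fixed-effects IVW meta-analysis:

* path ``a``  - PGS -> mediator (linear model on the square-root
  transformed symptom scale);
* path ``b``  - mediator -> outcome, adjusted for the PGS (ordinal model);
* total ``c`` - PGS -> outcome (ordinal model, no mediator);
* direct ``c'`` - PGS -> outcome adjusted for the mediator (same ordinal
  model that yields ``b``).

The mediation claim is *gated* on both ``a`` and ``b`` being significant
(pooled p < 0.05).  Classification is then made at the Bonferroni-corrected
threshold for the analysis family (default 0.05/6 for three subjects and
two genomic partitions per disorder):

* ``inconsistent/suppression`` - adjusting for the mediator *increases*
  the magnitude of the PGS effect or flips its sign (the two predictors act
  as mutual suppressors);
* ``full``    - the total effect is significant but the direct effect is
  not: the mediator accounts for the association;
* ``partial`` - both remain significant with an attenuated direct effect;
* ``none``    - gate failed or no significant total effect.

The proportion mediated is ``1 - c'/c`` on the linear-predictor (log-odds)
scale; the product-of-paths alternative ``a*b/c`` is available behind a
flag.  Under suppression the quantity is reported for information but is
not a mediation share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc
from .exceptions import InputDataError
from .inference import MetaResult, meta_fixed

log = logging.getLogger(__name__)

__all__ = ["MediationResult", "mediate", "proportion_mediated",
           "BONFERRONI_FAMILY"]

#: default mediation family: 3 subjects x 2 genomic partitions
BONFERRONI_FAMILY = 6


def proportion_mediated(c: float, cprime: float,
                        indirect: float | None = None,
                        method: str = "attenuation") -> float:
    """Fraction of the total effect explained by the mediator.

    ``attenuation`` (default) is ``1 - c'/c``; ``product`` is ``a*b/c``
    with ``indirect = a*b``.  May exceed 1 or be negative under
    suppression, in which case it accompanies the classification rather
    than standing as a mediation share.
    """
    if c == 0:
        raise InputDataError("total effect c = 0: proportion undefined")
    if method == "attenuation":
        return 1.0 - cprime / c
    if method == "product":
        if indirect is None:
            raise InputDataError("product method needs the indirect effect")
        return indirect / c
    raise InputDataError(f"unknown method {method!r}")


@dataclass
class MediationResult:
    path_a: MetaResult
    path_b: MetaResult
    total_c: MetaResult
    direct_cprime: MetaResult
    gate_passed: bool
    classification: str
    proportion: float | None
    bonferroni_threshold: float

    def to_row(self) -> dict:
        return {
            "a": self.path_a.beta, "a_p": self.path_a.p,
            "b": self.path_b.beta, "b_p": self.path_b.p,
            "c": self.total_c.beta, "c_p": self.total_c.p,
            "c_prime": self.direct_cprime.beta,
            "c_prime_p": self.direct_cprime.p,
            "classification": self.classification,
            "proportion_mediated_pct":
                None if self.proportion is None else 100.0 * self.proportion,
        }


def mediate(data: pd.DataFrame, pgs_col: str, mediator_col: str,
            outcome_col: str, covariate_cols: list[str] | None = None,
            wave_col: str = "wave", school_col: str | None = None,
            school_mode: str = "auto", gate_alpha: float = 0.05,
            bonferroni_m: int = BONFERRONI_FAMILY,
            alpha: float = 0.05,
            proportion_method: str = "attenuation") -> MediationResult:
    """Run the full three-model mediation procedure on a cohort table.

    ``data`` holds one row per individual with the PGS, the nonnegative
    mediator scale, the ordinal outcome (integer categories), covariates
    and the wave indicator.  Paths are fitted per wave and pooled; gating
    uses the pooled path p-values.
    """
    if (data[mediator_col] < 0).any():
        raise InputDataError("mediator scale must be nonnegative")
    covariate_cols = covariate_cols or []
    fits_a, fits_b, fits_c, fits_cp = [], [], [], []
    med_z_all = standardized_by_wave(data, mediator_col, wave_col)
    for wv, sub in data.groupby(wave_col):
        covs = sub[covariate_cols].reset_index(drop=True) if covariate_cols \
            else None
        school = sub[school_col].to_numpy() if school_col else None
        med_z = med_z_all.loc[sub.index].to_numpy()
        pgs = sub[pgs_col].to_numpy()
        y = sub[outcome_col].to_numpy()
        fits_a.append(assoc.fit_linear_scale(
            sub[mediator_col].to_numpy(), pgs, covariates=covs,
            school=school, school_mode=school_mode, wave=wv))
        covs_med = pd.DataFrame({"mediator": med_z})
        if covs is not None:
            covs_med = pd.concat([covs_med, covs], axis=1)
        fit_joint = assoc.fit_ordinal(
            y, pgs, covariates=covs_med, school=school,
            school_mode=school_mode, wave=wv)
        fits_cp.append(fit_joint)
        fits_b.append(_reterm(fit_joint, "mediator"))
        fits_c.append(assoc.fit_ordinal(
            y, pgs, covariates=covs, school=school,
            school_mode=school_mode, wave=wv))
    meta_a = meta_fixed(fits_a)
    meta_b = meta_fixed(fits_b)
    meta_c = meta_fixed(fits_c)
    meta_cp = meta_fixed(fits_cp)

    gate = meta_a.p < gate_alpha and meta_b.p < gate_alpha
    thresh = alpha / bonferroni_m
    c, cp = meta_c.beta, meta_cp.beta
    # a sign flip only counts as suppression when the flipped direct effect
    # is itself significant; under full mediation c' ~ 0 with a noise sign
    flipped = np.sign(cp) != np.sign(c) and meta_cp.p < thresh
    if not gate:
        classification, prop = "none", None
    elif flipped or abs(cp) > abs(c):
        classification = "inconsistent/suppression"
        prop = proportion_mediated(
            c, cp, indirect=meta_a.beta * meta_b.beta,
            method=proportion_method)
    elif meta_c.p < thresh and meta_cp.p >= thresh:
        classification = "full"
        prop = proportion_mediated(
            c, cp, indirect=meta_a.beta * meta_b.beta,
            method=proportion_method)
    elif meta_c.p < thresh and meta_cp.p < thresh:
        classification = "partial"
        prop = proportion_mediated(
            c, cp, indirect=meta_a.beta * meta_b.beta,
            method=proportion_method)
    else:
        classification, prop = "none", None
    log.info("mediation: a=%.3f b=%.3f c=%.3f c'=%.3f -> %s",
             meta_a.beta, meta_b.beta, c, cp, classification)
    return MediationResult(
        path_a=meta_a, path_b=meta_b, total_c=meta_c, direct_cprime=meta_cp,
        gate_passed=gate, classification=classification, proportion=prop,
        bonferroni_threshold=thresh,
    )


def standardized_by_wave(data: pd.DataFrame, col: str,
                         wave_col: str) -> pd.Series:
    """Square-root transform then z-score a nonnegative scale per wave, for
    use as a model predictor (keeps coefficients per mediator SD and makes
    the classification invariant to positive rescaling)."""
    vals = np.sqrt(data[col].to_numpy(dtype=float))
    out = pd.Series(index=data.index, dtype=float)
    for _, idx in data.groupby(wave_col).groups.items():
        v = vals[data.index.get_indexer(idx)]
        sd = v.std(ddof=1)
        out.loc[idx] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def _reterm(fit: assoc.AssocResult, name: str) -> assoc.AssocResult:
    """View of a fitted model reporting a different term's estimate."""
    import copy

    b = fit.covariate_estimates[name]
    res = fit._fit
    names = list(fit.exog_names)
    se = float(np.asarray(res.bse)[names.index(name)])
    z = b / se
    from scipy import stats as _st

    out = copy.copy(fit)
    out.term = name
    out.beta = float(b)
    out.se = se
    out.z = z
    out.p = float(2.0 * _st.norm.sf(abs(z)))
    out.or_ = float(np.exp(b))
    return out
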