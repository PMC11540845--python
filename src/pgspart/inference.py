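"""Pooling across genotyping waves and multiplicity control.

Per-wave effects are combined by fixed-effects inverse-variance weighted
(IVW) meta-analysis: ``b = sum(w_k b_k) / sum(w_k)`` with ``w_k = 1/se_k²``
and pooled ``se = (sum w_k)^(-1/2)``.  Cochran's Q is reported for
information only; the pooling model is always fixed-effects.

Multiple testing across an analysis family uses Benjamini-Hochberg
step-up FDR (the default) or Bonferroni.  Sex-stratified contrasts use a
Wald-type z-test on the difference of independent stratum estimates, and
a subsampling procedure re-runs an analysis on repeated without-replacement
subsets of the larger group at the smaller group's size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult, Z95
from .exceptions import ConfigError, InputDataError

log = logging.getLogger(__name__)

__all__ = ["MetaResult", "meta_fixed", "adjust_p", "sex_interaction_wald",
           "bootstrap_subsample", "BootstrapResult"]


@dataclass
class MetaResult:
    """Fixed-effects IVW pooled estimate across waves."""

    beta: float
    se: float
    z: float
    p: float
    or_: float
    ci: tuple[float, float]
    q_heterogeneity: float
    n_waves: int
    n_total: int
    per_wave: list = field(default_factory=list)
    term: str = ""
    delta_r2: float | None = None  # unweighted mean of per-wave increases

    def to_row(self) -> dict:
        return {
            "term": self.term, "beta": self.beta, "se": self.se,
            "z": self.z, "p": self.p, "OR": self.or_,
            "ci_low": self.ci[0], "ci_high": self.ci[1],
            "Q": self.q_heterogeneity, "k": self.n_waves,
            "n": self.n_total, "delta_R2": self.delta_r2,
        }


def meta_fixed(results: list[AssocResult]) -> MetaResult:
    """Pool per-wave results; waves with zero/NaN SE are excluded (logged)."""
    usable = []
    for r in results:
        if r.se is None or not np.isfinite(r.se) or r.se <= 0 or \
                not np.isfinite(r.beta):
            log.warning("excluding wave %r from meta-analysis (bad SE)",
                        r.wave)
            continue
        usable.append(r)
    if not usable:
        raise InputDataError("no usable waves for meta-analysis")
    b = np.array([r.beta for r in usable])
    se = np.array([r.se for r in usable])
    w = se ** -2.0
    beta = float((w * b).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = beta / pooled_se
    q = float((w * (b - beta) ** 2).sum())
    d_r2 = [r.delta_r2 for r in usable if r.delta_r2 is not None]
    return MetaResult(
        beta=beta, se=pooled_se, z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        or_=float(np.exp(beta)),
        ci=(float(np.exp(beta - Z95 * pooled_se)),
            float(np.exp(beta + Z95 * pooled_se))),
        q_heterogeneity=q, n_waves=len(usable),
        n_total=int(sum(r.n for r in usable)),
        per_wave=usable, term=usable[0].term,
        delta_r2=float(np.mean(d_r2)) if d_r2 else None,
    )


def adjust_p(p_values, method: str = "BH",
             m: int | None = None) -> pd.DataFrame:
    """Adjusted p-values: BH step-up (monotone) or Bonferroni.

    ``m`` widens the correction family beyond the supplied p-values (for
    Bonferroni families fixed by design, e.g. 3 subjects x 2 partitions);
    it must be at least the number of p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputDataError("p-values must lie in (0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ConfigError(f"family size m={m_eff} smaller than the "
                          f"{len(p)} supplied p-values")
    if method.upper() == "BH":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m_eff / np.arange(1, len(p) + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.clip(adj_sorted, 0, 1)
    elif method.lower() == "bonferroni":
        adj = np.minimum(p * m_eff, 1.0)
    else:
        raise ConfigError(f"unknown adjustment method {method!r}")
    return pd.DataFrame({"p": p, "p_adjusted": adj, "method": method,
                         "m": m_eff})


def bonferroni_threshold(alpha: float, m: int) -> float:
    return alpha / m


def sex_interaction_wald(result_m, result_f) -> tuple[float, float]:
    """Wald-type z for the difference of two independent stratum effects."""
    b1, s1 = result_m.beta, result_m.se
    b2, s2 = result_f.beta, result_f.se
    z = (b1 - b2) / np.sqrt(s1 ** 2 + s2 ** 2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class BootstrapResult:
    estimates: np.ndarray
    mean: float
    ci: tuple[float, float]
    frac_significant: float
    n_failed: int
    reps: int


def bootstrap_subsample(data: pd.DataFrame, n_target: int, analysis,
                        reps: int = 1000, seed: int = 0,
                        alpha: float = 0.05) -> BootstrapResult:
    """Re-run ``analysis(subset_df) -> (estimate, p)`` on ``reps`` random
    subsets of size ``n_target`` drawn *without replacement*.

    This subsampling design equalizes the sample size of a larger stratum
    to a smaller one (e.g. boys subsampled to the number of girls) so that
    a significant-in-one-stratum result cannot be an artifact of unequal n.
    Failed replicates are skipped and counted.
    """
    if n_target > len(data):
        raise InputDataError("n_target exceeds group size")
    rng = np.random.default_rng(seed)
    est, sig, failed = [], [], 0
    for _ in range(reps):
        idx = rng.choice(len(data), size=n_target, replace=False)
        try:
            b, p = analysis(data.iloc[np.sort(idx)])
        except Exception as exc:  # resample-level failure is not fatal
            log.debug("bootstrap replicate failed: %s", exc)
            failed += 1
            continue
        est.append(b)
        sig.append(p < alpha)
    est_arr = np.asarray(est, dtype=float)
    if est_arr.size == 0:
        raise InputDataError("all bootstrap replicates failed")
    return BootstrapResult(
        estimates=est_arr,
        mean=float(est_arr.mean()),
        ci=(float(np.percentile(est_arr, 2.5)),
            float(np.percentile(est_arr, 97.5))),
        frac_significant=float(np.mean(sig)),
        n_failed=failed, reps=reps,
    )
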