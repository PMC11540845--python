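"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the ordinal oracle
optimizes the cumulative-logit likelihood written from scratch with
Nelder-Mead; the clumping oracle is a plain-Python greedy loop; the HWE
oracle enumerates genotype configurations with exact rational arithmetic.
"""

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def ordinal_nll(params, y, x, n_cat):
    """Negative log-likelihood of the proportional-odds model in the
    (beta, first threshold, log-increments) parameterization."""
    k = x.shape[1]
    beta = params[:k]
    t0 = params[k]
    incr = np.exp(params[k + 1:])
    thresholds = np.concatenate([[t0], t0 + np.cumsum(incr)])
    ext = np.concatenate([[-np.inf], thresholds, [np.inf]])
    xb = x @ beta
    lo = ext[y] - xb
    up = ext[y + 1] - xb
    pr = expit(up) - expit(lo)
    return -np.sum(np.log(np.maximum(pr, 1e-300)))


def fit_ordinal_bruteforce(y, x):
    """Nelder-Mead MLE of the cumulative logit model from multiple starts.

    Returns (beta, thresholds, nll) at the best optimum found.
    """
    y = np.asarray(y, dtype=int)
    x = np.asarray(x, dtype=float)
    cats = np.unique(y)
    y = np.searchsorted(cats, y)
    n_cat = len(cats)
    k = x.shape[1]
    n_par = k + n_cat - 1
    # frequency-based threshold start
    cum = np.cumsum(np.bincount(y, minlength=n_cat)[:-1]) / len(y)
    t_start = np.log(cum / (1.0 - cum))
    p0 = np.zeros(n_par)
    p0[k] = t_start[0]
    if n_cat > 2:
        p0[k + 1:] = np.log(np.maximum(np.diff(t_start), 1e-3))
    best = None
    for jitter in (0.0, 0.3, -0.3):
        start = p0 + jitter
        res = minimize(
            ordinal_nll, start, args=(y, x, n_cat), method="Nelder-Mead",
            options={"maxiter": 50000, "maxfev": 50000,
                     "xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[:k]
    t0 = best.x[k]
    thresholds = np.concatenate(
        [[t0], t0 + np.cumsum(np.exp(best.x[k + 1:]))])
    return beta, thresholds, best.fun


def greedy_clump_oracle(pvals, r2, r2_thresh):
    """Plain-python greedy clumping: visit SNPs by ascending p, keep the
    index SNP, discard all remaining SNPs with r² above threshold."""
    order = sorted(range(len(pvals)), key=lambda j: (pvals[j], j))
    removed = set()
    kept = []
    for j in order:
        if j in removed:
            continue
        kept.append(j)
        for k in range(len(pvals)):
            if k != j and k not in removed and r2[j][k] > r2_thresh:
                removed.add(k)
    return sorted(kept)


def hwe_exact_oracle(n_het, n_hom1, n_hom2):
    """Exact HWE test by direct enumeration with exact rational
    arithmetic (probability of h heterozygotes given allele counts)."""
    from fractions import Fraction

    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * n - rare

    def pmf(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        num = (Fraction(math.factorial(n))
               / (math.factorial(h) * math.factorial(hr)
                  * math.factorial(hc)))
        num *= Fraction(2) ** h
        num *= Fraction(math.factorial(rare) * math.factorial(common),
                        math.factorial(2 * n))
        return num

    hs = list(range(rare % 2, rare + 1, 2))
    probs = {h: pmf(h) for h in hs}
    p_obs = probs[n_het]
    total = sum(p for p in probs.values() if p <= p_obs)
    return float(total)
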