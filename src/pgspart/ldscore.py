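"""Stratified LD-score regression: partitioned SNP-heritability,
enrichment of genome-wide significant hits, and annotation-stratified
cross-trait genetic covariance.

Heritability model.  For trait z-scores the expected association
chi-square of SNP j is

    E[chi2_j] = 1 + N * sum_c tau_c * l(j, c)

where ``l(j, c) = sum_{k in c} r²(j, k)`` is the LD score of j with
annotation c and ``tau_c`` the per-SNP heritability of category c.  A
weighted regression of chi2 on ``N * l(j, c)`` with a free intercept
(absorbing confounding) estimates tau; category heritability aggregates
``h²(C) = sum_{j in C} sum_c tau_c a_jc``.  Standard errors come from a
delete-a-block jackknife (default 200 contiguous blocks).

Cross-trait covariance.  The product of two traits' z-scores satisfies

    E[z1_j z2_j] = sqrt(N1 N2) * sum_c rho_c * l(j, c) / M_c + intercept

with ``rho_c`` the genetic covariance attributable to annotation c and an
intercept absorbing phenotypic correlation in overlapping samples.  This
stratified cross-trait LD-score estimator targets the same estimand as
method-of-moments annotation-stratified covariance tools, with sample
overlap handled by the free intercept.

Regression weights are ``1 / max(l_total, 1)`` (heteroscedasticity only).
Enrichment is reported as (h² share) / (SNP share), with the reciprocal
also emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InputDataError, StructureError

log = logging.getLogger(__name__)

__all__ = ["LDScoreTable", "StratifiedGenArchResult", "compute_ld_scores",
           "block_model_ld_scores", "stratified_h2", "gws_enrichment",
           "stratified_covariance", "cts_style_enrichment"]


@dataclass
class LDScoreTable:
    """Per-variant partitioned LD scores.

    ``scores`` has one column per annotation plus ``total``; ``annotations``
    is the 0/1 membership frame with the same columns (minus ``total``).
    A SNP's score includes itself (r² = 1) whenever it belongs to the
    annotation, so ``l(j, c) >= a_jc`` and ``total >= l(j, c)``.
    """

    scores: pd.DataFrame
    annotations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def names(self) -> list[str]:
        return [c for c in self.scores.columns if c != "total"]

    def m_c(self) -> pd.Series:
        return self.annotations.sum(axis=0)


def _as_annotations(annotations, m: int) -> pd.DataFrame:
    if annotations is None:
        return pd.DataFrame({"all": np.ones(m, dtype=float)})
    ann = pd.DataFrame(annotations).astype(float)
    if len(ann) != m:
        raise StructureError(
            f"annotations cover {len(ann)} SNPs, panel has {m}")
    return ann


def compute_ld_scores(dosages: np.ndarray, annotations=None,
                      window: int = 100) -> LDScoreTable:
    """Partitioned LD scores from a dosage panel.

    ``l(j, c)`` sums the adjusted squared correlation
    ``r~² = r² - (1 - r²) / (n - 2)`` (the small-sample unbiased estimator)
    over SNPs within ``window`` positions of j belonging to c.
    """
    x = np.asarray(dosages, dtype=float)
    n, m = x.shape
    if n < 100:
        log.warning("panel of %d individuals; r² estimates will be noisy", n)
    if n < 3:
        raise InputDataError("need at least 3 individuals for r²")
    ann = _as_annotations(annotations, m)
    a = ann.to_numpy()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    x = x / sd
    out = np.zeros((m, a.shape[1]))
    total = np.zeros(m)
    for j in range(m):
        lo, hi = max(0, j - window), min(m, j + window + 1)
        r = (x[:, lo:hi].T @ x[:, j]) / (n - 1)
        r2 = r ** 2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        r2_adj[j - lo] = 1.0  # self term is exact
        out[j] = r2_adj @ a[lo:hi]
        total[j] = r2_adj.sum()
    scores = pd.DataFrame(out, columns=list(ann.columns))
    scores["total"] = total
    return LDScoreTable(scores=scores, annotations=ann)


def block_model_ld_scores(L: int, B: int, rho,
                          annotations=None) -> LDScoreTable:
    """Population LD scores of the equicorrelated block model: r² is
    ``rho_b²`` between mates of block b, 1 on the diagonal and 0 across
    blocks.  ``rho`` may be a scalar or a per-block array."""
    m = L * B
    ann = _as_annotations(annotations, m)
    a = ann.to_numpy()
    block = np.repeat(np.arange(L), B)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (L,))
    out = np.empty((m, a.shape[1]))
    total = np.empty(m)
    for b in range(L):
        rows = block == b
        in_block = a[rows].sum(axis=0)
        out[rows] = rho[b] ** 2 * in_block + (1.0 - rho[b] ** 2) * a[rows]
        total[rows] = 1.0 + (B - 1) * rho[b] ** 2
    scores = pd.DataFrame(out, columns=list(ann.columns))
    scores["total"] = total
    return LDScoreTable(scores=scores, annotations=ann)


@dataclass
class StratifiedGenArchResult:
    """Per-annotation coefficients of a stratified regression."""

    estimand: str  # "h2" or "covariance"
    coefficients: pd.DataFrame  # per annotation: tau/rho, se, M_c, h2/cov...
    intercept: float
    intercept_se: float
    total: float
    total_se: float

    def by_annotation(self) -> dict[str, float]:
        col = "h2" if self.estimand == "h2" else "covariance"
        return dict(zip(self.coefficients["annotation"],
                        self.coefficients[col]))


def _jackknife_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   n_blocks: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least squares with delete-a-block jackknife.

    Returns (coef, jackknife covariance of coef, per-block pseudovalues'
    delete-one estimates as a (n_blocks, k) array).
    """
    m, k = x.shape
    n_blocks = min(n_blocks, m // max(k + 1, 2))
    if n_blocks < 2:
        raise InputDataError("too few variants for jackknife")
    # column equilibration: keeps the normal equations well-conditioned when
    # regressor scales differ by orders of magnitude (N*l vs intercept)
    col_scale = np.sqrt((x ** 2).mean(axis=0))
    col_scale = np.where(col_scale > 0, col_scale, 1.0)
    x = x / col_scale
    xw = x * w[:, None]
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    xtx_blocks = np.empty((n_blocks, k, k))
    xty_blocks = np.empty((n_blocks, k))
    for b in range(n_blocks):
        s = slice(edges[b], edges[b + 1])
        xtx_blocks[b] = xw[s].T @ x[s]
        xty_blocks[b] = xw[s].T @ y[s]
    xtx = xtx_blocks.sum(axis=0)
    xty = xty_blocks.sum(axis=0)
    try:
        coef = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(
            "rank-deficient annotation design (collinear annotations)"
        ) from exc
    cond = np.linalg.cond(xtx)
    if cond > 1e10:
        raise ConfigError(
            f"rank-deficient annotation design (condition number {cond:.2g})")
    deleted = np.empty((n_blocks, k))
    for b in range(n_blocks):
        deleted[b] = np.linalg.solve(xtx - xtx_blocks[b],
                                     xty - xty_blocks[b])
    coef = coef / col_scale
    deleted = deleted / col_scale
    mean_del = deleted.mean(axis=0)
    dev = deleted - mean_del
    cov = (n_blocks - 1) / n_blocks * (dev.T @ dev)
    return coef, cov, deleted


def _h2_from_tau(tau: np.ndarray, ann: np.ndarray) -> np.ndarray:
    """Aggregate per-annotation h²: for each annotation C, sum over its
    SNPs of the per-SNP heritability implied by all coefficients."""
    per_snp = ann @ tau
    return per_snp @ ann  # vector of h2(C) over annotation columns


def stratified_h2(z: np.ndarray, n_gwas, ld: LDScoreTable,
                  n_blocks: int = 200) -> StratifiedGenArchResult:
    """Stratified SNP-heritability from z-scores and partitioned LD scores.

    Negative category estimates are reported as-is with a warning: they
    indicate near-null categories or model misspecification, and masking
    them would bias aggregate shares.
    """
    z = np.asarray(z, dtype=float)
    m = len(z)
    if m != len(ld):
        raise StructureError("z-scores and LD scores differ in length")
    n_gwas = np.broadcast_to(np.asarray(n_gwas, dtype=float), (m,))
    names = ld.names
    ann = ld.annotations.to_numpy()
    x = np.column_stack([
        np.ones(m),
        n_gwas[:, None] * ld.scores[names].to_numpy(),
    ])
    y = z ** 2
    w = 1.0 / np.maximum(ld.scores["total"].to_numpy(), 1.0)
    coef, cov, deleted = _jackknife_wls(x, y, w, n_blocks)
    tau, tau_cov = coef[1:], cov[1:, 1:]
    h2 = _h2_from_tau(tau, ann)
    # jackknife the aggregation for category SEs
    h2_del = np.vstack([_h2_from_tau(d[1:], ann) for d in deleted])
    nb = len(deleted)
    h2_se = np.sqrt((nb - 1) / nb * ((h2_del - h2_del.mean(0)) ** 2).sum(0))
    m_c = ann.sum(axis=0)
    total = float((ann @ tau).sum())
    tot_del = np.array([(ann @ d[1:]).sum() for d in deleted])
    total_se = float(np.sqrt((nb - 1) / nb * ((tot_del - tot_del.mean()) ** 2
                                              ).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        share = h2 / total if total != 0 else np.full_like(h2, np.nan)
        snp_share = m_c / m
        enrich = share / snp_share
    if (h2 < 0).any():
        log.warning("negative h2 estimate(s) in %s: possible model "
                    "misspecification or null category",
                    [n for n, v in zip(names, h2) if v < 0])
    coefs = pd.DataFrame({
        "annotation": names,
        "tau": tau,
        "tau_se": np.sqrt(np.diag(tau_cov)),
        "M_c": m_c.astype(int),
        "h2": h2,
        "h2_se": h2_se,
        "enrichment": enrich,
        "enrichment_inverse": 1.0 / enrich,
    })
    return StratifiedGenArchResult(
        estimand="h2", coefficients=coefs,
        intercept=float(coef[0]), intercept_se=float(np.sqrt(cov[0, 0])),
        total=total, total_se=total_se,
    )


def stratified_covariance(z1: np.ndarray, z2: np.ndarray, n1, n2,
                          ld: LDScoreTable, n_blocks: int = 200,
                          min_variants: int = 200,
                          ) -> StratifiedGenArchResult:
    """Annotation-stratified genetic covariance of two traits from the
    regression of ``z1*z2`` on ``sqrt(N1 N2) * l(j,c) / M_c`` with a free
    intercept absorbing sample overlap."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    m = len(z1)
    if len(z2) != m or len(ld) != m:
        raise StructureError("traits and LD scores differ in length")
    if m < min_variants:
        raise InputDataError(
            f"only {m} shared variants (<{min_variants}): estimate unstable")
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), (m,))
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), (m,))
    names = ld.names
    m_c = ld.annotations.sum(axis=0).to_numpy()
    if (m_c == 0).any():
        raise ConfigError("annotation with zero SNPs")
    scale = np.sqrt(n1 * n2)
    x = np.column_stack([
        np.ones(m),
        scale[:, None] * ld.scores[names].to_numpy() / m_c[None, :],
    ])
    y = z1 * z2
    w = 1.0 / np.maximum(ld.scores["total"].to_numpy(), 1.0)
    coef, cov, deleted = _jackknife_wls(x, y, w, n_blocks)
    rho, rho_cov = coef[1:], cov[1:, 1:]
    nb = len(deleted)
    tot_del = deleted[:, 1:].sum(axis=1)
    coefs = pd.DataFrame({
        "annotation": names,
        "rho": rho,
        "rho_se": np.sqrt(np.diag(rho_cov)),
        "M_c": m_c.astype(int),
        "covariance": rho,
        "covariance_se": np.sqrt(np.diag(rho_cov)),
    })
    return StratifiedGenArchResult(
        estimand="covariance", coefficients=coefs,
        intercept=float(coef[0]), intercept_se=float(np.sqrt(cov[0, 0])),
        total=float(rho.sum()),
        total_se=float(np.sqrt((nb - 1) / nb
                               * ((tot_del - tot_del.mean()) ** 2).sum())),
    )


def gws_enrichment(p_values: np.ndarray, labels: np.ndarray,
                   p_gws: float = 5e-8) -> dict:
    """Chi-square test of genome-wide significant hits against expectation
    proportional to partition sizes.

    Partitions with an expected count of zero (empty partitions) are merged
    into the largest partition with a warning.
    """
    p_values = np.asarray(p_values, dtype=float)
    labels = np.asarray(labels)
    hits = p_values < p_gws
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise InputDataError("no genome-wide significant hits")
    names, sizes = np.unique(labels, return_counts=True)
    observed = np.array([(hits & (labels == nm)).sum() for nm in names],
                        dtype=float)
    expected = n_hits * sizes / sizes.sum()
    if (expected == 0).any():
        keep = expected > 0
        log.warning("merging zero-expectation partitions: %s",
                    list(names[~keep]))
        big = np.argmax(sizes[keep])
        observed = observed[keep]
        expected = expected[keep]
        names = names[keep]
    chi2, p = stats.chisquare(observed, expected)
    return {
        "chi2": float(chi2), "p": float(p), "df": len(names) - 1,
        "partitions": list(map(str, names)),
        "observed": observed.astype(int).tolist(),
        "expected": expected.tolist(),
        "n_hits": n_hits,
    }


def cts_style_enrichment(z: np.ndarray, n_gwas, partition_mask: np.ndarray,
                         secondary_mask: np.ndarray, ld_computer,
                         mode: str = "anti-target",
                         control_mask: np.ndarray | None = None,
                         n_blocks: int = 200) -> dict:
    """Cell-type-style conditional enrichment of a partition ∩ annotation.

    Builds the *target* annotation ``partition ∩ secondary`` and a
    *reference* annotation per mode: ``secondary ∩ ~partition``
    (``anti-target``: same cell-type signal outside the partition) or
    ``partition ∩ control`` (``control``; the control defaults to all
    SNPs).  Both enter one stratified h² regression together with the
    remainder of the genome, and the one-sided test asks whether the
    target per-SNP coefficient exceeds the reference one, using the
    jackknife covariance of the two coefficients.
    """
    partition_mask = np.asarray(partition_mask, dtype=bool)
    secondary_mask = np.asarray(secondary_mask, dtype=bool)
    target = partition_mask & secondary_mask
    if not target.any():
        log.warning("empty target intersection; skipped")
        return {"skipped": True, "reason": "empty intersection"}
    if mode == "anti-target":
        reference = secondary_mask & ~partition_mask
    elif mode == "control":
        control = (np.ones_like(partition_mask) if control_mask is None
                   else np.asarray(control_mask, dtype=bool))
        reference = partition_mask & control
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    reference = reference & ~target  # disjoint categories, comparable taus
    if not reference.any():
        log.warning("empty or degenerate reference annotation; skipped")
        return {"skipped": True, "reason": "empty or degenerate reference"}
    rest = ~(target | reference)
    ann = pd.DataFrame({"target": target.astype(float),
                        "reference": reference.astype(float)})
    if rest.any():
        ann["rest"] = rest.astype(float)
    ld = ld_computer(ann)
    z = np.asarray(z, dtype=float)
    m = len(z)
    n_gwas = np.broadcast_to(np.asarray(n_gwas, dtype=float), (m,))
    names = ld.names
    x = np.column_stack([
        np.ones(m), n_gwas[:, None] * ld.scores[names].to_numpy()])
    y = z ** 2
    w = 1.0 / np.maximum(ld.scores["total"].to_numpy(), 1.0)
    coef, cov, _ = _jackknife_wls(x, y, w, n_blocks)
    it, ir = names.index("target") + 1, names.index("reference") + 1
    diff = coef[it] - coef[ir]
    var = cov[it, it] + cov[ir, ir] - 2.0 * cov[it, ir]
    zstat = diff / np.sqrt(var)
    return {
        "tau_target": float(coef[it]), "tau_reference": float(coef[ir]),
        "coefficient_diff": float(diff), "z": float(zstat),
        "p_one_sided": float(stats.norm.sf(zstat)),
        "mode": mode, "m_target": int(target.sum()),
        "m_reference": int(reference.sum()),
    }
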