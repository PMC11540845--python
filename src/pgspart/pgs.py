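"""Polygenic scoring over arbitrary variant sets.

A polygenic score is the weighted sum of effect-allele dosages,
``score_i = sum_j w_j d_ij``, over a chosen variant set (a partition, the
shared subset, or everything).  Scores are standardized to mean 0 / SD 1
(sample SD) within each genotyping wave before modelling, matching the
convention of PGS association studies.

Default weights are the harmonized GWAS betas; a greedy LD
clumping+thresholding preparation is provided for sparser weights.  A
continuous-shrinkage posterior (PRS-CS-style) is deliberately not
implemented: the scoring engine consumes any external per-SNP weight
vector, so shrunk weights can be supplied from outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, StructureError
from .sumstats import HarmonizedFrame

log = logging.getLogger(__name__)

__all__ = ["WeightVector", "score", "standardize", "prepare_weights_ct",
           "pgs_correlation", "weights_from_frame"]


@dataclass
class WeightVector:
    """Per-variant scoring weights: key, effect allele, weight."""

    table: pd.DataFrame  # columns: key, effect_allele, weight
    provenance: str = "raw-beta"

    def __post_init__(self) -> None:
        need = {"key", "effect_allele", "weight"}
        if not need <= set(self.table.columns):
            raise StructureError(f"weight table needs columns {sorted(need)}")
        if not np.isfinite(self.table["weight"]).all():
            raise StructureError("non-finite weights")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def weights_from_frame(frame: HarmonizedFrame, trait: str,
                       variant_set: np.ndarray | None = None) -> WeightVector:
    """Raw-beta weights for one trait of a harmonized frame, optionally
    restricted to a variant-key set."""
    v = frame.variants
    tab = pd.DataFrame({
        "key": v["key"].to_numpy(),
        "effect_allele": v["effect_allele"].to_numpy(),
        "weight": v[f"{trait}_beta"].to_numpy(),
    })
    if variant_set is not None:
        tab = tab[tab["key"].isin(np.asarray(variant_set))]
    return WeightVector(table=tab.reset_index(drop=True),
                        provenance=f"raw-beta:{trait}")


def score(dosages: np.ndarray, panel_frame: pd.DataFrame,
          weights: WeightVector,
          variant_set: np.ndarray | None = None) -> np.ndarray:
    """Raw scores ``d @ w`` with effect alleles aligned to dosage coding.

    ``panel_frame`` must carry key / effect_allele / other_allele matching
    the dosage columns (ALT-allele dosage coding).  Weights whose effect
    allele is the panel's *other* allele contribute ``(2 - d) * w``, i.e.
    sign-flipped weight plus a constant, so scores are invariant to allele
    coding up to an additive shift.  Missing dosages are mean-imputed per
    variant.  Weights for variants absent from the panel are ignored with a
    log entry.
    """
    wt = weights.table
    if variant_set is not None:
        vs = np.asarray(variant_set)
        if vs.size == 0:
            raise DegenerateDataError("empty partition: no variants to score")
        wt = wt[wt["key"].isin(vs)]
    if len(wt) == 0:
        raise DegenerateDataError("empty partition: no variants to score")
    if "key" not in panel_frame.columns:
        raise StructureError("panel frame lacks a 'key' column")
    pos = pd.Series(np.arange(len(panel_frame)),
                    index=panel_frame["key"].to_numpy())
    present = wt["key"].isin(pos.index)
    if not present.all():
        log.info("%d weight(s) not in panel; ignored", int((~present).sum()))
        wt = wt[present]
        if len(wt) == 0:
            raise DegenerateDataError("no scored variants present in panel")
    idx = pos[wt["key"]].to_numpy()
    w = wt["weight"].to_numpy(dtype=float)
    panel_ea = panel_frame["effect_allele"].to_numpy()[idx]
    flip = panel_ea != wt["effect_allele"].to_numpy()
    d = np.asarray(dosages, dtype=float)[:, idx]
    if np.isnan(d).any():
        mu = np.nanmean(d, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(d))
        d = d.copy()
        d[nan_r, nan_c] = mu[nan_c]
    signed_w = np.where(flip, -w, w)
    const = float((w[flip] * 2.0).sum())
    return d @ signed_w + const


def standardize(raw: np.ndarray, waves: np.ndarray | None = None) -> np.ndarray:
    """Within-wave z-scores using the sample (n-1) standard deviation."""
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    waves = np.zeros(len(raw), dtype=int) if waves is None else np.asarray(waves)
    for wv in np.unique(waves):
        m = waves == wv
        if m.sum() < 2:
            raise DegenerateDataError(
                f"stratum {wv!r} has fewer than 2 individuals")
        sd = raw[m].std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(
                f"degenerate score distribution in stratum {wv!r}")
        out[m] = (raw[m] - raw[m].mean()) / sd
    return out


def prepare_weights_ct(frame: HarmonizedFrame, trait: str,
                       dosages: np.ndarray, panel_frame: pd.DataFrame,
                       r2_thresh: float = 0.1, p_thresh: float = 1.0,
                       window: int | None = None) -> WeightVector:
    """Greedy LD clumping + p-value thresholding weight preparation.

    Index SNPs are visited in order of ascending GWAS p; neighbours within
    ``window`` SNPs (default: unrestricted) with panel ``r^2`` above
    ``r2_thresh`` are removed.  Survivors with ``p <= p_thresh`` keep their
    harmonized beta; everything else gets weight 0 (i.e. is omitted).
    """
    v = frame.variants
    keymap = pd.Series(np.arange(len(panel_frame)),
                       index=panel_frame["key"].to_numpy())
    keep = v["key"].isin(keymap.index)
    v = v[keep].reset_index(drop=True)
    idx = keymap[v["key"]].to_numpy()
    d = np.asarray(dosages, dtype=float)[:, idx]
    d = d - d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    d = d / sd
    n = d.shape[0]
    p = v[f"{trait}_p"].to_numpy()
    order = np.argsort(p, kind="stable")
    alive = np.ones(len(v), dtype=bool)
    chosen = []
    for j in order:
        if not alive[j]:
            continue
        chosen.append(j)
        alive[j] = False
        if window is None:
            cand = np.nonzero(alive)[0]
        else:
            lo, hi = max(0, j - window), min(len(v), j + window + 1)
            cand = np.nonzero(alive[lo:hi])[0] + lo
        if cand.size:
            r = (d[:, cand].T @ d[:, j]) / (n - 1)
            alive[cand[r ** 2 > r2_thresh]] = False
    chosen = np.array(sorted(chosen))
    sel = chosen[p[chosen] <= p_thresh]
    tab = pd.DataFrame({
        "key": v.loc[sel, "key"].to_numpy(),
        "effect_allele": v.loc[sel, "effect_allele"].to_numpy(),
        "weight": v.loc[sel, f"{trait}_beta"].to_numpy(),
    })
    log.info("clumping kept %d of %d variants (r2<=%g, p<=%g)",
             len(tab), len(v), r2_thresh, p_thresh)
    return WeightVector(table=tab, provenance="clumped+thresholded")


def pgs_correlation(pgs_a: np.ndarray, pgs_b: np.ndarray,
                    ) -> tuple[float, float]:
    """Spearman rank correlation between two matched score vectors."""
    a = np.asarray(pgs_a, dtype=float)
    b = np.asarray(pgs_b, dtype=float)
    if a.shape != b.shape:
        raise StructureError("score vectors differ in length")
    if a.size < 3:
        raise DegenerateDataError("need at least 3 pairs for a correlation")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
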