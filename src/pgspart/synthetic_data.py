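"""Synthetic genotype / GWAS / cohort generator with known ground truth.

The generator emulates the data a polygenic-dissection study consumes:

* LD-blocked imputed dosage genotypes for a target cohort,
* GWAS summary statistics for an *anchor* trait (educational attainment in
  the motivating application) and a *target* disorder whose causal effects
  have controlled sign concordance with the anchor,
* an individual-level cohort with a 4-category ordinal outcome (school
  grades D<C<B<A per subject area) generated from a latent liability loaded
  on the concordant / discordant components of the true genetic score, plus
  a nonnegative mediating symptom scale, covariates, and wave / school
  structure.

LD is a Gaussian-copula block model: within each block all SNPs share one
minor-allele frequency and a constant pairwise dosage correlation; blocks
are mutually independent.  By default the per-block correlation varies
across blocks (drawn from ``rho_block_range``), giving the LD-score
heterogeneity across SNPs that identifies stratified LD-score regressions;
either way the LD scores are analytically known,
``l = 1 + (B - 1) * rho_b**2`` for block size ``B``, which the downstream
LD-score code is tested against.

Effect sizes live on the standardized-genotype scale (so the GWAS sampling
standard error is exactly ``1/sqrt(N)``); conversion to the per-allele
dosage scale used in output tables is ``beta / sqrt(2 f (1 - f))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import owens_t

__all__ = [
    "ArchitectureSpec",
    "CohortSpec",
    "TrueEffects",
    "TruthRecord",
    "Genotypes",
    "Cohort",
    "simulate_genotypes",
    "draw_true_effects",
    "simulate_sumstats",
    "simulate_ld_zscores",
    "simulate_cohort",
    "write_vcf",
    "write_sumstats_tsv",
    "write_manifest",
]

ANCHOR_P_THRESH = 0.05  # anchor-significance threshold defining the partitions

# effect/other allele pairs used for synthetic variants; palindromic pairs
# (A/T, C/G) excluded by default so harmonization keeps every variant
_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of the simulated anchor and target traits.

    Parameters
    ----------
    M : total SNP count (must be divisible by ``L``).
    L : number of independent LD blocks.
    maf_range : bounds for the per-block minor-allele frequency, in (0, 0.5].
    pi_causal_anchor, pi_causal_target : causal fractions per trait.
    h2_anchor, h2_target : SNP-heritabilities on the standardized scale.
    q_concordant : probability that a SNP causal for *both* traits gets a
        target effect whose sign agrees with its anchor effect.
    rho_block : within-block pairwise dosage correlation in [0, 1).
    N_anchor, N_target : GWAS sample sizes.  Defaults follow large published
        GWAS of educational attainment (~766k) and ADHD (~225k effective).
    """

    M: int = 2000
    L: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    pi_causal_anchor: float = 0.30
    pi_causal_target: float = 0.30
    h2_anchor: float = 0.15
    h2_target: float = 0.22
    q_concordant: float = 0.30
    rho_block: float = 0.5
    rho_block_range: tuple[float, float] | None = (0.2, 0.8)
    N_anchor: int = 766_345
    N_target: int = 225_534
    seed: int = 0
    palindromic_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.M <= 0 or self.L <= 0 or self.M % self.L != 0:
            raise ValueError(
                f"M ({self.M}) must be a positive multiple of L ({self.L})"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        for name in ("pi_causal_anchor", "pi_causal_target", "q_concordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("h2_anchor", "h2_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.rho_block < 1.0:
            raise ValueError("rho_block must lie in [0, 1)")
        if self.rho_block_range is not None:
            rlo, rhi = self.rho_block_range
            if not (0.0 <= rlo <= rhi < 1.0):
                raise ValueError("rho_block_range bounds must lie in [0, 1)")
        if min(self.N_anchor, self.N_target) < 1:
            raise ValueError("GWAS sample sizes must be positive")

    @property
    def block_size(self) -> int:
        return self.M // self.L

    def block_rhos(self) -> np.ndarray:
        """Per-block dosage correlations.  With ``rho_block_range`` set the
        blocks get heterogeneous correlations (drawn deterministically from
        the seed); LD-score heterogeneity across SNPs is what identifies
        stratified LD-score regressions, so this is the default.  With
        ``rho_block_range=None`` every block uses the flat ``rho_block``."""
        if self.rho_block_range is None:
            return np.full(self.L, self.rho_block)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 31]))
        lo, hi = self.rho_block_range
        return rng.uniform(lo, hi, size=self.L)


@dataclass(frozen=True)
class CohortSpec:
    """Target-cohort generative parameters.

    The defaults emulate a school-age cohort of 4278 children genotyped in
    three waves across 45 schools, graded D/C/B/A in three subject areas.
    Liability loadings are calibrated so each partition-level polygenic
    component explains roughly 1-3% of latent variance; the mediated path
    ``a_med * b_med`` contributes about a quarter to a third of the total
    discordant effect, and opposes the direct concordant effect (producing
    a suppression pattern for the concordant component).
    """

    n_individuals: int = 4278
    n_waves: int = 3
    n_schools: int = 45
    gamma_concordant: float = 0.18
    gamma_discordant: float = -0.12
    a_med: float = 0.25
    b_med: float = -0.20
    category_base_probs: tuple[float, float, float, float] = (0.15, 0.30, 0.35, 0.20)
    beta_age: float = 0.05
    beta_sex: float = 0.10
    beta_ses: float = 0.20
    school_sd: float = 0.15
    n_pcs: int = 20
    subjects: tuple[str, ...] = (
        "mathematics", "foreign_language", "primary_language"
    )
    mediator_shift: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_base_probs) - 1.0) > 1e-9:
            raise ValueError("category_base_probs must sum to 1")
        if any(p <= 0 for p in self.category_base_probs):
            raise ValueError("category_base_probs must be positive")
        if self.n_schools < 1 or self.n_waves < 1:
            raise ValueError("need at least one school and one wave")
        if self.school_sd < 0:
            raise ValueError("school_sd must be nonnegative")


@dataclass
class TrueEffects:
    """Per-SNP true standardized effects and the implied partition truth."""

    beta_anchor: np.ndarray
    beta_target: np.ndarray
    causal_anchor: np.ndarray  # bool masks
    causal_target: np.ndarray
    shared_causal: np.ndarray
    true_label: np.ndarray  # {"noEA", "concordant", "discordant"} per SNP
    realized_h2_anchor: float
    realized_h2_target: float
    h2_target_by_label: dict[str, float]


@dataclass
class Genotypes:
    """Dosage panel: ``dosages`` is n_individuals x M in [0, 2]; ``frame``
    carries snp_id / chrom / pos / effect_allele / other_allele / freq."""

    dosages: np.ndarray
    frame: pd.DataFrame

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        x = self.dosages
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (x - mu) / sd


@dataclass
class Cohort:
    """Individual-level cohort: dosage panel + phenotype/covariate table."""

    genotypes: Genotypes
    phenotypes: pd.DataFrame


@dataclass
class TruthRecord:
    effects: TrueEffects
    cohort_spec: CohortSpec | None = None
    s_concordant: np.ndarray | None = None
    s_discordant: np.ndarray | None = None
    mediator_latent: np.ndarray | None = None
    liability: dict[str, np.ndarray] = field(default_factory=dict)
    school_effects: np.ndarray | None = None
    fixed_part: np.ndarray | None = None  # liability minus subject noise


def _latent_rho_for_dosage_rho(f: float, rho: float) -> float:
    """Gaussian-copula latent correlation giving haplotype-indicator (and
    hence dosage) Pearson correlation ``rho`` at allele frequency ``f``."""
    if rho <= 0.0:
        return 0.0
    t = stats.norm.ppf(f)

    def binary_corr(lat: float) -> float:
        # P(Z1<t, Z2<t) via Owen's T: Phi2(t,t,lat) = Phi(t) - 2*T(t, a)
        a = np.sqrt((1.0 - lat) / (1.0 + lat))
        p11 = stats.norm.cdf(t) - 2.0 * owens_t(t, a)
        return (p11 - f * f) / (f * (1.0 - f))

    if binary_corr(0.999999) < rho:
        return 0.999999
    return brentq(lambda lat: binary_corr(lat) - rho, 0.0, 0.999999, xtol=1e-10)


def _block_mafs(spec: ArchitectureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, size=spec.L)


def variant_frame(spec: ArchitectureSpec, rng: np.random.Generator | None = None,
                  mafs_by_block: np.ndarray | None = None) -> pd.DataFrame:
    """Deterministic variant metadata for the architecture (one
    pseudo-chromosome; positions 1-based; alleles drawn from the seed)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if mafs_by_block is None:
        mafs_by_block = _block_mafs(spec, rng)
    pairs = list(_NON_PALINDROMIC_PAIRS)
    probs = np.full(len(pairs), (1.0 - spec.palindromic_frac) / len(pairs))
    if spec.palindromic_frac > 0:
        pairs = pairs + list(_PALINDROMIC_PAIRS)
        probs = np.concatenate([
            probs,
            np.full(len(_PALINDROMIC_PAIRS),
                    spec.palindromic_frac / len(_PALINDROMIC_PAIRS)),
        ])
    idx = rng.choice(len(pairs), size=spec.M, p=probs / probs.sum())
    ea = np.array([pairs[i][0] for i in idx])
    oa = np.array([pairs[i][1] for i in idx])
    return pd.DataFrame({
        "snp_id": [f"rs{j + 1}" for j in range(spec.M)],
        "chrom": "1",
        "pos": np.arange(1, spec.M + 1) * 1000,
        "effect_allele": ea,
        "other_allele": oa,
        "freq": np.repeat(mafs_by_block, spec.block_size),
        "block": np.repeat(np.arange(spec.L), spec.block_size),
    })


def simulate_genotypes(spec: ArchitectureSpec, n: int,
                       seed: int | None = None) -> Genotypes:
    """Draw an ``n`` x ``M`` dosage matrix under the block-copula LD model.

    Each haplotype allele is the threshold indicator of an equicorrelated
    Gaussian vector whose latent correlation is calibrated so the *dosage*
    correlation within a block equals ``rho_block``; dosage = sum of two
    independent haplotypes, hence marginally Binomial(2, f).
    """
    if n < 1:
        raise ValueError("need at least one individual")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    # the variant frame (alleles, block MAFs) is a deterministic function of
    # the spec alone, so panels and sumstat tables always agree on it; only
    # the dosage draws use the sampling seed
    frame = variant_frame(spec)
    mafs = frame["freq"].to_numpy()[::spec.block_size]
    rhos = spec.block_rhos()
    B = spec.block_size
    dos = np.empty((n, spec.M), dtype=np.float64)
    for b in range(spec.L):
        f = mafs[b]
        lat = _latent_rho_for_dosage_rho(f, rhos[b])
        t = stats.norm.ppf(f)
        cols = slice(b * B, (b + 1) * B)
        block = np.zeros((n, B))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, B))
            z = np.sqrt(lat) * shared + np.sqrt(1.0 - lat) * own
            block += (z < t).astype(np.float64)
        dos[:, cols] = block
    return Genotypes(dosages=dos, frame=frame)


def _blockwise_quadratic(beta: np.ndarray, rho, L: int) -> float:
    """beta' R beta for block-equicorrelated R (equal block sizes);
    ``rho`` may be a scalar or a per-block array."""
    b = beta.reshape(L, -1)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), (L,))
    return float(((1.0 - rho) * (b ** 2).sum(axis=1)
                  + rho * b.sum(axis=1) ** 2).sum())


def draw_true_effects(spec: ArchitectureSpec,
                      seed: int | None = None) -> TrueEffects:
    """Draw causal masks and standardized effect sizes for both traits.

    Anchor and target causal sets are independent Bernoulli draws; the
    shared set is their intersection.  For shared SNPs the target sign is
    set equal to the anchor sign with probability ``q_concordant``.  Effects
    are rescaled so the population heritability ``beta' R beta`` equals the
    spec value exactly under the block LD model.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    M = spec.M
    causal_a = rng.random(M) < spec.pi_causal_anchor
    causal_t = rng.random(M) < spec.pi_causal_target
    shared = causal_a & causal_t

    beta_a = np.zeros(M)
    beta_a[causal_a] = rng.standard_normal(causal_a.sum())
    qa = _blockwise_quadratic(beta_a, spec.block_rhos(), spec.L)
    if qa > 0:
        beta_a *= np.sqrt(spec.h2_anchor / qa)

    beta_t = np.zeros(M)
    beta_t[causal_t] = rng.standard_normal(causal_t.sum())
    # impose sign concordance with the anchor on the shared causal set
    concordant_draw = rng.random(M) < spec.q_concordant
    sh = shared & (beta_a != 0) & (beta_t != 0)
    want_sign = np.where(concordant_draw, np.sign(beta_a), -np.sign(beta_a))
    beta_t[sh] = np.abs(beta_t[sh]) * want_sign[sh]
    qt = _blockwise_quadratic(beta_t, spec.block_rhos(), spec.L)
    if qt > 0:
        beta_t *= np.sqrt(spec.h2_target / qt)

    # truth labels under the noise-free anchor test at the partition threshold
    z_crit = stats.norm.ppf(1.0 - ANCHOR_P_THRESH / 2.0)
    anchor_sig = np.abs(beta_a) * np.sqrt(spec.N_anchor) >= z_crit
    label = np.full(M, "noEA", dtype=object)
    signed = anchor_sig & (beta_t != 0) & (beta_a != 0)
    conc = signed & (np.sign(beta_t) == np.sign(beta_a))
    label[signed] = "discordant"
    label[conc] = "concordant"

    h2_by = {}
    for lab in ("noEA", "concordant", "discordant"):
        bt = np.where(label == lab, beta_t, 0.0)
        h2_by[lab] = _blockwise_quadratic(bt, spec.block_rhos(), spec.L)

    return TrueEffects(
        beta_anchor=beta_a,
        beta_target=beta_t,
        causal_anchor=causal_a,
        causal_target=causal_t,
        shared_causal=sh,
        true_label=label.astype(str),
        realized_h2_anchor=spec.h2_anchor if qa > 0 else 0.0,
        realized_h2_target=spec.h2_target if qt > 0 else 0.0,
        h2_target_by_label=h2_by,
    )


def draw_second_target(spec: ArchitectureSpec, effects: TrueEffects,
                       q_concordant: float, pi_causal: float | None = None,
                       h2: float | None = None,
                       seed: int | None = None) -> TrueEffects:
    """Draw a second disorder sharing the anchor architecture.

    The anchor effects and causal set are taken from ``effects``; only the
    new target's causal mask, magnitudes and sign-concordance (with
    probability ``q_concordant`` of agreeing with the anchor on shared
    causal SNPs) are drawn.  Emulates a disorder pair with opposite
    relationships to the anchor: SNPs discordant for one trait and
    concordant for the other carry opposite-signed weights, so the two
    partition scores correlate negatively.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    M = spec.M
    pi_causal = spec.pi_causal_target if pi_causal is None else pi_causal
    h2 = spec.h2_target if h2 is None else h2
    beta_a = effects.beta_anchor
    causal_a = effects.causal_anchor
    causal_t = rng.random(M) < pi_causal
    shared = causal_a & causal_t
    beta_t = np.zeros(M)
    beta_t[causal_t] = rng.standard_normal(causal_t.sum())
    concordant_draw = rng.random(M) < q_concordant
    sh = shared & (beta_a != 0) & (beta_t != 0)
    want_sign = np.where(concordant_draw, np.sign(beta_a), -np.sign(beta_a))
    beta_t[sh] = np.abs(beta_t[sh]) * want_sign[sh]
    qt = _blockwise_quadratic(beta_t, spec.block_rhos(), spec.L)
    if qt > 0:
        beta_t *= np.sqrt(h2 / qt)
    z_crit = stats.norm.ppf(1.0 - ANCHOR_P_THRESH / 2.0)
    anchor_sig = np.abs(beta_a) * np.sqrt(spec.N_anchor) >= z_crit
    label = np.full(M, "noEA", dtype=object)
    signed = anchor_sig & (beta_t != 0) & (beta_a != 0)
    conc = signed & (np.sign(beta_t) == np.sign(beta_a))
    label[signed] = "discordant"
    label[conc] = "concordant"
    h2_by = {}
    for lab in ("noEA", "concordant", "discordant"):
        bt = np.where(label == lab, beta_t, 0.0)
        h2_by[lab] = _blockwise_quadratic(bt, spec.block_rhos(), spec.L)
    return TrueEffects(
        beta_anchor=beta_a, beta_target=beta_t, causal_anchor=causal_a,
        causal_target=causal_t, shared_causal=sh,
        true_label=label.astype(str),
        realized_h2_anchor=effects.realized_h2_anchor,
        realized_h2_target=h2 if qt > 0 else 0.0,
        h2_target_by_label=h2_by,
    )


def _to_dosage_scale(beta_std: np.ndarray, freq: np.ndarray) -> np.ndarray:
    return beta_std / np.sqrt(2.0 * freq * (1.0 - freq))


def _sumstat_table(frame: pd.DataFrame, beta_std_hat: np.ndarray,
                   se_std: float, N: int) -> pd.DataFrame:
    freq = frame["freq"].to_numpy()
    keep = (freq > 0.0) & (freq < 1.0)
    if not keep.all():  # monomorphic variants carry no association signal
        frame = frame.loc[keep]
        beta_std_hat = beta_std_hat[keep]
        freq = freq[keep]
    z = beta_std_hat / se_std
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    scale = np.sqrt(2.0 * freq * (1.0 - freq))
    return pd.DataFrame({
        "SNP": frame["snp_id"].to_numpy(),
        "CHR": frame["chrom"].to_numpy(),
        "BP": frame["pos"].to_numpy(),
        "A1": frame["effect_allele"].to_numpy(),
        "A2": frame["other_allele"].to_numpy(),
        "BETA": beta_std_hat / scale,
        "SE": se_std / scale,
        "P": p,
        "Z": z,
        "FRQ": freq,
        "N": N,
    })


def simulate_sumstats(spec: ArchitectureSpec, effects: TrueEffects,
                      seed: int | None = None, noise: bool = True,
                      N_target: int | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate anchor and target GWAS tables.

    Estimated standardized effects are ``beta_hat ~ N(beta_true, 1/N)``;
    two-sided normal p-values; tables are emitted on the per-allele dosage
    scale with columns SNP CHR BP A1 A2 BETA SE P FRQ N (plus Z).  With
    ``noise=False`` the estimates equal the true effects and p-values come
    from the noise-free z-statistic ``beta_true * sqrt(N)``.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    frame = variant_frame(spec)
    tables = []
    n_t = spec.N_target if N_target is None else N_target
    for beta, N in ((effects.beta_anchor, spec.N_anchor),
                    (effects.beta_target, n_t)):
        se = 1.0 / np.sqrt(N)
        bhat = beta + (rng.normal(0.0, se, size=spec.M) if noise else 0.0)
        tables.append(_sumstat_table(frame, bhat, se, N))
    return tables[0], tables[1]


def simulate_ld_zscores(spec: ArchitectureSpec, beta: np.ndarray, N: int,
                        seed: int = 0, rng: np.random.Generator | None = None,
                        ) -> np.ndarray:
    """GWAS z-scores with LD convolution: ``z = sqrt(N) R beta + e`` with
    ``e ~ MVN(0, R)`` under the block-equicorrelated LD matrix R.

    This is the marginal-association sampling model that stratified
    LD-score regression assumes; the plain :func:`simulate_sumstats` noise
    model (independent errors around joint effects) is kept for the
    partition / scoring pipeline where LD convolution is irrelevant.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    L, B = spec.L, spec.block_size
    rho = spec.block_rhos()[:, None]
    b = beta.reshape(L, B)
    mean = (1.0 - rho) * b + rho * b.sum(axis=1, keepdims=True)
    shared = rng.standard_normal((L, 1))
    own = rng.standard_normal((L, B))
    noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    return (np.sqrt(N) * mean + noise).ravel()


def simulate_cohort(cspec: CohortSpec, genotypes: Genotypes,
                    effects: TrueEffects, seed: int | None = None,
                    ) -> tuple[Cohort, TruthRecord]:
    """Generate the phenotype/covariate table on top of a dosage panel.

    Latent liability per subject area::

        lia = gamma_c * S_conc + gamma_d * S_disc + b_med * mediator_latent
              + beta_age * age_z + beta_sex * sex + beta_ses * ses_z
              + school_intercept + eps

    where ``S_conc`` / ``S_disc`` are z-scored true-effect scores over the
    concordant / discordant causal SNPs, and the mediator latent is
    ``a_med * z(S_conc + S_disc) + noise`` (unit variance).  Grades are the
    4-way threshold of the z-scored liability at the normal quantiles of
    the cumulative ``category_base_probs``; the observed symptom scale is
    the mediator latent shifted by ``mediator_shift`` and truncated at 0.
    """
    if genotypes.m != effects.beta_target.shape[0]:
        raise ValueError(
            f"genotype panel has {genotypes.m} SNPs but effects have "
            f"{effects.beta_target.shape[0]}"
        )
    seed = cspec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n = genotypes.n
    if n != cspec.n_individuals:
        raise ValueError(
            f"panel has {n} individuals, cohort spec asks for "
            f"{cspec.n_individuals}"
        )
    x = genotypes.standardized()

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    conc = effects.true_label == "concordant"
    disc = effects.true_label == "discordant"
    s_conc_raw = x[:, conc] @ effects.beta_target[conc] if conc.any() else np.zeros(n)
    s_disc_raw = x[:, disc] @ effects.beta_target[disc] if disc.any() else np.zeros(n)
    s_conc = zscore(s_conc_raw)
    s_disc = zscore(s_disc_raw)
    s_sum = zscore(s_conc_raw + s_disc_raw)

    age = rng.normal(10.03, 2.95, size=n)
    sex = (rng.random(n) < 0.437).astype(int)  # 1 = female
    ses = rng.standard_normal(n)
    pcs = rng.standard_normal((n, cspec.n_pcs))
    wave = rng.integers(1, cspec.n_waves + 1, size=n)
    school = rng.integers(0, cspec.n_schools, size=n)
    school_eff = rng.normal(0.0, cspec.school_sd, size=cspec.n_schools)

    med_noise_sd = np.sqrt(max(0.0, 1.0 - cspec.a_med ** 2))
    med_latent = cspec.a_med * s_sum + rng.normal(0.0, med_noise_sd, size=n)
    symptoms = np.clip(med_latent + cspec.mediator_shift, 0.0, None)

    base = (
        cspec.gamma_concordant * s_conc
        + cspec.gamma_discordant * s_disc
        + cspec.b_med * med_latent
        + cspec.beta_age * zscore(age)
        + cspec.beta_sex * (sex - sex.mean())
        + cspec.beta_ses * zscore(ses)
        + school_eff[school]
    )
    cuts = stats.norm.ppf(np.cumsum(cspec.category_base_probs)[:-1])
    pheno = pd.DataFrame({
        "iid": [f"ind{i + 1}" for i in range(n)],
        "wave": wave,
        "school": school,
        "age": age,
        "sex": sex,
        "ses": ses,
        "symptoms": symptoms,
    })
    for j in range(cspec.n_pcs):
        pheno[f"pc{j + 1}"] = pcs[:, j]
    liability = {}
    for s_i, subj in enumerate(cspec.subjects):
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, 19, s_i]))
        lia = base + sub_rng.standard_normal(n)
        liability[subj] = lia
        lia_z = zscore(lia)
        pheno[f"grade_{subj}"] = np.searchsorted(cuts, lia_z, side="left")
    truth = TruthRecord(
        effects=effects,
        cohort_spec=cspec,
        s_concordant=s_conc,
        s_discordant=s_disc,
        mediator_latent=med_latent,
        liability=liability,
        school_effects=school_eff,
        fixed_part=base,
    )
    return Cohort(genotypes=genotypes, phenotypes=pheno), truth


# ---------------------------------------------------------------------------
# writers

GRADE_LETTERS = {0: "D", 1: "C", 2: "B", 3: "A"}  # letter mapping at I/O only


def write_vcf(genotypes: Genotypes, path: str | Path,
              precision: int = 3) -> Path:
    """Write the panel as an uncompressed VCF with per-sample DS dosages.

    REF is the other allele, ALT the effect allele, so DS counts the effect
    allele.  One pseudo-chromosome, 1-based positions.
    """
    path = Path(path)
    frame = genotypes.frame
    samples = [f"ind{i + 1}" for i in range(genotypes.n)]
    max_pos = int(frame["pos"].max())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={max_pos + 1000}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = genotypes.dosages
        for j, row in enumerate(frame.itertuples(index=False)):
            ds = "\t".join(f"{d:.{precision}f}" for d in dos[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t"
                     f"{row.other_allele}\t{row.effect_allele}\t.\t.\t.\tDS\t"
                     f"{ds}\n")
    return path


def write_sumstats_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "FRQ", "N"]
    table[cols].to_csv(path, sep="\t", index=False)
    return path


def write_phenotypes_tsv(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    out = cohort.phenotypes.copy()
    for col in [c for c in out.columns if c.startswith("grade_")]:
        out[col] = out[col].map(GRADE_LETTERS)
    out.to_csv(path, sep="\t", index=False)
    return path


def write_truth_tsv(truth: TruthRecord, path: str | Path) -> Path:
    path = Path(path)
    eff = truth.effects
    pd.DataFrame({
        "snp_index": np.arange(eff.beta_anchor.shape[0]),
        "beta_anchor": eff.beta_anchor,
        "beta_target": eff.beta_target,
        "causal_anchor": eff.causal_anchor.astype(int),
        "causal_target": eff.causal_target.astype(int),
        "shared_causal": eff.shared_causal.astype(int),
        "true_label": eff.true_label,
    }).to_csv(path, sep="\t", index=False)
    return path


def write_manifest(path: str | Path, **specs) -> Path:
    """Echo all specs / seeds of a run into a JSON manifest."""
    path = Path(path)
    payload = {}
    for name, obj in specs.items():
        if hasattr(obj, "__dataclass_fields__"):
            payload[name] = asdict(obj)
        else:
            payload[name] = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
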