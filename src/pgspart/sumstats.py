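"""Reading, validation, filtering and harmonization of GWAS summary
statistics and dosage genotypes.

All cross-table comparisons of effect signs (the basis of the concordant /
discordant partitioning) require every table to express its effect relative
to the same allele of each variant; :func:`harmonize` produces that common
frame, resolving swapped-allele and strand-flipped records and dropping
palindromic (A/T, C/G) and irreconcilable variants.

Coordinates are 1-based inclusive throughout, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import ConfigError, InputDataError, StructureError

log = logging.getLogger(__name__)

__all__ = [
    "SumStatTable",
    "HarmonizedFrame",
    "read_sumstats",
    "sumstat_table_from_df",
    "filter_variants",
    "filter_panel",
    "hwe_exact_test",
    "harmonize",
    "read_dosage_vcf",
]

#: canonical name -> default column name in GWAS text files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "freq": "FRQ",
    "n": "N",
}
MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "p")
OPTIONAL = ("freq", "n", "info")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    return a1 in _VALID_ALLELES and _COMPLEMENT[a1] == a2


def canonical_key(chrom, pos, a1, a2) -> str:
    """Strand- and order-invariant variant key ``chrom:pos:alleleA:alleleB``.

    The allele pair is the lexicographically smaller of the sorted pair and
    the sorted complemented pair, so records reported on opposite strands or
    with swapped effect/other alleles share a key.
    """
    fwd = sorted((a1, a2))
    try:
        rev = sorted((_COMPLEMENT[a1], _COMPLEMENT[a2]))
    except KeyError:
        rev = fwd
    pair = min(fwd, rev)
    return f"{chrom}:{pos}:{pair[0]}:{pair[1]}"


@dataclass
class SumStatTable:
    """Validated GWAS summary statistics: one association per SNV.

    ``data`` holds canonical columns (snp_id, chrom, pos, effect_allele,
    other_allele, beta, se, p[, freq, n, info]); ``dropped`` records every
    discarded input row with its reason.
    """

    data: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"]))
    name: str = "trait"

    def __len__(self) -> int:
        return len(self.data)

    def drop_counts(self) -> pd.Series:
        return self.dropped["reason"].value_counts()

    def keys(self) -> pd.Series:
        d = self.data
        return pd.Series(
            [canonical_key(c, p, a, b) for c, p, a, b in zip(
                d["chrom"].astype(str), d["pos"], d["effect_allele"],
                d["other_allele"])],
            index=d.index,
        )


def _validate(df: pd.DataFrame, name: str) -> SumStatTable:
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    a1 = df["effect_allele"].astype(str).str.upper()
    a2 = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=a1, other_allele=a2)
    flag(~(a1.isin(_VALID_ALLELES) & a2.isin(_VALID_ALLELES)), "non-SNV")
    flag(a1 == a2, "identical alleles")
    for col in ("beta", "se", "p"):
        flag(~np.isfinite(pd.to_numeric(df[col], errors="coerce")),
             f"missing or non-numeric {col}")
    se = pd.to_numeric(df["se"], errors="coerce")
    flag(se <= 0, "nonpositive SE")
    p = pd.to_numeric(df["p"], errors="coerce")
    flag((p <= 0) | (p > 1), "p out of range")
    if "freq" in df.columns:
        f = pd.to_numeric(df["freq"], errors="coerce")
        flag(f.notna() & ((f <= 0) | (f >= 1)), "frequency out of range")
    bad = reasons != ""
    dropped = pd.DataFrame({
        "snp_id": df.loc[bad, "snp_id"].astype(str),
        "reason": reasons[bad],
    }).reset_index(drop=True)
    good = df.loc[~bad].copy()
    for col in ("beta", "se", "p", "freq", "n", "info"):
        if col in good.columns:
            good[col] = pd.to_numeric(good[col], errors="coerce")
    good["pos"] = good["pos"].astype(int)
    good["chrom"] = good["chrom"].astype(str)
    if len(good) == 0:
        raise InputDataError(f"no valid rows in summary statistics '{name}'")
    if len(dropped):
        log.info("%s: dropped %d malformed rows (%s)", name, len(dropped),
                 dict(dropped["reason"].value_counts()))
    return SumStatTable(data=good.reset_index(drop=True), dropped=dropped,
                        name=name)


def read_sumstats(path: str | Path, column_map: dict[str, str] | None = None,
                  name: str | None = None) -> SumStatTable:
    """Read a whitespace/TSV GWAS table into a validated :class:`SumStatTable`.

    ``column_map`` maps canonical names to file column names (defaults in
    :data:`DEFAULT_COLUMN_MAP`).  An ``OR`` column is accepted in place of
    ``BETA`` and converted to ``log(OR)``.  Malformed rows are dropped and
    logged, never fatal; an entirely invalid file is.
    """
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"summary statistics file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype={cmap.get("chrom", "CHR"): str})
    rename = {}
    for canon, source in cmap.items():
        if source in raw.columns:
            rename[source] = canon
    df = raw.rename(columns=rename)
    if "beta" not in df.columns and "OR" in raw.columns:
        df["beta"] = np.log(pd.to_numeric(raw["OR"], errors="coerce"))
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: mandatory columns missing after mapping: {missing}")
    keep = [c for c in (*MANDATORY, *OPTIONAL) if c in df.columns]
    return _validate(df[keep], name or path.stem)


def sumstat_table_from_df(df: pd.DataFrame, name: str = "trait") -> SumStatTable:
    """Build a validated table from an in-memory frame with either canonical
    or default GWAS column names (as produced by the simulator)."""
    rename = {v: k for k, v in DEFAULT_COLUMN_MAP.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ConfigError(f"columns missing: {missing}")
    keep = [c for c in (*MANDATORY, *OPTIONAL) if c in df.columns]
    return _validate(df[keep].copy(), name)


# ---------------------------------------------------------------------------
# filtering

def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, by enumeration).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, whose probability does not exceed that of the
    observed configuration (Wigginton-style exact test).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1) - gammaln(hets + 1) - gammaln(hom_r + 1)
        - gammaln(hom_c + 1) + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def filter_variants(table: SumStatTable, maf_min: float = 0.01,
                    info_min: float = 0.8) -> SumStatTable:
    """Apply post-imputation variant filters to a summary-statistic table.

    Filters on MAF (``min(f, 1-f) >= maf_min``) and imputation INFO score;
    a filter whose column is absent is skipped with a warning.  Counts per
    filter are logged and appended to the drop log.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ConfigError("maf_min must lie in [0, 0.5)")
    df = table.data
    keep = pd.Series(True, index=df.index)
    reasons = pd.Series("", index=df.index, dtype=object)
    if "freq" in df.columns and df["freq"].notna().any():
        maf = np.minimum(df["freq"], 1.0 - df["freq"])
        fail = maf < maf_min
        reasons[fail & keep] = f"MAF < {maf_min}"
        keep &= ~fail
    else:
        log.warning("%s: no frequency column; MAF filter skipped", table.name)
    if "info" in df.columns and df["info"].notna().any():
        fail = df["info"] <= info_min
        reasons[fail & keep] = f"INFO <= {info_min}"
        keep &= ~fail
    else:
        log.warning("%s: no INFO column; INFO filter skipped", table.name)
    newly = pd.DataFrame({
        "snp_id": df.loc[~keep, "snp_id"], "reason": reasons[~keep],
    })
    log.info("%s: variant filters removed %d of %d (%s)", table.name,
             (~keep).sum(), len(df),
             dict(newly["reason"].value_counts()) if len(newly) else {})
    return SumStatTable(
        data=df.loc[keep].reset_index(drop=True),
        dropped=pd.concat([table.dropped, newly], ignore_index=True),
        name=table.name,
    )


def filter_panel(dosages: np.ndarray, frame: pd.DataFrame,
                 maf_min: float = 0.01, hwe_p_min: float = 1e-10,
                 ) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Filter a dosage panel on realized MAF and exact-test HWE.

    Dosages are hard-called by rounding for the HWE test.  Returns the
    filtered matrix, the filtered variant frame, and a drop log.
    """
    f = dosages.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= maf_min
    reasons = np.where(keep, "", f"MAF < {maf_min}").astype(object)
    hard = np.rint(dosages).astype(int)
    for j in np.nonzero(keep)[0]:
        counts = np.bincount(np.clip(hard[:, j], 0, 2), minlength=3)
        p = hwe_exact_test(int(counts[1]), int(counts[0]), int(counts[2]))
        if p <= hwe_p_min:
            keep[j] = False
            reasons[j] = f"HWE p <= {hwe_p_min}"
    dropped = pd.DataFrame({
        "snp_id": frame.loc[~keep, "snp_id"], "reason": reasons[~keep],
    })
    return dosages[:, keep], frame.loc[keep].reset_index(drop=True), dropped


# ---------------------------------------------------------------------------
# harmonization

@dataclass
class HarmonizedFrame:
    """Common variant frame with per-table effects on one agreed allele.

    ``variants`` has key / chrom / pos / effect_allele / other_allele / freq
    (panel frequency when a panel was supplied, else the reference table's);
    ``variants`` additionally carries ``<name>_beta``, ``<name>_se``,
    ``<name>_p``, ``<name>_freq``, ``<name>_n`` per input table.
    ``provenance`` maps each kept variant and table to a flag in
    {kept, allele-flipped, strand-flipped, strand+allele-flipped};
    ``dropped`` records discarded variants with reasons.
    """

    variants: pd.DataFrame
    table_names: list[str]
    provenance: pd.DataFrame
    dropped: pd.DataFrame

    def __len__(self) -> int:
        return len(self.variants)

    def table(self, name: str) -> pd.DataFrame:
        """Per-table view with canonical sumstat columns."""
        v = self.variants
        cols = {
            "key": v["key"], "snp_id": v["snp_id"], "chrom": v["chrom"],
            "pos": v["pos"], "effect_allele": v["effect_allele"],
            "other_allele": v["other_allele"],
            "beta": v[f"{name}_beta"], "se": v[f"{name}_se"],
            "p": v[f"{name}_p"],
        }
        for extra in ("freq", "n"):
            col = f"{name}_{extra}"
            if col in v.columns:
                cols[extra] = v[col]
        return pd.DataFrame(cols)

    def as_tables(self) -> dict[str, SumStatTable]:
        return {
            name: SumStatTable(data=self.table(name).drop(columns="key"),
                               name=name)
            for name in self.table_names
        }


def _orient(df: pd.DataFrame, ref: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Align one table's rows (indexed like ``ref``) to the reference
    effect/other alleles; returns oriented frame and per-row flags
    ('' = irreconcilable)."""
    a1 = df["effect_allele"].to_numpy(dtype=object)
    a2 = df["other_allele"].to_numpy(dtype=object)
    r1 = ref["effect_allele"].to_numpy(dtype=object)
    r2 = ref["other_allele"].to_numpy(dtype=object)
    c1 = np.array([_COMPLEMENT.get(a, "N") for a in a1], dtype=object)
    c2 = np.array([_COMPLEMENT.get(a, "N") for a in a2], dtype=object)
    same = (a1 == r1) & (a2 == r2)
    swap = (a1 == r2) & (a2 == r1)
    strand = (c1 == r1) & (c2 == r2) & ~same & ~swap
    strand_swap = (c1 == r2) & (c2 == r1) & ~same & ~swap & ~strand
    flags = np.full(len(df), "", dtype=object)
    flags[same] = "kept"
    flags[strand] = "strand-flipped"
    flags[swap] = "allele-flipped"
    flags[strand_swap] = "strand+allele-flipped"
    out = df.copy()
    flip = swap | strand_swap
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    if "freq" in out.columns:
        out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
    out["effect_allele"] = r1
    out["other_allele"] = r2
    return out, pd.Series(flags, index=df.index)


def harmonize(tables: dict[str, SumStatTable] | list[SumStatTable],
              panel: pd.DataFrame | None = None,
              allow_palindromic: bool = False) -> HarmonizedFrame:
    """Intersect >= 2 GWAS tables (and optionally a genotype panel frame)
    onto one variant frame with a single effect allele per variant.

    The panel (or, without one, the first table) defines the reference
    allele orientation and, when present, the authoritative frequency.
    Swapped-allele records get ``beta := -beta``, ``freq := 1 - freq``;
    opposite-strand records are complemented; palindromic variants are
    dropped unless ``allow_palindromic``; inconsistent allele pairs are
    dropped with reason ``allele mismatch``.  Idempotent on its own output.
    """
    if isinstance(tables, list):
        tables = {t.name: t for t in tables}
    if len(tables) < 2 and panel is None:
        raise StructureError("harmonize needs >= 2 tables (or a panel)")
    names = list(tables)

    indexed: dict[str, pd.DataFrame] = {}
    dup_drops = []
    for name, t in tables.items():
        d = t.data.copy()
        d["key"] = t.keys().to_numpy()
        ndup = d["key"].duplicated(keep="first").sum()
        if ndup:
            dup_drops.append(pd.DataFrame({
                "key": d.loc[d["key"].duplicated(keep="first"), "key"],
                "reason": "duplicate key", "table": name}))
            d = d.drop_duplicates("key", keep="first")
        indexed[name] = d.set_index("key")

    if panel is not None:
        ref = panel.copy()
        ref["key"] = [canonical_key(c, p, a, b) for c, p, a, b in zip(
            ref["chrom"].astype(str), ref["pos"], ref["effect_allele"],
            ref["other_allele"])]
        ref = ref.drop_duplicates("key").set_index("key")
    else:
        ref = indexed[names[0]]

    common = ref.index
    for name in names:
        common = common.intersection(indexed[name].index)
    common = pd.Index(sorted(common, key=lambda k: (
        ref.loc[k, "chrom"], int(ref.loc[k, "pos"]))))

    # positions present in every table whose allele pairs are mutually
    # irreconcilable never share a canonical key; log them explicitly
    def _positions(df: pd.DataFrame) -> set[str]:
        return set(df["chrom"].astype(str) + ":" + df["pos"].astype(str))

    common_pos = _positions(ref)
    for name in names:
        common_pos &= _positions(indexed[name])
    matched_pos = set(ref.loc[common, "chrom"].astype(str) + ":"
                      + ref.loc[common, "pos"].astype(str))
    mismatched = sorted(common_pos - matched_pos)
    if mismatched:
        dup_drops.append(pd.DataFrame({
            "key": mismatched, "reason": "allele mismatch", "table": "*"}))

    dropped_frames = list(dup_drops)
    refc = ref.loc[common]
    palin = np.array([is_palindromic(a, b) for a, b in zip(
        refc["effect_allele"], refc["other_allele"])])
    if not allow_palindromic and palin.any():
        dropped_frames.append(pd.DataFrame({
            "key": common[palin], "reason": "palindromic alleles",
            "table": "*"}))
        common = common[~palin]
        refc = ref.loc[common]

    out = pd.DataFrame({
        "key": common,
        "snp_id": refc["snp_id"].to_numpy(),
        "chrom": refc["chrom"].to_numpy(),
        "pos": refc["pos"].to_numpy(dtype=int),
        "effect_allele": refc["effect_allele"].to_numpy(),
        "other_allele": refc["other_allele"].to_numpy(),
    }).set_index("key", drop=False)
    if "freq" in refc.columns:
        out["freq"] = refc["freq"].to_numpy()

    prov = pd.DataFrame(index=common)
    bad = pd.Series(False, index=common)
    for name in names:
        sub = indexed[name].loc[common]
        oriented, flags = _orient(sub, refc)
        mism = flags == ""
        if mism.any():
            dropped_frames.append(pd.DataFrame({
                "key": common[mism.to_numpy()], "reason": "allele mismatch",
                "table": name}))
            bad |= mism
        prov[name] = flags
        out[f"{name}_beta"] = oriented["beta"].to_numpy()
        out[f"{name}_se"] = oriented["se"].to_numpy()
        out[f"{name}_p"] = oriented["p"].to_numpy()
        if "freq" in oriented.columns:
            out[f"{name}_freq"] = oriented["freq"].to_numpy()
        if "n" in oriented.columns:
            out[f"{name}_n"] = oriented["n"].to_numpy()
    if "freq" not in out.columns:
        first = names[0]
        if f"{first}_freq" in out.columns:
            out["freq"] = out[f"{first}_freq"]

    keep = ~bad
    dropped = (pd.concat(dropped_frames, ignore_index=True)
               if dropped_frames else
               pd.DataFrame(columns=["key", "reason", "table"]))
    frame = HarmonizedFrame(
        variants=out.loc[keep].reset_index(drop=True),
        table_names=names,
        provenance=prov.loc[keep.to_numpy()].reset_index(names="key"),
        dropped=dropped,
    )
    log.info("harmonized %d tables -> %d variants (%d dropped)",
             len(names), len(frame), len(dropped))
    return frame


# ---------------------------------------------------------------------------
# genotype I/O

def read_dosage_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read dosages from a VCF.  Uses the DS FORMAT field when present,
    otherwise falls back to hard genotypes from GT.  ALT is taken as the
    effect (counted) allele.  Returns (n x M dosage matrix, variant frame).
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ds = var.format("DS")
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.gt_types, dtype=float)
            vals = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        rows.append(vals)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.ALT[0], var.REF))
    if not rows:
        raise InputDataError(f"no biallelic variants in {path}")
    dos = np.vstack(rows).T
    frame = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos",
                                        "effect_allele", "other_allele"])
    frame["freq"] = np.nanmean(dos, axis=0) / 2.0
    frame.attrs["samples"] = samples
    return dos, frame
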