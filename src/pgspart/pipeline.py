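"""End-to-end orchestration: simulate (optional) -> harmonize -> partition
-> score -> per-wave association -> meta-analysis -> FDR -> mediation ->
stratified h² / covariance, with a run manifest and TSV outputs.

`run_pipeline` is deterministic given (config, seed): every stage derives
its stream from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, inference, ldscore, mediation, pgs, synthetic_data
from .exceptions import ConfigError
from .partition import build_partitions, shared_subset
from .sumstats import harmonize, sumstat_table_from_df, read_sumstats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

PGS_SETS = ("all", "noEA", "EA", "concordant", "discordant")


@dataclass
class RunConfig:
    """Serializable configuration of a full run."""

    outdir: str | None = None
    seed: int = 0
    arch: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    p_thresh: float = 0.05
    school_mode: str = "auto"
    n_pcs_used: int = 20
    pgs_sets: tuple[str, ...] = PGS_SETS
    anchor_sumstats: str | None = None  # file inputs override simulation
    target_sumstats: str | None = None
    second_target: dict | None = None  # e.g. {"q_concordant": 0.6, "h2": 0.2}
    run_mediation: bool = True
    run_ldscore: bool = True
    fdr_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0.0 < self.p_thresh < 1.0):
            raise ConfigError("p_thresh must lie in (0, 1)")
        if (self.anchor_sumstats is None) != (self.target_sumstats is None):
            raise ConfigError(
                "provide both anchor and target sumstats, or neither")
        for p in (self.anchor_sumstats, self.target_sumstats):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input not found: {p}")


def demo_config(seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale demonstration configuration: the defaults of the
    synthetic generator with a reduced SNP panel."""
    cfg = RunConfig(
        seed=seed,
        arch={"M": 1500, "L": 75, "q_concordant": 0.3},
        cohort={},
        second_target={"q_concordant": 0.6, "h2": 0.2},
        **overrides,
    )
    return cfg


def _covariate_frame(pheno: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    cols = ["age", "sex", "ses"] + [f"pc{i + 1}" for i in range(n_pcs)
                                    if f"pc{i + 1}" in pheno.columns]
    return pheno[cols]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the result bundle and (if ``outdir``)
    writes TSV outputs plus a manifest.  Aborts naming the failing stage.
    """
    config.validate()
    t0 = time.time()
    bundle: dict = {"config": asdict(config)}
    stage = "setup"
    try:
        stage = "simulate"
        arch = synthetic_data.ArchitectureSpec(
            **{"seed": config.seed, **config.arch})
        cspec = synthetic_data.CohortSpec(
            **{"seed": config.seed, **config.cohort})
        effects = synthetic_data.draw_true_effects(arch)
        genotypes = synthetic_data.simulate_genotypes(
            arch, n=cspec.n_individuals, seed=config.seed + 1)
        cohort, truth = synthetic_data.simulate_cohort(
            cspec, genotypes, effects, seed=config.seed + 2)
        tables = {}
        if config.anchor_sumstats:
            tables["anchor"] = read_sumstats(config.anchor_sumstats,
                                             name="anchor")
            tables["target"] = read_sumstats(config.target_sumstats,
                                             name="target")
        else:
            anchor_df, target_df = synthetic_data.simulate_sumstats(
                arch, effects, seed=config.seed + 3)
            tables["anchor"] = sumstat_table_from_df(anchor_df, name="anchor")
            tables["target"] = sumstat_table_from_df(target_df, name="target")
        effects2 = None
        if config.second_target is not None and not config.anchor_sumstats:
            st = dict(config.second_target)
            n2 = int(st.pop("N", 46_351))
            effects2 = synthetic_data.draw_second_target(
                arch, effects, seed=config.seed, **st)
            _, target2_df = synthetic_data.simulate_sumstats(
                arch, effects2, seed=config.seed + 4, N_target=n2)
            tables["target2"] = sumstat_table_from_df(target2_df,
                                                      name="target2")
        bundle["truth"] = truth
        bundle["genotypes"] = genotypes

        stage = "harmonize"
        frame = harmonize(tables, panel=genotypes.frame)
        bundle["frame"] = frame

        stage = "partition"
        assignment = build_partitions(frame, target="target",
                                      anchor="anchor",
                                      p_thresh=config.p_thresh)
        bundle["assignment"] = assignment
        bundle["partition_summary"] = assignment.summary()

        stage = "score"
        pheno = cohort.phenotypes
        panel_frame = genotypes.frame.copy()
        from .sumstats import canonical_key
        panel_frame["key"] = [
            canonical_key(c, p, a, b) for c, p, a, b in zip(
                panel_frame["chrom"].astype(str), panel_frame["pos"],
                panel_frame["effect_allele"], panel_frame["other_allele"])]
        waves = pheno["wave"].to_numpy()
        scores = pd.DataFrame({"iid": pheno["iid"], "wave": waves})
        for set_name in config.pgs_sets:
            vs = assignment.variant_set(set_name)
            w = pgs.weights_from_frame(frame, "target", vs)
            raw = pgs.score(genotypes.dosages, panel_frame, w)
            scores[f"pgs_{set_name}"] = pgs.standardize(raw, waves)
        bundle["scores"] = scores

        stage = "assoc"
        covs_all = _covariate_frame(pheno, config.n_pcs_used)
        subjects = list(cspec.subjects)
        rows = []
        per_meta: dict[tuple[str, str], inference.MetaResult] = {}
        for subj in subjects:
            grades = pheno[f"grade_{subj}"].to_numpy()
            reduced_by_wave = {}
            for wv in np.unique(waves):
                mask = waves == wv
                reduced_by_wave[wv] = assoc.fit_ordinal(
                    grades[mask], pgs=None,
                    covariates=covs_all[mask].reset_index(drop=True),
                    school=pheno.loc[mask, "school"].to_numpy(),
                    school_mode=config.school_mode, wave=int(wv))
            for set_name in config.pgs_sets:
                fits = []
                for wv in np.unique(waves):
                    mask = waves == wv
                    fit = assoc.fit_ordinal(
                        grades[mask],
                        scores.loc[mask, f"pgs_{set_name}"].to_numpy(),
                        covariates=covs_all[mask].reset_index(drop=True),
                        school=pheno.loc[mask, "school"].to_numpy(),
                        school_mode=config.school_mode,
                        wave=int(wv))
                    fit.delta_r2 = assoc.delta_nagelkerke(
                        fit, reduced_by_wave[wv])
                    fits.append(fit)
                meta = inference.meta_fixed(fits)
                per_meta[(subj, set_name)] = meta
                row = meta.to_row()
                row.update({"outcome": subj, "pgs_set": set_name})
                rows.append(row)
        table = pd.DataFrame(rows)

        stage = "fdr"
        adj = inference.adjust_p(table["p"].to_numpy(), method="BH")
        table["p_adjusted"] = adj["p_adjusted"].to_numpy()
        cols = ["outcome", "pgs_set", "OR", "ci_low", "ci_high", "z", "p",
                "p_adjusted", "delta_R2", "n", "Q", "k", "beta", "se"]
        bundle["association_table"] = table[cols]
        bundle["meta_results"] = per_meta

        stage = "pgs-correlation"
        if {"concordant", "discordant"} <= set(config.pgs_sets):
            rho, rho_p = pgs.pgs_correlation(
                scores["pgs_discordant"].to_numpy(),
                scores["pgs_concordant"].to_numpy())
            bundle["spearman_disc_conc"] = {"rho": rho, "p": rho_p}

        stage = "cross-trait"
        if effects2 is not None:
            assignment2 = build_partitions(frame, target="target2",
                                           anchor="anchor",
                                           p_thresh=config.p_thresh)
            shared_dc = shared_subset(assignment, "discordant",
                                      assignment2, "concordant")
            w2 = pgs.weights_from_frame(
                frame, "target2", assignment2.variant_set("concordant"))
            raw2 = pgs.score(genotypes.dosages, panel_frame, w2)
            pgs2_conc = pgs.standardize(raw2, waves)
            scores["pgs2_concordant"] = pgs2_conc
            rho_x, rho_x_p = pgs.pgs_correlation(
                scores["pgs_discordant"].to_numpy(), pgs2_conc)
            bundle["assignment2"] = assignment2
            bundle["shared_subset"] = shared_dc
            bundle["spearman_cross_trait"] = {"rho": rho_x, "p": rho_x_p}

        stage = "mediation"
        if config.run_mediation:
            med_rows = {}
            data = pd.concat(
                [pheno.reset_index(drop=True),
                 scores.drop(columns=["iid", "wave"]).reset_index(drop=True)],
                axis=1)
            for subj in subjects:
                for set_name in ("concordant", "discordant"):
                    if set_name not in config.pgs_sets:
                        continue
                    res = mediation.mediate(
                        data, pgs_col=f"pgs_{set_name}",
                        mediator_col="symptoms",
                        outcome_col=f"grade_{subj}",
                        covariate_cols=list(covs_all.columns),
                        wave_col="wave", school_col="school",
                        school_mode=config.school_mode)
                    med_rows[(subj, set_name)] = res
            bundle["mediation"] = med_rows

        stage = "ldscore"
        if config.run_ldscore:
            key_order = pd.Series(
                np.arange(len(panel_frame)), index=panel_frame["key"])
            kept = key_order[frame.variants["key"]].to_numpy()
            labels = assignment.labels
            ann = pd.DataFrame({
                lab: (labels == lab).astype(float)
                for lab in ("noEA", "concordant", "discordant")})
            ld = ldscore.compute_ld_scores(
                genotypes.dosages[:, kept], annotations=ann,
                window=arch.block_size)
            v = frame.variants
            z_t = (v["target_beta"] / v["target_se"]).to_numpy()
            z_a = (v["anchor_beta"] / v["anchor_se"]).to_numpy()
            h2 = ldscore.stratified_h2(
                z_t, v["target_n"].to_numpy(), ld)
            cov = ldscore.stratified_covariance(
                z_a, z_t, v["anchor_n"].to_numpy(),
                v["target_n"].to_numpy(), ld)
            gws = None
            if (v["target_p"] < 5e-8).any():
                gws = ldscore.gws_enrichment(
                    v["target_p"].to_numpy(), labels)
            bundle["stratified_h2"] = h2
            bundle["stratified_covariance"] = cov
            bundle["gws_enrichment"] = gws

        stage = "write"
        if config.outdir:
            out = Path(config.outdir)
            out.mkdir(parents=True, exist_ok=True)
            bundle["association_table"].to_csv(
                out / "association_meta.tsv", sep="\t", index=False)
            scores.to_csv(out / "pgs_scores.tsv", sep="\t", index=False)
            assignment.to_frame().to_csv(
                out / "partitions.tsv", sep="\t", index=False)
            synthetic_data.write_phenotypes_tsv(
                cohort, out / "phenotypes.tsv")
            if config.run_ldscore:
                bundle["stratified_h2"].coefficients.to_csv(
                    out / "stratified_h2.tsv", sep="\t", index=False)
                bundle["stratified_covariance"].coefficients.to_csv(
                    out / "stratified_covariance.tsv", sep="\t", index=False)
            if config.run_mediation:
                pd.DataFrame([
                    {"outcome": s, "pgs_set": g, **r.to_row()}
                    for (s, g), r in bundle["mediation"].items()
                ]).to_csv(out / "mediation.tsv", sep="\t", index=False)
            manifest = {
                "config": asdict(config),
                "partition_summary": bundle["partition_summary"],
                "elapsed_s": round(time.time() - t0, 2),
            }
            with open(out / "run_manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
    except Exception:
        log.error("pipeline aborted at stage %r", stage)
        raise
    bundle["elapsed_s"] = time.time() - t0
    return bundle
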