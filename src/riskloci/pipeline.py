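"""End-to-end pipeline: simulate -> build loci -> region test -> eQTL ->
SMR -> meta-analysis -> methylation scan -> enrichment.

The pipeline is driven by a strict, validated :class:`PipelineConfig`
(unknown keys are rejected) and a single global seed that fans out to
per-stage child seeds.  Each stage writes its TSV/BED output into the run
directory, and the run ends with a machine-readable ``report.json`` that
validates against the shipped schema (``report_schema.json``, generated
from :class:`PipelineReport`).  Re-running with an identical config and
seed reproduces every output byte-identically; wall-clock timestamps only
appear in the log.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import evidence, loci as loci_mod, region, simulate, smr, sumstats

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "ConfigError",
    "StageError",
    "load_config",
    "run_pipeline",
    "flag_colocalized",
]

logger = logging.getLogger("riskloci")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 in the CLI)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Thresholds(_Strict):
    """Every analysis threshold, with its default."""

    p_subthresh: float = Field(1e-3, gt=0, lt=1)
    radius: int = Field(100_000, gt=0)
    alpha_region: float = Field(5e-8, gt=0, lt=1)
    p_eqtl_max: float = Field(1e-3, gt=0, lt=1)
    r2_max: float = Field(0.9, ge=0, le=1)
    known_margin: int = Field(500_000, ge=0)
    gene_window: int = Field(1_000_000, ge=0)
    alpha_target: float = Field(0.05, gt=0, lt=1)
    p_dmp: float = Field(1e-6, gt=0, lt=1)
    n_null: int = Field(10_000, ge=100)


class ScenarioBlock(_Strict):
    scenario: str = "pleiotropy"
    n_ref: int = Field(500, ge=30)
    m_snps: int = Field(60, ge=2)
    rho: float = Field(0.8, ge=0, lt=1)
    lam: float = 6.0
    h2_like: float = Field(0.1, ge=0, le=1)
    n_genes: int = Field(5, ge=1)
    linkage_r: float = Field(0.4, ge=0, le=1)


class MetaBlock(_Strict):
    k_studies: int = Field(9, ge=1)
    n_case: int = Field(32, ge=2)
    n_control: int = Field(38, ge=2)
    true_smd: float = -0.3
    tau: float = Field(0.1, ge=0)


class MethylationBlock(_Strict):
    n_cases: int = Field(100, ge=3)
    n_controls: int = Field(100, ge=3)
    m_probes: int = Field(2000, ge=1)
    n_dmp: int = Field(4, ge=0)
    effect: float = 1.5
    covariate_confounding: float = Field(0.0, ge=0, le=1)


class PipelineConfig(_Strict):
    seed: int = Field(0, ge=0, lt=2**31)
    outdir: str = "riskloci_run"
    # SMR runs over all built risk loci by default: target prioritization is
    # Bonferroni-gated by the SMR stage itself, and the region-significance
    # flag is reported alongside.  "significant" restricts SMR to loci
    # passing alpha_region.
    smr_scope: str = Field("all", pattern="^(all|significant)$")
    thresholds: Thresholds = Thresholds()
    simulate: ScenarioBlock = ScenarioBlock()
    meta: MetaBlock = MetaBlock()
    methylation: MethylationBlock = MethylationBlock()


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file strictly (unknown keys are an error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


class StageSummary(_Strict):
    model_config = ConfigDict(extra="allow")


class PipelineReport(_Strict):
    """Schema of report.json; shipped alongside the report itself."""

    seed: int
    thresholds: dict
    scenario: str
    n_loci: int
    n_significant_loci: int
    min_p_region: float | None
    region_or_correlation: dict | None
    n_smr_pairs: int
    n_smr_skipped: int
    target_genes: list[dict]
    best_gene: str | None
    meta: dict
    n_dmp_screened: int
    dmp_probes: list[str]
    enrichment: dict | None
    n_colocalized_snps: int
    stage_metadata: dict


def flag_colocalized(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    p_gwas_max: float = 5e-8,
    p_eqtl_max: float = 1e-3,
) -> list:
    """SNPs passing both the GWAS and eQTL significance thresholds.

    A simple threshold overlap (GWAS p < 5e-8 AND eQTL p < 1e-3) after
    allele harmonization — a reporting flag, not a colocalization
    posterior.
    """
    merged, _ = sumstats.harmonize_alleles(gwas, eqtl)
    if merged.empty:
        return []
    hit = (merged["p"] < p_gwas_max) & (merged["p_eqtl"] < p_eqtl_max)
    return sorted(set(merged.loc[hit, "snp_id"]))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                logger.error("stage %s: FAILED (%s)", name, err)
                raise StageError(name, err) from err
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on a simulated study and write the report bundle.

    Returns the report as a dict (also written to ``<outdir>/report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    th = config.thresholds
    logger.info("config: %s", config.model_dump())

    try:
        # ---- simulate ---------------------------------------------------
        sim = _stage("simulate")(simulate.simulate_smr_scenario)(
            scenario=config.simulate.scenario,
            n_ref=config.simulate.n_ref,
            m_snps=config.simulate.m_snps,
            rho=config.simulate.rho,
            lam=config.simulate.lam,
            h2_like=config.simulate.h2_like,
            n_genes=config.simulate.n_genes,
            linkage_r=config.simulate.linkage_r,
            seed=config.seed,
        )
        panel, gwas = sim["panel"], sim["sumstats"]
        sumstats.write_gwas_sumstats(gwas, outdir / "gwas_sumstats.tsv")
        simulate.write_panel(panel, outdir / "dosages.tsv", outdir / "snp_map.tsv")
        sim["genes"].to_csv(outdir / "genes.tsv", sep="\t", index=False)
        sim["truth"].to_yaml(outdir / "truth.yaml")

        # ---- build loci -------------------------------------------------
        locus_table = _stage("build-loci")(loci_mod.select_index_snps)(
            gwas, p_subthresh=th.p_subthresh, radius=th.radius
        )
        export = locus_table.drop(columns=["member_snps"]).assign(
            member_snps=locus_table["member_snps"].map(",".join)
        )
        export.to_csv(outdir / "loci.tsv", sep="\t", index=False)
        if len(locus_table):
            loci_mod.loci_to_bed(locus_table, outdir / "loci.bed")

        # ---- region test ------------------------------------------------
        region_results, region_meta = _stage("region-test")(region.genome_scan)(
            locus_table, gwas, panel, alpha=th.alpha_region
        )
        region_results.to_csv(outdir / "region_results.tsv", sep="\t", index=False)
        significant = region_results[region_results["significant"]]
        corr = None
        if len(region_results) >= 3:
            try:
                r, p, n = loci_mod.correlate_region_or(region_results)
                corr = {"r": r, "p": p, "n": n}
            except ValueError:
                corr = None

        # ---- eQTL -------------------------------------------------------
        eqtl = _stage("eqtl")(smr.eqtl_scan)(panel, sim["expression"], sim["covariates"])
        sumstats.write_eqtl(eqtl, outdir / "eqtl.tsv")

        # ---- SMR --------------------------------------------------------
        sig_loci = locus_table[locus_table["locus_id"].isin(significant["locus_id"])]
        smr_loci = sig_loci if config.smr_scope == "significant" else locus_table
        smr_results, skipped, smr_meta = _stage("smr")(smr.run_smr)(
            smr_loci, sim["genes"], gwas, eqtl, panel,
            window=th.gene_window, p_eqtl_max=th.p_eqtl_max,
            r2_max=th.r2_max, n_null=th.n_null, alpha=th.alpha_target,
            seed=simulate.child_seed(config.seed, "scenario"),
        )
        smr_results.to_csv(outdir / "smr_results.tsv", sep="\t", index=False)
        targets = smr_results[smr_results["target"]]
        best_gene = None
        if len(smr_results):
            best_gene = smr_results.loc[smr_results["p_smr_multi"].idxmin(), "gene_id"]

        # ---- meta-analysis ---------------------------------------------
        studies = _stage("meta")(simulate.simulate_expression_studies)(
            config.meta.k_studies, config.meta.n_case, config.meta.n_control,
            true_smd=config.meta.true_smd, tau=config.meta.tau,
            seed=simulate.child_seed(config.seed, "expression"),
        )
        effects = [
            evidence.study_effect(s["case"], s["control"], study_id=s["study_id"])
            for s in studies
        ]
        meta_result = evidence.meta_random_effects(effects)
        pd.DataFrame(
            [{"study_id": e.study_id, "effect": e.g, "variance": e.v} for e in effects]
        ).to_csv(outdir / "meta_input.tsv", sep="\t", index=False)

        # ---- methylation scan -------------------------------------------
        beta, labels, meth_cov, truth_probes = _stage("dmp")(simulate.simulate_methylation)(
            config.methylation.n_cases, config.methylation.n_controls,
            config.methylation.m_probes, n_dmp=config.methylation.n_dmp,
            effect=config.methylation.effect,
            covariate_confounding=config.methylation.covariate_confounding,
            seed=simulate.child_seed(config.seed, "methylation"),
        )
        dmp_stats, screened, n_constant = evidence.dmp_scan(
            beta, labels, meth_cov, p_screen=th.p_dmp
        )
        dmp_stats.to_csv(outdir / "dmp_results.tsv", sep="\t", index=False)

        # ---- enrichment --------------------------------------------------
        enrichment = None
        if len(sig_loci):
            hit_genes = set()
            for locus in sig_loci.itertuples(index=False):
                hit_genes |= set(loci_mod.map_genes(locus, sim["genes"], mode="overlap"))
            truth_set = set(sim["truth"].causal_eqtl)
            background = set(sim["genes"]["gene_id"])
            if hit_genes and truth_set:
                enr = _stage("enrich")(loci_mod.fisher_enrichment)(
                    hit_genes, truth_set, background
                )
                enrichment = {
                    "table": [list(enr.table[0]), list(enr.table[1])],
                    "odds_ratio": enr.odds_ratio,
                    "p": enr.p_value,
                }

        # ---- colocalization flag -----------------------------------------
        coloc = flag_colocalized(gwas, eqtl, p_gwas_max=th.alpha_region,
                                 p_eqtl_max=th.p_eqtl_max)

        report = PipelineReport(
            seed=config.seed,
            thresholds=th.model_dump(),
            scenario=config.simulate.scenario,
            n_loci=int(len(locus_table)),
            n_significant_loci=int(len(significant)),
            min_p_region=float(region_results["p_region"].min()) if len(region_results) else None,
            region_or_correlation=corr,
            n_smr_pairs=int(len(smr_results)),
            n_smr_skipped=int(len(skipped)),
            target_genes=[
                {"gene_id": row.gene_id, "locus_id": row.locus_id,
                 "p_smr_multi": row.p_smr_multi, "adj_p_smr_multi": row.adj_p_smr_multi}
                for row in targets.itertuples(index=False)
            ],
            best_gene=best_gene,
            meta={
                "pooled": meta_result.pooled, "se": meta_result.se_pooled,
                "ci95": list(meta_result.ci95), "tau2": meta_result.tau2,
                "q": meta_result.q, "p_meta": meta_result.p_meta, "k": meta_result.k,
            },
            n_dmp_screened=len(screened),
            dmp_probes=screened,
            enrichment=enrichment,
            n_colocalized_snps=len(coloc),
            stage_metadata={"region": region_meta, "smr": smr_meta,
                            "dmp": {"n_constant": n_constant,
                                    "truth_probes": truth_probes}},
        )
        payload = report.model_dump()
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        with open(outdir / "report_schema.json", "w") as fh:
            json.dump(PipelineReport.model_json_schema(), fh, indent=2)
        logger.info("report written to %s", outdir / "report.json")
        return payload
    finally:
        logger.removeHandler(handler)
        handler.close()
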