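"""End-to-end orchestration of the synthetic interaction-GWAS analysis.

``run_pipeline`` mirrors the sequence of a two-stage multi-cohort
gene-lifestyle interaction study at desk scale: simulate discovery and
replication cohorts sharing causal SNPs -> per-cohort genome-wide
interaction scan -> within-stage meta-analysis -> stage combination ->
LD clumping into signals and loci -> enrichment of interaction effects
conditional on marginal effects with direction classification ->
variance-explained decomposition -> exposure-stratified heritability ->
(optionally) the heterogeneity bias simulation.

Every stage writes its artifact into the run directory; a manifest records
the config hash, seed, package version and output list, and a JSON-lines
event log records every filter count so SNP bookkeeping is conserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .synthetic import (
    CohortData, CohortSpec, PhenoModel,
    simulate_exposure, simulate_genotypes, simulate_ldsc_inputs,
    simulate_ldsc_sumstats, LdscSimSpec, write_cohort_tsv,
)
from .gwis import run_gwis
from .meta import combine_stages, meta_sumstats
from .signals import LdPanel, clump, define_loci, write_loci_bed
from .enrichment import classify_directions, marginal_bins_enrichment
from .variance import variance_decomposition
from .ldsc import enrichment_comparison, h2_difference_test, ldsc_fit, ldsc_partitioned
from .bias_sim import CohortScenario, ScenarioSpec, run_null_scenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults give a few-minute desk-scale run."""

    seed: int = 1
    outdir: str = "gxemeta_run"

    # synthetic study design
    n_per_cohort: int = 2000
    cohorts_per_stage: int = 2
    m_snps: int = 600
    ld_block_size: int = 4
    ld_block_rho: float = 0.8
    prevalence: float = 0.4
    causal_index: tuple = (0, 200, 400)
    causal_betaG: tuple = (0.25, 0.20, 0.15)
    causal_betaGE: tuple = (0.15, 0.0, -0.10)
    betaE: float = 0.3
    sigma2: float = 1.0

    # thresholds
    p_threshold: float = 5e-8
    r2_threshold: float = 0.2
    window_kb: float = 500.0
    alpha_int: float = 0.05

    # stratified heritability (summary-level simulation scale)
    ldsc_M: int = 5000
    ldsc_N: int = 50000
    h2_unexposed: float = 0.25
    h2_exposed: float = 0.15
    n_annotations: int = 4
    ldsc_blocks: int = 100

    # stage toggles
    do_gwis: bool = True
    do_meta: bool = True
    do_signals: bool = True
    do_enrichment: bool = True
    do_varexp: bool = True
    do_ldsc: bool = True
    do_bias: bool = False
    bias_replicates: int = 500
    write_cohorts: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("causal_index", "causal_betaG", "causal_betaGE"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("causal_index", "causal_betaG", "causal_betaGE"):
            d[key] = list(d[key])
        return d


class _EventLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def emit(self, stage: str, event: str, **data):
        rec = {"stage": stage, "event": event, **data}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        logger.info("[%s] %s %s", stage, event, data)


def _simulate_study_cohort(cfg: RunConfig, seed: int) -> CohortData:
    """One cohort with the shared multi-SNP causal architecture."""
    n_blocks = cfg.m_snps // cfg.ld_block_size
    spec = CohortSpec(
        n=cfg.n_per_cohort,
        m=cfg.m_snps,
        maf=(0.05, 0.5),
        ld_blocks=tuple((cfg.ld_block_size, cfg.ld_block_rho) for _ in range(n_blocks)),
        exposure_kind="binary",
        exposure_param=cfg.prevalence,
        model=PhenoModel(betaE=cfg.betaE, sigma2=cfg.sigma2),
        seed=seed,
    )
    g = simulate_genotypes(spec)
    e = simulate_exposure(spec)
    rng = np.random.default_rng([seed, 5555])
    y = cfg.betaE * e + rng.normal(0.0, np.sqrt(cfg.sigma2), size=cfg.n_per_cohort)
    for j, bg, bge in zip(cfg.causal_index, cfg.causal_betaG, cfg.causal_betaGE):
        y = y + bg * g[:, j] + bge * g[:, j] * e
    return CohortData(genotypes=g, exposure=e, phenotype=y, truth=spec)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = _EventLog(outdir / "events.jsonl")
    outputs = []

    def save_df(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        outputs.append(name)
        return path

    def save_json(obj, name: str):
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        outputs.append(name)
        return path

    # ---- simulate -------------------------------------------------------
    stage_cohorts = {}
    for stage in (1, 2):
        stage_cohorts[stage] = [
            _simulate_study_cohort(config, seed=config.seed + 10 * stage + c)
            for c in range(config.cohorts_per_stage)
        ]
    events.emit("simulate", "done",
                cohorts=2 * config.cohorts_per_stage, m=config.m_snps)
    if config.write_cohorts:
        for stage, cohorts in stage_cohorts.items():
            for c, cohort in enumerate(cohorts):
                write_cohort_tsv(cohort, outdir / f"cohort_s{stage}_{c}")

    if not config.do_gwis:
        _finish(config, outdir, outputs)
        return outdir

    # ---- per-cohort GWIS ------------------------------------------------
    cohort_tables = {}
    for stage, cohorts in stage_cohorts.items():
        tables = []
        for c, cohort in enumerate(cohorts):
            tab = run_gwis(cohort)
            events.emit(
                "gwis", "cohort_done", stage_no=stage, cohort=c,
                snps_in=config.m_snps, snps_out=len(tab),
                n_excluded=len(tab.attrs["excluded"]),
            )
            save_df(tab, f"gwis_s{stage}_c{c}.tsv")
            tables.append(tab)
        cohort_tables[stage] = tables

    if not config.do_meta:
        _finish(config, outdir, outputs)
        return outdir

    # ---- meta-analysis --------------------------------------------------
    stage_meta = {}
    for stage, tables in cohort_tables.items():
        m = meta_sumstats(tables)
        events.emit("meta", "stage_done", stage_no=stage, snps=len(m),
                    n_dropped=m.attrs["n_dropped"])
        save_df(m, f"meta_stage{stage}.tsv")
        stage_meta[stage] = m
    combined = combine_stages(stage_meta[1], stage_meta[2])
    events.emit("meta", "combined", snps=len(combined),
                n_rejected=combined.attrs["n_rejected"])
    save_df(combined, "meta_combined.tsv")

    if not config.do_signals:
        _finish(config, outdir, outputs)
        return outdir

    # ---- signals and loci ----------------------------------------------
    panel_cohort = stage_cohorts[1][0]
    panel = LdPanel(
        panel_cohort.genotypes,
        [f"snp{j + 1:06d}" for j in range(config.m_snps)],
    )
    sigs = clump(
        combined, panel, p_col="P_2DF",
        p_threshold=config.p_threshold,
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
    )
    loci = define_loci(sigs, flank_kb=config.window_kb)
    sig_df = pd.DataFrame(
        [
            {"lead": s.lead, "CHR": s.chrom, "POS": s.pos, "P": s.p,
             "n_members": len(s.members), "members": ",".join(s.members)}
            for s in sigs
        ],
        columns=["lead", "CHR", "POS", "P", "n_members", "members"],
    )
    save_df(sig_df, "signals.tsv")
    write_loci_bed(loci, outdir / "loci.bed")
    outputs.append("loci.bed")
    events.emit("signals", "done", n_signals=len(sigs), n_loci=len(loci))

    lead_records = combined[combined["SNPID"].isin([s.lead for s in sigs])]

    if config.do_enrichment:
        # clump on the marginal track so the binned SNPs are independent
        marg = combined.copy()
        marg["P_MARG"] = stats.chi2.sf(
            (marg["BETA_MARG"] / marg["SE_MARG"]) ** 2, df=1
        )
        marg_sigs = clump(
            marg, panel, p_col="P_MARG", p_threshold=1.0,
            r2_threshold=config.r2_threshold, window_kb=config.window_kb,
        )
        marg_leads = marg[marg["SNPID"].isin([s.lead for s in marg_sigs])]
        bins = marginal_bins_enrichment(
            marg_leads["P_MARG"].to_numpy(),
            marg_leads["P_1DF"].to_numpy(),
            alpha_int=config.alpha_int,
        )
        bin_df = pd.DataFrame(
            [
                {
                    "upper": b.upper, "lower": b.lower, "n_snps": b.n_snps,
                    "n_int_sig": b.n_int_sig, "proportion": b.proportion,
                    "ci_low": b.ci_low, "ci_high": b.ci_high,
                    "null_low_05": b.null_band_05[0],
                    "null_high_05": b.null_band_05[1],
                }
                for b in bins
            ]
        )
        save_df(bin_df, "enrichment_bins.tsv")
        trio = classify_directions(lead_records, trio_id=("synthetic", "binary", "NA"))
        save_json(dataclasses.asdict(trio), "trio_classification.json")
        events.emit("enrichment", "done", n_bins=len(bins),
                    n_sig_snps=trio.n_sig_snps)

    if config.do_varexp and len(lead_records) > 0:
        var_y = float(np.var(np.concatenate(
            [c.phenotype for c in stage_cohorts[1]]
        )))
        dec = variance_decomposition(
            lead_records, exposure_param=config.prevalence,
            kind="binary", var_Y=var_y,
        )
        save_json(dataclasses.asdict(dec), "variance_explained.json")
        events.emit("varexp", "done", n_snps=dec.n_snps,
                    r2_joint=dec.r2_joint)

    if config.do_ldsc:
        ld, annot = simulate_ldsc_inputs(
            config.ldsc_M, config.n_annotations, seed=config.seed + 77
        )
        names = ["base"] + [f"annot{c}" for c in range(1, config.n_annotations + 1)]
        strata = {}
        for label, h2, offset in (
            ("unexposed", config.h2_unexposed, 201),
            ("exposed", config.h2_exposed, 202),
        ):
            chi2 = simulate_ldsc_sumstats(LdscSimSpec(
                M=config.ldsc_M, ld_scores=ld, N=config.ldsc_N, h2=h2,
                seed=config.seed + offset,
            ))
            fit = ldsc_fit(chi2, ld, N=config.ldsc_N,
                           n_blocks=config.ldsc_blocks)
            pfit = ldsc_partitioned(
                chi2, annot * ld[:, None], annot, N=config.ldsc_N,
                n_blocks=config.ldsc_blocks, annot_names=names,
            )
            strata[label] = (fit, pfit)
        z, p_diff = h2_difference_test(
            strata["unexposed"][0].h2, strata["unexposed"][0].h2_se,
            strata["exposed"][0].h2, strata["exposed"][0].h2_se,
        )
        comp = enrichment_comparison(
            strata["unexposed"][1], strata["exposed"][1],
            grouping={n: "tissueA" if i % 2 else "tissueB"
                      for i, n in enumerate(names[1:])},
        )
        save_json(
            {
                "unexposed": {"h2": strata["unexposed"][0].h2,
                              "h2_se": strata["unexposed"][0].h2_se,
                              "intercept": strata["unexposed"][0].intercept},
                "exposed": {"h2": strata["exposed"][0].h2,
                            "h2_se": strata["exposed"][0].h2_se,
                            "intercept": strata["exposed"][0].intercept},
                "difference_z": z,
                "difference_p": p_diff,
                "delta_enrichment": comp.delta_enrichment,
                "enrichment_corr": comp.enrichment_corr,
            },
            "ldsc_strata.json",
        )
        events.emit("ldsc", "done", p_diff=p_diff)

    if config.do_bias:
        spec = ScenarioSpec(
            cohorts=(
                CohortScenario(n=2000, f=0.3, betaG=0.0, exposure_param=0.2),
                CohortScenario(n=2000, f=0.3, betaG=0.5, exposure_param=0.8),
            ),
            n_replicates=config.bias_replicates,
            seed=config.seed + 909,
        )
        report = run_null_scenario(spec)
        save_df(report.rates, "bias_rates.tsv")
        events.emit("bias", "done", n_dropped=report.n_dropped)

    _finish(config, outdir, outputs)
    return outdir


def _finish(config: RunConfig, outdir: Path, outputs: list) -> None:
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": cfg,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "gxemeta_version": __version__,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
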