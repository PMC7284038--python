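"""One-config end-to-end run: simulate two cohorts, clump, scan, score,
categorize, transfer cutoffs, and evaluate head-to-head against the packaged
36-SNP score.

The YAML config mirrors :class:`~ldlprs.simulate.SimulationConfig`; every
key is optional.  Example::

    seed: 1
    n_null_genotyped: 100        # null loci carried in the genotypes
    construction: {n_samples: 1200, target_incremental_r2: 0.08}
    replication:  {n_samples: 2400}
    clump: {r2: 0.1, window_kb: 250}
    scan:  {grid_min_exp: 3, grid_max_exp: 100, grid_step: 1}
    covariates: [age, sex, bmi, mds1, mds2]
    fractions: [0.3, 0.3, 0.4]

Outputs (TSV/JSON) are written to the output directory: the scan table, the
selected scoring file, cutoffs, per-cohort scores and risk classes, the
reclassification table, and an ``evaluation.json`` with the fit, AUC, risk
ratio, Wilcoxon and DeLong results for both cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ldstats, risk, scoring, simulate
from .io import (
    ScoreDefinition,
    load_canonical_36snp_score,
    write_genotypes_vcf,
    write_score_definition,
)

logger = logging.getLogger(__name__)

_PROFILE_KEYS = {
    "n_samples",
    "target_incremental_r2",
    "age_mean",
    "age_sd",
    "male_fraction",
    "bmi_median",
    "bmi_q1",
    "bmi_q3",
    "smoker_fraction",
    "age_coef",
    "sex_coef",
    "bmi_coef",
    "smoker_coef",
    "ldl_median",
    "ldl_q1",
    "ldl_q3",
}


def load_pipeline_config(path: str | Path | None) -> dict:
    cfg = {}
    if path is not None:
        with Path(path).open() as fh:
            cfg = yaml.safe_load(fh) or {}
    return cfg


def _cohort_configs(cfg: dict, seed: int) -> tuple[simulate.SimulationConfig, simulate.SimulationConfig]:
    n_null = int(cfg.get("n_null_genotyped", 100))
    specs = list(simulate.canonical_variant_specs(seed))
    if n_null:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
        freqs = rng.uniform(0.05, 0.5, size=n_null)
        for i in range(n_null):
            specs.append(
                simulate.VariantSpec(
                    id=f"null{i + 1}", chrom="21", pos=1_000_000 + i * 600_000, freq=float(freqs[i])
                )
            )
    specs = tuple(specs)
    con_over = {k: v for k, v in (cfg.get("construction") or {}).items() if k in _PROFILE_KEYS}
    rep_over = {k: v for k, v in (cfg.get("replication") or {}).items() if k in _PROFILE_KEYS}
    con = simulate.american_cohort_config(seed, variants=specs, **con_over)
    rep = simulate.finnish_cohort_config(seed, variants=specs, **rep_over)
    return con, rep


def run_pipeline(
    config: dict | str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
    write_inputs: bool = False,
) -> dict:
    """Run the full construction/replication study on synthetic cohorts.

    Returns the evaluation dictionary (also written to
    ``out_dir/evaluation.json``).  ``seed`` overrides the config's seed.
    """
    cfg = load_pipeline_config(config) if not isinstance(config, dict) else dict(config)
    if config is None:
        cfg = {}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    con_cfg, rep_cfg = _cohort_configs(cfg, seed)
    bundle_con, bundle_rep = simulate.two_cohort_scenario(con_cfg, rep_cfg)
    sumstats = simulate.simulate_summary_stats(con_cfg)
    sumstats.to_csv(out / "summary_stats.tsv", sep="\t", index=False)
    if write_inputs:
        write_genotypes_vcf(bundle_con.genotypes, out / "construction.vcf")
        write_genotypes_vcf(bundle_rep.genotypes, out / "replication.vcf")
        bundle_con.phenotypes.to_csv(out / "construction_phenotypes.csv")
        bundle_rep.phenotypes.to_csv(out / "replication_phenotypes.csv")

    # --- clump against construction-cohort LD
    clump_cfg = cfg.get("clump") or {}
    clumped = ldstats.clump(
        sumstats,
        bundle_con.genotypes,
        r2_threshold=float(clump_cfg.get("r2", 0.1)),
        window_kb=float(clump_cfg.get("window_kb", 250.0)),
    )
    pd.DataFrame(
        [{"rsid": r, "status": "retained", "index_snp": "", "r2": ""} for r in clumped.retained]
        + [
            {"rsid": v, "status": "removed", "index_snp": idx, "r2": f"{r2:.4f}"}
            for v, (idx, r2) in clumped.removed.items()
        ]
    ).to_csv(out / "clump.tsv", sep="\t", index=False)
    clumped_ss = sumstats[sumstats["rsid"].isin(clumped.retained)]

    # --- ancestry covariates and threshold scan on the construction cohort
    covariates = list(cfg.get("covariates", ["age", "sex", "bmi", "mds1", "mds2"]))
    k_mds = sum(1 for c in covariates if c.startswith("mds"))
    pheno_con = bundle_con.phenotypes.copy()
    pheno_rep = bundle_rep.phenotypes.copy()
    if k_mds:
        pheno_con = pheno_con.join(ldstats.mds_covariates(bundle_con.genotypes, k=k_mds))
        pheno_rep = pheno_rep.join(ldstats.mds_covariates(bundle_rep.genotypes, k=k_mds))
    scan_cfg = cfg.get("scan") or {}
    grid = scoring.default_threshold_grid(
        float(scan_cfg.get("grid_min_exp", 3)),
        float(scan_cfg.get("grid_max_exp", 100)),
        float(scan_cfg.get("grid_step", 1)),
    )
    scan = scoring.scan_thresholds(clumped_ss, bundle_con.genotypes, pheno_con, covariates, grid)
    scan.table.to_csv(out / "scan.tsv", sep="\t", index=False)
    best = scan.best_score
    write_score_definition(best, out / "best_score.tsv")

    # --- score both cohorts with the selected and the packaged score
    results: dict = {"seed": seed, "best_threshold": scan.best_threshold, "n_snps_best": best.n}
    canonical = load_canonical_36snp_score()
    prs = {}
    for label, bundle, pheno in (
        ("construction", bundle_con, pheno_con),
        ("replication", bundle_rep, pheno_rep),
    ):
        aligned = scoring.align_alleles(best, bundle.genotypes)
        imputed = scoring.impute_missing_dosages(bundle.genotypes, aligned)
        vec = scoring.compute_prs(imputed, aligned)
        aligned_c = scoring.align_alleles(canonical, bundle.genotypes)
        vec_c = scoring.compute_prs(
            scoring.impute_missing_dosages(bundle.genotypes, aligned_c), aligned_c
        )
        prs[label] = (vec, vec_c, pheno)
        pd.DataFrame(
            {"prs_selected": vec.values, "prs_canonical": vec_c.values}
        ).to_csv(out / f"prs_{label}.tsv", sep="\t")

    # --- cutoffs on construction, transferred to replication
    fractions = tuple(cfg.get("fractions", risk.DEFAULT_FRACTIONS))
    cutoffs = risk.decile_cutoffs(prs["construction"][0].values, fractions)
    risk.write_cutoffs(cutoffs, out / "cutoffs.tsv")
    cutoffs_c = risk.decile_cutoffs(prs["construction"][1].values, fractions)

    for label in ("construction", "replication"):
        vec, vec_c, pheno = prs[label]
        classes = risk.assign_risk_class(vec.values, cutoffs)
        classes_c = risk.assign_risk_class(vec_c.values, cutoffs_c)
        pheno_cls = risk.categorize_phenotype(pheno)
        pd.DataFrame(
            {"risk_selected": classes, "risk_canonical": classes_c, "ldl_class": pheno_cls}
        ).to_csv(out / f"risk_classes_{label}.tsv", sep="\t")

        fit = scoring.incremental_r2(vec, pheno, covariates)
        severe = (pheno_cls == "severe_HC").astype(int)
        auc = risk.roc_auc(vec.values, severe)
        auc_a, auc_b, z, p_delong = risk.delong_test(vec.values, vec_c.values, severe)
        high, low = classes == "high", classes == "low"
        rr = risk.risk_ratio(
            int((severe[high] == 1).sum()), int(high.sum()),
            int((severe[low] == 1).sum()), int(low.sum()),
        )
        w_stat, w_p = risk.wilcoxon_test(
            pheno.loc[high, "ldl_c"], pheno.loc[low, "ldl_c"]
        )
        severe_idx = pheno_cls.index[pheno_cls == "severe_HC"]
        reclass = risk.reclassification_table(classes_c, classes, subset=severe_idx)
        reclass.counts.to_csv(out / f"reclassification_severe_{label}.tsv", sep="\t")
        results[label] = {
            "n": len(pheno),
            "incremental_r2": fit.incremental,
            "r2_full": fit.r2_full,
            "r2_null": fit.r2_null,
            "model_pvalue": fit.model_pvalue,
            "auc_severe": auc,
            "auc_canonical": auc_b,
            "delong_z": z,
            "delong_p": p_delong,
            "risk_ratio": rr.rr,
            "rr_ci": [rr.ci_low, rr.ci_high],
            "rr_p": rr.pvalue,
            "wilcoxon_p": w_p,
            "median_ldl_high": float(pheno.loc[high, "ldl_c"].median()),
            "median_ldl_low": float(pheno.loc[low, "ldl_c"].median()),
            "n_severe": int((pheno_cls == "severe_HC").sum()),
            "concordance_severe": (
                risk.concordance_fraction(classes_c, classes, subset=severe_idx)
                if len(severe_idx)
                else None
            ),
        }
    with (out / "evaluation.json").open("w") as fh:
        json.dump(results, fh, indent=2)
    return results
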