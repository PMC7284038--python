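"""Synthetic two-cohort generator for end-to-end testing of the PRS pipeline.

Genotypes are drawn per LD block from a latent Gaussian threshold model:
each haplotype gets a multivariate-normal vector with exchangeable
within-block correlation, an allele is carried where the latent value falls
below the variant's frequency quantile, and the two haplotypes sum to a
dosage in {0, 1, 2}.  Blocks are independent of each other.

The phenotype follows the linear model the evaluation assumes,
LDL-C = intercept + c * PRS + covariate terms + Gaussian noise, with the
scale ``c`` and the noise variance solved from the *realized* score and
covariate variances so that the score's incremental variance share equals
the configured target.  Cohort location/scale targets (median, IQR) default
to the construction- and replication-cohort values of the study design this
package implements (American: median 3.60, IQR 3.08-4.11; Finnish: median
2.90, IQR 2.40-3.50 mmol/L).

Randomness is fully deterministic under a seed, with separate spawned
streams for genotypes, covariates, phenotype noise and summary statistics,
so toggling one component leaves the others bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, ScoreDefinition, load_canonical_36snp_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSpec:
    """One simulated locus: position, alleles, effect-allele (ALT) frequency
    and an optional LD-block label (variants sharing a label are correlated)."""

    id: str
    chrom: str
    pos: int
    freq: float
    ref: str = "A"
    alt: str = "G"
    block: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.freq < 1.0):
            raise ValueError(f"{self.id}: frequency must be in (0, 1), got {self.freq}")


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    ``block_r2`` maps an LD-block label to the target within-block dosage
    r²; the latent haplotype correlation is its square root, so the
    realized dosage correlation is mildly attenuated by thresholding.
    ``true_betas`` (variant id -> per-allele effect) defines the causal
    score; ``target_incremental_r2`` is the share of phenotype variance the
    true score explains beyond the covariates.  Covariate moments and LDL-C
    location/scale default to the construction-cohort profile.
    """

    n_samples: int
    variants: tuple[VariantSpec, ...]
    seed: int
    block_r2: dict[str, float] = field(default_factory=dict)
    true_betas: dict[str, float] = field(default_factory=dict)
    target_incremental_r2: float = 0.08
    # covariate moments (construction-cohort profile)
    age_mean: float = 60.0
    age_sd: float = 11.5
    male_fraction: float = 0.49
    bmi_median: float = 27.8
    bmi_q1: float = 24.9
    bmi_q3: float = 31.4
    smoker_fraction: float = 0.31
    # covariate effects on LDL-C (mmol/L per unit)
    age_coef: float = 0.01
    sex_coef: float = 0.10
    bmi_coef: float = 0.02
    smoker_coef: float = 0.05
    # phenotype location/scale targets (mmol/L)
    ldl_median: float = 3.60
    ldl_q1: float = 3.08
    ldl_q3: float = 4.11
    # summary-statistic generation
    n_null_variants: int = 0
    causal_p_exponent_range: tuple[float, float] = (20.0, 100.0)
    null_p_exponent_range: tuple[float, float] | None = None
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.target_incremental_r2 < 1.0):
            raise ValueError("target_incremental_r2 must be in [0, 1)")
        ids = [v.id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant ids in config")
        unknown = set(self.true_betas) - set(ids)
        if unknown:
            raise ValueError(f"true_betas for unknown variants: {sorted(unknown)}")
        for b, r2 in self.block_r2.items():
            if not (0.0 <= r2 < 1.0):
                raise ValueError(f"block {b}: target r2 must be in [0, 1), got {r2}")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named, independent RNG streams spawned from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genotypes", "covariates", "noise", "sumstats")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class CohortBundle:
    """One simulated cohort plus the generative ground truth."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_prs: pd.Series
    realized: dict


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw dosages from the latent-Gaussian threshold model.

    Within a block, haplotypes share an exchangeable latent correlation of
    sqrt(target r²); across blocks haplotypes are independent.  Errors if a
    block's implied correlation matrix is not positive semi-definite.
    """
    if rng is None:
        rng = config.streams()["genotypes"]
    n = config.n_samples
    ids = [v.id for v in config.variants]
    dosages = np.empty((n, len(ids)), dtype=float)
    col = {vid: j for j, vid in enumerate(ids)}

    groups: dict[str, list[VariantSpec]] = {}
    for v in config.variants:
        groups.setdefault(v.block if v.block is not None else f"__solo_{v.id}", []).append(v)

    for label, members in groups.items():
        k = len(members)
        rho = math.sqrt(config.block_r2.get(label, 0.0)) if k > 1 else 0.0
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        if k > 1 and np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError(f"block {label}: correlation matrix not positive semi-definite")
        thresholds = stats.norm.ppf([m.freq for m in members])
        # two haplotypes per individual, each a latent MVN draw
        z = rng.multivariate_normal(np.zeros(k), cov, size=(n, 2), method="cholesky")
        alleles = (z < thresholds).sum(axis=1)  # sum over the two haplotypes
        for jj, m in enumerate(members):
            dosages[:, col[m.id]] = alleles[:, jj]

    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": [v.chrom for v in config.variants],
            "pos": [v.pos for v in config.variants],
            "ref": [v.ref for v in config.variants],
            "alt": [v.alt for v in config.variants],
        }
    )
    sample_ids = [f"{config.sample_prefix}{i + 1}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, dosages=dosages, dosage_allele="alt"
    )


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Age (normal), sex (Bernoulli, 1 = male), BMI (log-normal matched to
    the configured median and IQR) and smoking status."""
    if rng is None:
        rng = config.streams()["covariates"]
    n = config.n_samples
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    sigma_log = math.log(config.bmi_q3 / config.bmi_q1) / (2.0 * stats.norm.ppf(0.75))
    bmi = np.exp(rng.normal(math.log(config.bmi_median), sigma_log, size=n))
    smoker = (rng.random(n) < config.smoker_fraction).astype(int)
    sample_ids = [f"{config.sample_prefix}{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {"age": age, "sex": sex, "bmi": bmi, "smoker": smoker},
        index=pd.Index(sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------


def true_prs(genotypes: GenotypeMatrix, config: SimulationConfig) -> pd.Series:
    """The generative score: sum of true betas times ALT dosages."""
    if not config.true_betas:
        return pd.Series(
            np.zeros(genotypes.n_samples),
            index=pd.Index(genotypes.sample_ids, name="sample_id"),
        )
    vidx = genotypes.variant_index()
    cols = [vidx[vid] for vid in config.true_betas]
    betas = np.array(list(config.true_betas.values()))
    values = genotypes.dosages[:, cols] @ betas
    return pd.Series(values, index=pd.Index(genotypes.sample_ids, name="sample_id"))


LDL_FLOOR = 0.1  # mmol/L; truncation floor keeping LDL-C positive


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    score: pd.Series,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """LDL-C from the linear generative model, calibrated to the target
    incremental variance share and the configured median/IQR.

    The total phenotype variance target is ((q3 - q1) / 1.349)^2.  The
    score scale ``c`` satisfies c^2 * var(score) = target_r2 * total, and
    the Gaussian noise variance absorbs the remainder after the covariate
    contribution; a covariate contribution exceeding (1 - target) * total
    is infeasible and raises.  Values at or below zero after the location
    shift are truncated to a small positive floor with a logged count.

    Returns the phenotype table (covariates + ldl_c + complete flag) and a
    dict of realized generative parameters.
    """
    streams = config.streams()
    if rng is None:
        rng = streams["noise"]
    if covariates is None:
        covariates = simulate_covariates(config, streams["covariates"])
    n = config.n_samples
    g = score.to_numpy(dtype=float)
    covar_lin = (
        config.age_coef * covariates["age"].to_numpy()
        + config.sex_coef * covariates["sex"].to_numpy()
        + config.bmi_coef * covariates["bmi"].to_numpy()
        + config.smoker_coef * covariates["smoker"].to_numpy()
    )
    total_sd = (config.ldl_q3 - config.ldl_q1) / (2.0 * stats.norm.ppf(0.75))
    total_var = total_sd**2
    vg = float(np.var(g))
    vc = float(np.var(covar_lin))
    t = config.target_incremental_r2
    if vc > (1.0 - t) * total_var + 1e-12:
        raise ValueError(
            f"covariate variance {vc:.4f} exceeds (1 - target) * total variance "
            f"{(1.0 - t) * total_var:.4f}; target share infeasible"
        )
    if t > 0 and vg == 0:
        raise ValueError("target_incremental_r2 > 0 but the true score has zero variance")
    c = math.sqrt(t * total_var / vg) if t > 0 and vg > 0 else 0.0
    noise_var = max(total_var - t * total_var - vc, 0.0)
    noise = rng.normal(0.0, math.sqrt(noise_var), size=n)
    raw = c * g + covar_lin + noise
    ldl = raw + (config.ldl_median - float(np.median(raw)))
    n_trunc = int((ldl <= 0).sum())
    if n_trunc:
        logger.warning("simulate_phenotype: truncated %d non-positive LDL-C value(s)", n_trunc)
        ldl = np.maximum(ldl, LDL_FLOOR)
    pheno = covariates.copy()
    pheno.insert(0, "ldl_c", ldl)
    pheno["complete"] = True
    realized = {
        "score_scale_c": c,
        "noise_variance": noise_var,
        "score_variance": vg,
        "covariate_variance": vc,
        "total_variance_target": total_var,
        "generative_incremental_r2": (c**2 * vg) / total_var if total_var > 0 else 0.0,
        "n_truncated": n_trunc,
    }
    return pheno, realized


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def simulate_summary_stats(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Emulated GWAS summary statistics over the configured variants.

    Causal variants (those with a true beta) report their beta with a
    p-value of 10^-U(causal_p_exponent_range).  The remaining configured
    variants, plus ``n_null_variants`` extra loci placed on a separate
    chromosome, report small noise betas with p ~ Uniform(0, 1) (or
    10^-U(null_p_exponent_range) when configured).
    """
    if rng is None:
        rng = config.streams()["sumstats"]
    rows = []

    def null_p() -> float:
        if config.null_p_exponent_range is not None:
            lo, hi = config.null_p_exponent_range
            return 10.0 ** (-rng.uniform(lo, hi))
        return float(np.clip(rng.uniform(), 1e-300, 1.0))

    for v in config.variants:
        if v.id in config.true_betas:
            lo, hi = config.causal_p_exponent_range
            p = 10.0 ** (-rng.uniform(lo, hi))
            beta = config.true_betas[v.id]
        else:
            p = null_p()
            beta = float(rng.normal(0.0, 0.01))
        rows.append((v.id, v.chrom, v.pos, v.ref, v.alt, beta, p))
    for i in range(config.n_null_variants):
        rows.append(
            (
                f"null{i + 1}",
                "99",
                1_000_000 + i * 1_000_000,
                "A",
                "G",
                float(rng.normal(0.0, 0.01)),
                null_p(),
            )
        )
    return pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "allele_a", "allele_b", "beta", "pvalue"]
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Genotypes, covariates and phenotype for one cohort, with realized
    generative parameters (achieved frequencies, achieved variance share)."""
    streams = config.streams()
    genotypes = simulate_genotypes(config, streams["genotypes"])
    covariates = simulate_covariates(config, streams["covariates"])
    g = true_prs(genotypes, config)
    pheno, realized = simulate_phenotype(
        genotypes, g, config, covariates=covariates, rng=streams["noise"]
    )
    realized["achieved_freq"] = dict(
        zip(genotypes.variants["id"], genotypes.alt_frequency())
    )
    return CohortBundle(genotypes=genotypes, phenotypes=pheno, true_prs=g, realized=realized)


def two_cohort_scenario(
    config_construction: SimulationConfig,
    config_replication: SimulationConfig,
    shared_score: ScoreDefinition | None = None,
) -> tuple[CohortBundle, CohortBundle]:
    """Two independent cohorts over the same variants and the same true
    score — the construction/replication (cutoff-transfer) scenario."""
    ids_a = [v.id for v in config_construction.variants]
    ids_b = [v.id for v in config_replication.variants]
    if ids_a != ids_b:
        raise ValueError("cohort configs reference different variant specs")
    if config_construction.true_betas != config_replication.true_betas:
        raise ValueError("cohort configs carry different true scores")
    if shared_score is not None:
        absent = set(shared_score.variant_ids) - set(ids_a)
        if absent:
            raise ValueError(f"shared score variants absent from variant spec: {sorted(absent)}")
    return simulate_cohort(config_construction), simulate_cohort(config_replication)


# ---------------------------------------------------------------------------
# Study-profile factories
# ---------------------------------------------------------------------------


def canonical_variant_specs(
    seed: int,
    freq_range: tuple[float, float] = (0.05, 0.5),
    block_from_proximity: bool = False,
) -> tuple[VariantSpec, ...]:
    """Variant specs for the packaged 36-SNP score with frequencies drawn
    Uniform(freq_range) — the score publishes no allele frequencies, so the
    draw is an arbitrary but documented default.  With
    ``block_from_proximity`` variants within 250 kb on the same chromosome
    share an LD block."""
    score = load_canonical_36snp_score()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 36]))
    freqs = rng.uniform(*freq_range, size=score.n)
    specs = []
    block_of: dict[str, str] = {}
    if block_from_proximity:
        ordered = sorted(score.variants, key=lambda v: (v.chrom, v.pos))
        current: list = []
        for v in ordered:
            if current and v.chrom == current[-1].chrom and v.pos - current[-1].pos <= 250_000:
                current.append(v)
            else:
                current = [v]
            block_of[v.variant_id] = f"{current[0].chrom}:{current[0].pos}"
    for v, f in zip(score.variants, freqs):
        specs.append(
            VariantSpec(
                id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                freq=float(f),
                ref=v.other_allele,
                alt=v.effect_allele,
                block=block_of.get(v.variant_id),
            )
        )
    return tuple(specs)


def american_cohort_config(seed: int, n_samples: int = 2197, **overrides) -> SimulationConfig:
    """Construction-cohort profile: n = 2,197; LDL-C median 3.60
    (IQR 3.08-4.11); age 60 +/- 11.5; 49% male; BMI 27.8 (24.9-31.4);
    31% smokers; true score = the packaged 36-SNP weights at 8% share."""
    variants = overrides.pop("variants", canonical_variant_specs(seed))
    betas = overrides.pop(
        "true_betas", {v.variant_id: v.weight for v in load_canonical_36snp_score().variants}
    )
    return SimulationConfig(
        n_samples=n_samples,
        variants=variants,
        seed=seed,
        true_betas=betas,
        sample_prefix="A",
        **overrides,
    )


def finnish_cohort_config(seed: int, n_samples: int = 4787, **overrides) -> SimulationConfig:
    """Replication-cohort profile: n = 4,787; LDL-C median 2.90
    (IQR 2.40-3.50); age 31 +/- 0.2 (birth cohort); 48% male; BMI 23.9
    (21.9-26.6); 37% smokers.  Must share the variant spec (hence seed)
    with the construction cohort for cutoff transfer."""
    variants = overrides.pop("variants", canonical_variant_specs(seed))
    betas = overrides.pop(
        "true_betas", {v.variant_id: v.weight for v in load_canonical_36snp_score().variants}
    )
    defaults = dict(
        age_mean=31.0,
        age_sd=0.2,
        male_fraction=0.48,
        bmi_median=23.9,
        bmi_q1=21.9,
        bmi_q3=26.6,
        smoker_fraction=0.37,
        ldl_median=2.90,
        ldl_q1=2.40,
        ldl_q3=3.50,
    )
    defaults.update(overrides)
    return SimulationConfig(
        n_samples=n_samples,
        variants=variants,
        seed=seed + 1,
        true_betas=betas,
        sample_prefix="F",
        **defaults,
    )
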