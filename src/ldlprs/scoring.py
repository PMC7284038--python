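"""Score application and selection.

The polygenic risk score of individual *j* is the weighted sum of
effect-allele dosages, PRS_j = sum_i beta_i * x_ij, with weights taken from
GWAS summary statistics.  Scores are raw weighted sums — no per-SNP
averaging and no standardisation — because the packaged risk-class cutoffs
are on the raw-sum scale.

Model comparison uses the incremental R²: the ordinary R² of
LDL-C ~ PRS + covariates minus that of LDL-C ~ covariates.  The
p-value-threshold scan rebuilds the score at each threshold on a grid and
keeps the threshold maximising incremental R².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import GenotypeMatrix, ScoreDefinition, ScoreVariant

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_COVARIATES = ["age", "sex", "bmi", "mds1", "mds2"]


class Orientation(str, Enum):
    DIRECT = "direct"
    FLIPPED = "flipped"
    DROPPED = "dropped"


@dataclass(frozen=True)
class AlignedVariant:
    variant_id: str
    weight: float | None
    orientation: Orientation
    genotype_column: int | None
    effect_allele_freq: float | None
    reason: str | None = None


@dataclass
class AlignedScore:
    """Per-variant orientation of a score against a genotype matrix.

    Every score variant appears exactly once, either usable (direct /
    flipped, with a genotype column and in-sample effect-allele frequency)
    or dropped with a reason.
    """

    score_name: str
    variants: list[AlignedVariant]

    @property
    def used(self) -> list[AlignedVariant]:
        return [v for v in self.variants if v.orientation is not Orientation.DROPPED]

    @property
    def dropped(self) -> list[AlignedVariant]:
        return [v for v in self.variants if v.orientation is Orientation.DROPPED]


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) == b.upper()


def align_alleles(
    score: ScoreDefinition,
    genotypes: GenotypeMatrix,
    palindromic_policy: str = "maf",
) -> AlignedScore:
    """Orient each score variant against the genotype matrix's counted allele.

    Variants are matched by id, falling back to (chrom, pos).  If the effect
    allele is the genotype's ALT allele the orientation is direct; if it is
    the REF allele the dosage enters as 2 - x (flipped).  Palindromic (A/T,
    C/G) variants are handled per ``palindromic_policy``:

    * ``"maf"`` (default) — drop when the in-sample minor-allele frequency
      is in (0.4, 0.5] (strand ambiguity unresolvable), else orient by
      allele match;
    * ``"keep"`` — always orient by allele match;
    * ``"drop"`` — always drop.

    A score whose variants all fail to match is an error.
    """
    if palindromic_policy not in ("maf", "keep", "drop"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    score.require_weights()
    by_id = genotypes.variant_index()
    by_pos = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(genotypes.variants["chrom"], genotypes.variants["pos"]))
    }
    alt_freq = genotypes.alt_frequency()
    out: list[AlignedVariant] = []
    for v in score.variants:
        j = by_id.get(v.variant_id)
        if j is None:
            j = by_pos.get((str(v.chrom), int(v.pos)))
        if j is None:
            out.append(
                AlignedVariant(v.variant_id, v.weight, Orientation.DROPPED, None, None, "unmatched")
            )
            continue
        ref = str(genotypes.variants["ref"].iloc[j]).upper()
        alt = str(genotypes.variants["alt"].iloc[j]).upper()
        ea = (v.effect_allele or "").upper()
        oa = (v.other_allele or "").upper()
        if not ea:
            out.append(
                AlignedVariant(
                    v.variant_id, v.weight, Orientation.DROPPED, None, None, "no effect allele"
                )
            )
            continue
        if _is_palindromic(ea, oa) if oa else _is_palindromic(ref, alt):
            if palindromic_policy == "drop":
                out.append(
                    AlignedVariant(
                        v.variant_id, v.weight, Orientation.DROPPED, None, None, "palindromic"
                    )
                )
                continue
            if palindromic_policy == "maf":
                af = alt_freq[j]
                maf = min(af, 1 - af) if np.isfinite(af) else np.nan
                if not np.isfinite(maf) or 0.4 < maf <= 0.5:
                    out.append(
                        AlignedVariant(
                            v.variant_id,
                            v.weight,
                            Orientation.DROPPED,
                            None,
                            None,
                            "ambiguous palindromic",
                        )
                    )
                    continue
        if ea == alt and (not oa or oa == ref):
            orient, eaf = Orientation.DIRECT, alt_freq[j]
        elif ea == ref and (not oa or oa == alt):
            orient, eaf = Orientation.FLIPPED, 1.0 - alt_freq[j]
        else:
            out.append(
                AlignedVariant(
                    v.variant_id, v.weight, Orientation.DROPPED, None, None, "allele mismatch"
                )
            )
            continue
        out.append(AlignedVariant(v.variant_id, v.weight, orient, j, float(eaf)))
    aligned = AlignedScore(score_name=score.name, variants=out)
    if not aligned.used:
        raise ValueError(f"no variant of score '{score.name}' matched the genotype matrix")
    if aligned.dropped:
        logger.info(
            "align_alleles: %d/%d variant(s) dropped (%s)",
            len(aligned.dropped),
            len(out),
            ", ".join(f"{d.variant_id}:{d.reason}" for d in aligned.dropped[:5]),
        )
    return aligned


def impute_missing_dosages(genotypes: GenotypeMatrix, aligned: AlignedScore) -> GenotypeMatrix:
    """Replace missing dosages at scored variants by twice the in-sample
    effect-allele frequency (expressed on the matrix's counted allele).

    Errors if a scored variant has no observed dosage at all.
    """
    X = genotypes.dosages.copy()
    for v in aligned.used:
        j = v.genotype_column
        col = X[:, j]
        miss = np.isnan(col)
        if miss.all():
            raise ValueError(f"{v.variant_id}: all dosages missing, cannot impute")
        if miss.any():
            alt_af = (
                v.effect_allele_freq
                if v.orientation is Orientation.DIRECT
                else 1.0 - v.effect_allele_freq
            )
            col[miss] = 2.0 * alt_af
    return GenotypeMatrix(
        sample_ids=list(genotypes.sample_ids),
        variants=genotypes.variants.copy(),
        dosages=X,
        dosage_allele=genotypes.dosage_allele,
    )


@dataclass
class PRSVector:
    """Per-sample raw weighted-sum scores and the number of variants used."""

    values: pd.Series  # index: sample_id
    n_variants_used: int

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "sample_id"


def compute_prs(genotypes: GenotypeMatrix, aligned: AlignedScore) -> PRSVector:
    """PRS_j = sum_i beta_i * x_ij over the aligned, non-dropped variants.

    Flipped variants contribute beta * (2 - x).  Missing dosages must have
    been imputed first.
    """
    used = aligned.used
    cols = np.array([v.genotype_column for v in used], dtype=int)
    X = genotypes.dosages[:, cols]
    if np.isnan(X).any():
        raise ValueError("missing dosages present; run impute_missing_dosages first")
    betas = np.array([v.weight for v in used], dtype=float)
    flipped = np.array([v.orientation is Orientation.FLIPPED for v in used])
    Xeff = np.where(flipped, 2.0 - X, X)
    values = Xeff @ betas
    return PRSVector(
        values=pd.Series(values, index=pd.Index(genotypes.sample_ids, name="sample_id")),
        n_variants_used=len(used),
    )


class IncrementalR2(NamedTuple):
    r2_full: float
    r2_null: float
    incremental: float
    model_pvalue: float


def incremental_r2(
    prs: PRSVector | pd.Series,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = ("age", "sex", "bmi"),
    adjusted: bool = False,
) -> IncrementalR2:
    """Variance in LDL-C explained by the PRS beyond the covariates.

    Fits LDL-C ~ PRS + covariates and LDL-C ~ covariates by OLS on complete
    cases and returns (R²_full, R²_null, difference, Wald p of the PRS
    coefficient).  The ordinary R² is reported by default; ``adjusted=True``
    switches both models to adjusted R².
    """
    values = prs.values if isinstance(prs, PRSVector) else prs
    covariate_names = list(covariate_names)
    missing_cols = [c for c in covariate_names if c not in phenotypes.columns]
    if missing_cols:
        raise ValueError(f"covariate column(s) {missing_cols} absent from phenotypes")
    df = phenotypes.loc[:, ["ldl_c", *covariate_names]].copy()
    df["prs"] = values.reindex(df.index)
    n_before = len(df)
    df = df.dropna()
    n_drop = n_before - len(df)
    if n_drop:
        logger.info("incremental_r2: dropped %d incomplete sample(s)", n_drop)
    if len(df) < len(covariate_names) + 3:
        raise ValueError(f"too few complete cases ({len(df)}) for the model")
    y = df["ldl_c"].to_numpy()
    X_null = sm.add_constant(df[covariate_names].to_numpy()) if covariate_names else np.ones(
        (len(df), 1)
    )
    X_full = np.column_stack([X_null, df["prs"].to_numpy()])
    if np.linalg.matrix_rank(X_null) < X_null.shape[1]:
        raise ValueError("collinear covariates: null design is rank deficient")
    full = sm.OLS(y, X_full).fit()
    null = sm.OLS(y, X_null).fit()
    r2_attr = "rsquared_adj" if adjusted else "rsquared"
    r2_full = float(getattr(full, r2_attr))
    r2_null = float(getattr(null, r2_attr)) if X_null.shape[1] > 1 else 0.0
    return IncrementalR2(
        r2_full=r2_full,
        r2_null=r2_null,
        incremental=r2_full - r2_null,
        model_pvalue=float(full.pvalues[-1]),
    )


def default_threshold_grid(min_exp: float = 3.0, max_exp: float = 100.0, step: float = 1.0) -> np.ndarray:
    """Thresholds 10^-e for e from ``min_exp`` to ``max_exp`` (inclusive),
    log10-spaced with the given step."""
    exps = np.arange(min_exp, max_exp + 0.5 * step, step)
    return 10.0 ** (-exps)


@dataclass
class ThresholdScanResult:
    """Output of the p-value-threshold scan.

    ``table`` has one row per threshold: threshold, n_snps, r2_full,
    r2_null, incremental_r2, pvalue (NaN where the threshold retained no
    SNP).  ``best_threshold`` maximises incremental R²; ``best_score`` is
    the scoring file rebuilt at that threshold.
    """

    table: pd.DataFrame
    best_threshold: float
    best_score: ScoreDefinition


def score_from_sumstats(
    sumstats: pd.DataFrame, threshold: float, name: str | None = None
) -> ScoreDefinition:
    """Build a scoring file from summary statistics at p < ``threshold``:
    weights are the betas, the effect allele is ``allele_b``."""
    sel = sumstats.loc[sumstats["pvalue"] < threshold]
    variants = tuple(
        ScoreVariant(
            variant_id=r.rsid,
            chrom=str(r.chrom),
            pos=int(r.pos),
            other_allele=r.allele_a,
            effect_allele=r.allele_b,
            weight=float(r.beta),
            pvalue=float(r.pvalue),
        )
        for r in sel.itertuples()
    )
    return ScoreDefinition(name=name or f"p_lt_{threshold:g}", variants=variants)


def scan_thresholds(
    clumped_sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariate_names: Sequence[str] = ("age", "sex", "bmi"),
    grid: np.ndarray | Sequence[float] | None = None,
    palindromic_policy: str = "maf",
) -> ThresholdScanResult:
    """Scan p-value thresholds and keep the score maximising incremental R².

    At each threshold the score is rebuilt from the (clumped) summary
    statistics with p < threshold, aligned, imputed, applied, and evaluated
    by :func:`incremental_r2`.  Thresholds retaining zero SNPs are recorded
    with NaN fit statistics, never fatal.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]  # loosest first
    rows = []
    best: tuple[float, float, ScoreDefinition] | None = None
    # Alignment and PRS are monotone in the SNP set, so align once at the
    # loosest threshold and subset.
    loosest = score_from_sumstats(clumped_sumstats, grid[0])
    if loosest.n == 0:
        aligned_all = None
        imputed = None
    else:
        aligned_all = align_alleles(loosest, genotypes, palindromic_policy=palindromic_policy)
        imputed = impute_missing_dosages(genotypes, aligned_all)
        usable = {v.variant_id: v for v in aligned_all.used}
    pvals = dict(zip(clumped_sumstats["rsid"], clumped_sumstats["pvalue"]))
    for thr in grid:
        sel_ids = [r for r, p in pvals.items() if p < thr]
        n_snps = len(sel_ids)
        if n_snps == 0 or aligned_all is None:
            rows.append(
                {
                    "threshold": thr,
                    "n_snps": n_snps,
                    "r2_full": np.nan,
                    "r2_null": np.nan,
                    "incremental_r2": np.nan,
                    "pvalue": np.nan,
                }
            )
            continue
        sub = AlignedScore(
            score_name=f"p_lt_{thr:g}",
            variants=[usable[i] for i in sel_ids if i in usable],
        )
        if not sub.used:
            rows.append(
                {
                    "threshold": thr,
                    "n_snps": n_snps,
                    "r2_full": np.nan,
                    "r2_null": np.nan,
                    "incremental_r2": np.nan,
                    "pvalue": np.nan,
                }
            )
            continue
        prs = compute_prs(imputed, sub)
        fit = incremental_r2(prs, phenotypes, covariate_names)
        rows.append(
            {
                "threshold": thr,
                "n_snps": n_snps,
                "r2_full": fit.r2_full,
                "r2_null": fit.r2_null,
                "incremental_r2": fit.incremental,
                "pvalue": fit.model_pvalue,
            }
        )
        # ties prefer the more stringent threshold (fewest SNPs)
        if best is None or fit.incremental >= best[1]:
            best = (thr, fit.incremental, score_from_sumstats(clumped_sumstats, thr))
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no threshold on the grid retained any scorable SNP")
    return ThresholdScanResult(table=table, best_threshold=best[0], best_score=best[2])
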