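"""Readers and writers for the file formats the PRS pipeline consumes.

Formats (all plain text):

* summary statistics — TSV, header ``rsid chrom pos allele_a allele_b beta
  pvalue``; ``allele_b`` is the effect (trait-raising) allele.
* scoring file — TSV, header ``rsid chrom pos other_allele effect_allele
  weight [gene] [pvalue]`` (PGS-Catalog-compatible column semantics).
* genotypes — VCF v4.2+, biallelic records, plain or bgzipped; FORMAT/DS
  dosage is used when present, otherwise the ALT-allele count from GT.
* phenotypes — CSV, header ``sample_id ldl_c age sex bmi [smoker] [...]``;
  sex is accepted as {0,1} or {F,M} and normalised to 0=female, 1=male.

Coordinates are 1-based GRCh38 throughout, matching VCF convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMMARY_STAT_COLUMNS = ["rsid", "chrom", "pos", "allele_a", "allele_b", "beta", "pvalue"]
SCORE_COLUMNS = ["rsid", "chrom", "pos", "other_allele", "effect_allele", "weight"]

#: Gene labels treated as "intergenic" when counting distinct genes.
_INTERGENIC_LABELS = {"-", "—", "‒", "–", ""}
#: Versioned accessions (AC115619.1) and RNA-family ids (RF00285) are not
#: gene symbols; they are excluded from the distinct-gene count.
_ACCESSION_RE = re.compile(r"^[A-Za-z]+[0-9]+\.[0-9]+$|^RF[0-9]+$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreVariant:
    """A single scored variant: the effect allele and its per-allele weight.

    ``weight`` is the per-effect-allele effect on the trait (mmol/L per
    allele for LDL-C).  ``weight=None`` marks a structural entry whose
    weight must be supplied before scoring.  Alleles may be ``None`` only
    for such structural entries.
    """

    variant_id: str
    chrom: str
    pos: int
    other_allele: str | None
    effect_allele: str | None
    weight: float | None
    gene: str | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.weight is not None and not np.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: weight must be finite, got {self.weight}")
        if (
            self.effect_allele is not None
            and self.other_allele is not None
            and self.effect_allele == self.other_allele
        ):
            raise ValueError(
                f"{self.variant_id}: effect allele equals other allele ({self.effect_allele})"
            )
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered set of score variants, optionally with published risk cutoffs.

    ``published_cutoffs`` holds the (low/intermediate, intermediate/high)
    score boundaries on the raw weighted-sum scale, when the score ships
    with externally derived risk-class boundaries.
    """

    name: str
    variants: tuple[ScoreVariant, ...]
    published_cutoffs: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate variant ids in score '{self.name}': {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        """Per-variant weights; raises if any weight is absent."""
        self.require_weights()
        return np.array([v.weight for v in self.variants], dtype=float)

    def require_weights(self) -> None:
        missing = [v.variant_id for v in self.variants if v.weight is None]
        if missing:
            raise ValueError(
                f"score '{self.name}' has no weights for {missing}; "
                "supply a weighted scoring file before scoring"
            )

    def with_weights(self, weights: dict[str, float]) -> "ScoreDefinition":
        """Return a copy with weights filled in from ``variant_id -> weight``."""
        unknown = set(weights) - set(self.variant_ids)
        if unknown:
            raise KeyError(f"weights supplied for unknown variants: {sorted(unknown)}")
        new = tuple(
            replace(v, weight=weights.get(v.variant_id, v.weight)) for v in self.variants
        )
        return replace(self, variants=new)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x variants) for one allele per variant.

    ``dosages[i, j]`` is the expected count in [0, 2] of variant ``j``'s
    counted allele carried by sample ``i``; missing genotypes are NaN.
    ``dosage_allele`` names which of the two alleles the dosage counts
    (always ``"alt"`` for VCF input and for simulated cohorts).
    ``variants`` has columns ``id, chrom, pos, ref, alt``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    dosage_allele: str = "alt"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bool(np.any(bad)):
            raise ValueError("dosages outside [0, 2] present")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        return {vid: j for j, vid in enumerate(self.variants["id"])}

    def alt_frequency(self) -> np.ndarray:
        """In-sample ALT-allele frequency per variant (missing ignored);
        NaN for all-missing variants."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path: str | Path, p_filter: float | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics; optionally drop rows with p >= ``p_filter``.

    Returns a DataFrame with columns ``rsid chrom pos allele_a allele_b beta
    pvalue`` (``allele_b`` is the effect allele).  Rows failing the p-value
    ceiling are dropped and the drop count logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[list(df.columns)]
    for col in ("beta", "pvalue"):
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: unparseable {col} in row {bad + 2} "
                f"(rsid {df.loc[bad, 'rsid']!r}): {exc}"
            ) from None
    df["pos"] = df["pos"].astype(int)
    if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
        bad = df.loc[(df["pvalue"] <= 0) | (df["pvalue"] > 1), "rsid"].tolist()
        raise ValueError(f"{path}: p-values outside (0, 1] for {bad}")
    if (df["allele_a"] == df["allele_b"]).any():
        bad = df.loc[df["allele_a"] == df["allele_b"], "rsid"].tolist()
        raise ValueError(f"{path}: identical alleles for {bad}")
    if p_filter is not None:
        keep = df["pvalue"] < p_filter
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("read_summary_stats: dropped %d rows with p >= %g", n_drop, p_filter)
        df = df.loc[keep].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Scoring files
# ---------------------------------------------------------------------------


def read_score_definition(path: str | Path, name: str | None = None) -> ScoreDefinition:
    """Read a TSV scoring file into an ordered :class:`ScoreDefinition`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    variants = []
    for _, row in df.iterrows():
        variants.append(
            ScoreVariant(
                variant_id=row["rsid"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                other_allele=row["other_allele"],
                effect_allele=row["effect_allele"],
                weight=float(row["weight"]),
                gene=row.get("gene") if isinstance(row.get("gene"), str) else None,
                pvalue=float(row["pvalue"]) if "pvalue" in row and pd.notna(row["pvalue"]) else None,
            )
        )
    return ScoreDefinition(name=name or Path(path).stem, variants=tuple(variants))


def write_score_definition(score: ScoreDefinition, path: str | Path) -> None:
    """Write a scoring file; weights are serialized with full precision."""
    rows = []
    for v in score.variants:
        rows.append(
            {
                "rsid": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "other_allele": v.other_allele,
                "effect_allele": v.effect_allele,
                "weight": repr(v.weight) if v.weight is not None else "",
                "gene": v.gene if v.gene is not None else "",
                "pvalue": repr(v.pvalue) if v.pvalue is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: Published low/intermediate and intermediate/high boundaries for the
#: packaged 36-SNP LDL-C score, on the raw weighted-sum scale.
CANONICAL_CUTOFFS = (5.98, 6.44)


def load_canonical_36snp_score() -> ScoreDefinition:
    """The packaged 36-SNP LDL-C polygenic risk score.

    Weights are GLGC per-allele effect sizes; the effect allele is the
    LDL-C-raising allele.  Ships with the published risk-class cutoffs
    (5.98, 6.44) derived from decile categorisation in a white American
    cohort.
    """
    with resources.files("ldlprs.data").joinpath("ldl_prs_36snp.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    variants = tuple(
        ScoreVariant(
            variant_id=r.rsid,
            chrom=str(r.chrom),
            pos=int(r.pos),
            other_allele=r.other_allele,
            effect_allele=r.effect_allele,
            weight=float(r.weight),
            gene=None if r.gene in _INTERGENIC_LABELS else r.gene,
            pvalue=float(r.pvalue),
        )
        for r in df.itertuples()
    )
    return ScoreDefinition(
        name="ldl_prs_36snp", variants=variants, published_cutoffs=CANONICAL_CUTOFFS
    )


#: rsIDs of the 12-SNP LDL-C raising score used in UK clinical practice
#: (Talmud-style comparator).  Five of these overlap the 36-SNP score and
#: carry its metadata; the remainder are structural entries (no alleles,
#: no weights) pending a user-supplied weighted scoring file.
RAISING_SCORE_RSIDS = [
    "rs629301",    # CELSR2/SORT1 locus, shared with the 36-SNP score
    "rs6511720",   # LDLR, shared
    "rs1367117",   # APOB, shared
    "rs4299376",   # ABCG8, shared
    "rs2479409",   # PCSK9, shared
    "rs1564348",
    "rs1800562",
    "rs3757354",
    "rs11220462",
    "rs8017377",
    "rs429358",
    "rs7412",
]


def load_raising_score_definition() -> ScoreDefinition:
    """The 12-SNP LDL-C raising-score comparator, as a structural definition.

    Only the five variants shared with the 36-SNP score carry positions and
    alleles; no entry carries a weight (the comparator's weights are not
    packaged).  Scoring a weight-less definition raises; fill weights with
    :meth:`ScoreDefinition.with_weights` or a user scoring file first.
    """
    canonical = {v.variant_id: v for v in load_canonical_36snp_score().variants}
    variants = []
    for rsid in RAISING_SCORE_RSIDS:
        if rsid in canonical:
            variants.append(replace(canonical[rsid], weight=None))
        else:
            variants.append(
                ScoreVariant(
                    variant_id=rsid,
                    chrom="NA",
                    pos=1,
                    other_allele=None,
                    effect_allele=None,
                    weight=None,
                )
            )
    return ScoreDefinition(name="ldl_raising_12snp", variants=tuple(variants))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix` of ALT dosages.

    FORMAT/DS is used where present; otherwise the dosage is the ALT-allele
    count from GT.  Missing genotypes (``./.``) become NaN.  Multiallelic
    records are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta_rows: list[dict] = []
    dosage_rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        fmts = rec.FORMAT
        if "DS" in fmts:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            ds = np.asarray(
                [np.nan if g is None else g for g in _alt_counts(rec)], dtype=float
            )
        if np.nanmax(ds, initial=0.0) > 2 or np.nanmin(ds, initial=0.0) < 0:
            raise ValueError(f"{rec.ID or rec.POS}: dosage outside [0, 2]")
        meta_rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        dosage_rows.append(ds)
    if n_multi:
        logger.warning("read_genotypes_vcf: skipped %d multiallelic record(s)", n_multi)
    variants = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.column_stack(dosage_rows) if dosage_rows else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, dosages=dosages, dosage_allele="alt"
    )


def _alt_counts(rec) -> Iterable[float | None]:
    """ALT-allele count per sample from the genotype field (None = missing)."""
    for g in rec.genotypes:  # [allele1, allele2, ..., phased]
        alleles = g[:-1]
        if any(a < 0 for a in alleles):
            yield None
        else:
            yield float(sum(1 for a in alleles if a == 1))


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write integer/float dosages as a minimal VCF v4.2 (GT for integer calls,
    DS otherwise)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = dict.fromkeys(genotypes.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        X = genotypes.dosages
        integral = np.all(np.isnan(X) | (X == np.round(X)))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(genotypes.variants.itertuples()):
            col = X[:, j]
            if integral:
                cells = ["./." if np.isnan(x) else gt_map[int(x)] for x in col]
                fmt = "GT"
            else:
                cells = ["." if np.isnan(x) else f"{x:g}" for x in col]
                fmt = "DS"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_SEX_CODES = {"0": 0, "1": 1, "F": 0, "M": 1, "FEMALE": 0, "MALE": 1}

PHENOTYPE_REQUIRED = ["sample_id", "ldl_c", "age", "sex", "bmi"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype/covariate CSV, indexed by sample id.

    Columns: ``ldl_c`` (mmol/L), ``age`` (years), ``sex`` (0=female,
    1=male), ``bmi`` (kg/m^2), optional ``smoker`` and arbitrary extra
    covariates.  Samples with any missing required value are flagged in the
    boolean ``complete`` column rather than dropped; downstream model fits
    use complete cases only.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    sex = df["sex"].astype(str).str.strip().str.upper().map(_SEX_CODES)
    if sex.isna().any() and df["sex"].notna().any():
        bad = df.loc[sex.isna() & df["sex"].notna(), "sex"].unique().tolist()
        if bad:
            raise ValueError(f"{path}: unrecognised sex code(s) {bad}")
    df["sex"] = sex
    for col in df.columns:
        if col in ("sample_id",):
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["ldl_c"].dropna() <= 0).any():
        bad = df.loc[df["ldl_c"] <= 0, "sample_id"].tolist()
        raise ValueError(f"{path}: non-positive LDL-C for {bad}")
    df = df.set_index("sample_id")
    covar_cols = [c for c in df.columns if c != "smoker"]
    df["complete"] = df[covar_cols].notna().all(axis=1)
    n_flagged = int((~df["complete"]).sum())
    if n_flagged:
        logger.warning("read_phenotypes: %d sample(s) flagged incomplete", n_flagged)
    return df


# ---------------------------------------------------------------------------
# Score bookkeeping
# ---------------------------------------------------------------------------


def distinct_gene_count(score: ScoreDefinition) -> int:
    """Number of distinct genes the score's variants map to.

    Intergenic markers ("-", em-dash, empty) and non-symbol labels —
    versioned accessions such as ``AC115619.1`` and RNA-family ids such as
    ``RF00285`` — are excluded.  Invariant to row order and to duplicated
    labels.
    """
    labels = set()
    any_annotated = False
    for v in score.variants:
        lab = (v.gene or "").strip()
        if lab:
            any_annotated = True
        if lab in _INTERGENIC_LABELS:
            continue
        if _ACCESSION_RE.match(lab):
            continue
        labels.add(lab)
    if not any_annotated and score.n > 0:
        logger.warning("distinct_gene_count: score '%s' carries no gene labels", score.name)
    return len(labels)
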