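"""Genotype-matrix statistics: pairwise LD, greedy clumping, allele-sharing
distances and classical multidimensional scaling for ancestry covariates.

LD is always computed in-sample as the squared Pearson correlation of
dosages, with per-variant mean imputation of missing cells.  Clumping is the
standard greedy index-SNP procedure: repeatedly promote the most significant
unprocessed variant and remove its correlated same-chromosome neighbours
within a physical window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Conventional clumping window: 250 kb each side of the index SNP.
DEFAULT_WINDOW_KB = 250.0


@dataclass
class LDPairs:
    """Pairwise r² within a physical window, keyed by unordered variant-id pairs."""

    r2: dict[frozenset[str], float]
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def get(self, a: str, b: str) -> float | None:
        return self.r2.get(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self.r2)


@dataclass
class ClumpResult:
    """Index SNPs retained by clumping and, for each removed variant, the
    index SNP responsible and the offending r²."""

    retained: list[str]
    removed: dict[str, tuple[str, float]]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (m < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


@dataclass
class MDSResult:
    """Principal-coordinate embedding: sample coordinates scaled by the
    square root of each (non-negative) eigenvalue."""

    sample_ids: list[str]
    components: np.ndarray
    eigenvalues: np.ndarray


def _mean_imputed(dosages: np.ndarray) -> np.ndarray:
    """Column-mean-impute missing dosages; error on all-missing columns."""
    X = np.asarray(dosages, dtype=float).copy()
    all_missing = np.all(np.isnan(X), axis=0)
    if all_missing.any():
        raise ValueError(f"variant column(s) {np.where(all_missing)[0].tolist()} are all missing")
    col_means = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_means[idx[1]]
    return X


def pairwise_r2(genotypes: GenotypeMatrix, window_kb: float = DEFAULT_WINDOW_KB) -> LDPairs:
    """Squared Pearson correlation of dosages for every same-chromosome pair
    within ``window_kb`` (kilobases, centre to centre).

    Missing dosages are mean-imputed per variant.  Pairs where either
    variant has zero dosage variance have undefined correlation; they are
    excluded from the result and reported in ``undefined``.
    """
    if genotypes.n_variants < 2:
        raise ValueError("need at least two variants for pairwise LD")
    X = _mean_imputed(genotypes.dosages)
    sd = X.std(axis=0)
    ids = genotypes.variants["id"].to_numpy()
    chroms = genotypes.variants["chrom"].astype(str).to_numpy()
    pos = genotypes.variants["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    Xc = X - X.mean(axis=0)
    r2: dict[frozenset[str], float] = {}
    undefined: list[tuple[str, str]] = []
    n = genotypes.n_variants
    for i in range(n):
        for j in range(i + 1, n):
            if chroms[i] != chroms[j] or abs(pos[i] - pos[j]) > window_bp:
                continue
            if sd[i] == 0.0 or sd[j] == 0.0:
                undefined.append((ids[i], ids[j]))
                continue
            r = float(Xc[:, i] @ Xc[:, j]) / (len(X) * sd[i] * sd[j])
            r2[frozenset((ids[i], ids[j]))] = min(r * r, 1.0)
    if undefined:
        logger.info("pairwise_r2: %d pair(s) with zero dosage variance excluded", len(undefined))
    return LDPairs(r2=r2, undefined=undefined)


def clump(
    sumstats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> ClumpResult:
    """Greedy LD clumping of summary statistics against in-sample LD.

    Repeatedly takes the smallest-p unprocessed variant as the index SNP and
    removes every unprocessed same-chromosome variant within ``window_kb``
    whose dosage r² with the index is >= ``r2_threshold``.  Ties on p-value
    are broken by (chrom, pos, rsid) so the result is deterministic.
    Summary-stat variants absent from the genotypes are dropped with a
    warning; pairs with undefined r² (zero variance) never cause removal.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError(f"r2_threshold must be in (0, 1), got {r2_threshold}")
    vidx = genotypes.variant_index()
    present = sumstats["rsid"].isin(vidx.keys())
    n_absent = int((~present).sum())
    if n_absent:
        logger.warning("clump: %d summary-stat variant(s) absent from genotypes", n_absent)
    ss = sumstats.loc[present]
    if ss.empty:
        raise ValueError("no summary-stat variants present in the genotype matrix")

    order = ss.sort_values(
        ["pvalue", "chrom", "pos", "rsid"], kind="mergesort"
    )  # deterministic tie rule
    X = _mean_imputed(genotypes.dosages)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    chrom_of = dict(zip(genotypes.variants["id"], genotypes.variants["chrom"].astype(str)))
    pos_of = dict(zip(genotypes.variants["id"], genotypes.variants["pos"].astype(float)))
    window_bp = window_kb * 1000.0

    unprocessed = set(order["rsid"])
    retained: list[str] = []
    removed: dict[str, tuple[str, float]] = {}
    for rsid in order["rsid"]:
        if rsid not in unprocessed:
            continue
        unprocessed.discard(rsid)
        retained.append(rsid)
        i = vidx[rsid]
        if sd[i] == 0.0:
            continue
        for other in list(unprocessed):
            if chrom_of[other] != chrom_of[rsid]:
                continue
            if abs(pos_of[other] - pos_of[rsid]) > window_bp:
                continue
            j = vidx[other]
            if sd[j] == 0.0:
                continue
            r = float(Xc[:, i] @ Xc[:, j]) / (len(X) * sd[i] * sd[j])
            if r * r >= r2_threshold:
                unprocessed.discard(other)
                removed[other] = (rsid, min(r * r, 1.0))
    return ClumpResult(retained=retained, removed=removed)


def ibs_distance(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing (identity-by-state) distance between all sample pairs.

    d(i, j) = mean over variants non-missing in both samples of
    |x_i - x_j| / 2, hence in [0, 1].  Errors if some pair shares no
    non-missing variant.
    """
    if genotypes.n_samples < 2:
        raise ValueError("need at least two samples")
    X = genotypes.dosages
    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X, nan=0.0)
    # |xi - xj| for dosages in {0,1,2} decomposes over value-indicator
    # matmuls; fractional dosages fall back to the direct loop.
    n_shared = obs.astype(float) @ obs.astype(float).T
    if np.any(n_shared == 0):
        raise ValueError("some sample pair shares no non-missing variants")
    vals = np.unique(Xz[obs])
    if np.allclose(vals, np.round(vals)):
        acc = np.zeros((genotypes.n_samples, genotypes.n_samples))
        ind = {v: ((Xz == v) & obs).astype(float) for v in (0.0, 1.0, 2.0)}
        for u in (0.0, 1.0, 2.0):
            for v in (0.0, 1.0, 2.0):
                w = abs(u - v)
                if w:
                    acc += w * (ind[u] @ ind[v].T)
        D = acc / (2.0 * n_shared)
    else:
        n = genotypes.n_samples
        D = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(X[i] - X[i + 1 :])
            with np.errstate(invalid="ignore"):
                D[i, i + 1 :] = np.nanmean(diff / 2.0, axis=1)
        D = D + D.T
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(sample_ids=list(genotypes.sample_ids), matrix=D)


def classical_mds(distance: DistanceMatrix, k: int) -> MDSResult:
    """Torgerson principal-coordinates analysis of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and returns the
    top-``k`` coordinates scaled by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean input) are truncated to zero with a warning.  Component
    signs are fixed by forcing the largest-magnitude loading positive.
    """
    n = len(distance.sample_ids)
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n_samples ({n}), got {k}")
    D2 = distance.matrix**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    if n > 2000:
        from scipy.sparse.linalg import eigsh

        eigvals, eigvecs = eigsh(B, k=k, which="LA")
        order = np.argsort(eigvals)[::-1]
    else:
        eigvals, eigvecs = scipy.linalg.eigh(B)
        order = np.argsort(eigvals)[::-1][:k]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if (eigvals < -1e-9 * max(1.0, abs(eigvals[0]))).any():
        logger.warning("classical_mds: negative eigenvalue(s) truncated to zero")
    eigvals = np.clip(eigvals, 0.0, None)
    comps = eigvecs * np.sqrt(eigvals)
    for c in range(comps.shape[1]):
        if comps[:, c].any():
            imax = np.argmax(np.abs(comps[:, c]))
            if comps[imax, c] < 0:
                comps[:, c] = -comps[:, c]
    return MDSResult(
        sample_ids=list(distance.sample_ids), components=comps, eigenvalues=eigvals
    )


def mds_covariates(genotypes: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """First ``k`` MDS components of the IBS distance, as covariate columns
    ``mds1..mdsk`` indexed by sample id."""
    res = classical_mds(ibs_distance(genotypes), k=k)
    return pd.DataFrame(
        res.components,
        index=pd.Index(res.sample_ids, name="sample_id"),
        columns=[f"mds{i + 1}" for i in range(k)],
    )
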