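"""Risk stratification and score-vs-score comparison statistics.

The score distribution is cut into low / intermediate / high classes at
decile boundaries (bottom three deciles low, next three intermediate, top
four high by default).  The cutoffs are plain score values, so boundaries
learned in one cohort transfer unchanged to another — the mechanism behind
cross-cohort risk-class replication.

Phenotype classes follow clinical LDL-C bands: severe hypercholesterolemia
above 4.9 mmol/L, intermediate between 3.0 and 4.9 inclusive, normal below
3.0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RISK_CLASSES = ["low", "intermediate", "high"]
PHENO_CLASSES = ["normal", "intermediate_HC", "severe_HC"]

#: LDL-C bands (mmol/L): severe HC strictly above the upper bound,
#: normal strictly below the lower bound.
LDL_SEVERE_THRESHOLD = 4.9
LDL_NORMAL_THRESHOLD = 3.0

DEFAULT_FRACTIONS = (0.3, 0.3, 0.4)


def categorize_phenotype(phenotypes: pd.DataFrame | pd.Series) -> pd.Series:
    """Assign clinical LDL-C classes: > 4.9 severe_HC, [3.0, 4.9]
    intermediate_HC, < 3.0 normal.  Missing LDL-C stays unclassified (NaN)
    with a logged count."""
    ldl = phenotypes["ldl_c"] if isinstance(phenotypes, pd.DataFrame) else phenotypes
    out = pd.Series(pd.NA, index=ldl.index, dtype="object")
    out[ldl > LDL_SEVERE_THRESHOLD] = "severe_HC"
    out[(ldl >= LDL_NORMAL_THRESHOLD) & (ldl <= LDL_SEVERE_THRESHOLD)] = "intermediate_HC"
    out[ldl < LDL_NORMAL_THRESHOLD] = "normal"
    n_missing = int(ldl.isna().sum())
    if n_missing:
        logger.warning("categorize_phenotype: %d sample(s) without LDL-C left unclassified", n_missing)
    return out


@dataclass(frozen=True)
class RiskCutoffs:
    """Transferable low/intermediate and intermediate/high score boundaries."""

    c_low: float
    c_high: float
    provenance: str = "computed-on-cohort"

    def __post_init__(self) -> None:
        if self.c_low > self.c_high:
            raise ValueError(f"c_low ({self.c_low}) exceeds c_high ({self.c_high})")


def write_cutoffs(cutoffs: RiskCutoffs, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# provenance: {cutoffs.provenance}\n")
        fh.write("c_low\tc_high\n")
        fh.write(f"{cutoffs.c_low!r}\t{cutoffs.c_high!r}\n")


def read_cutoffs(path: str | Path) -> RiskCutoffs:
    provenance = "published"
    with Path(path).open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for ln in lines:
        if ln.startswith("# provenance:"):
            provenance = ln.split(":", 1)[1].strip()
    data = [ln for ln in lines if not ln.startswith("#")]
    vals = data[1].split("\t")
    return RiskCutoffs(c_low=float(vals[0]), c_high=float(vals[1]), provenance=provenance)


def decile_cutoffs(
    prs: pd.Series | np.ndarray, fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
) -> RiskCutoffs:
    """Empirical risk-class boundaries from the score distribution.

    With fractions (f1, f2, f3), c_low is the floor(f1*n)-th smallest score
    and c_high the floor((f1+f2)*n)-th smallest, so on all-distinct scores
    the low class holds exactly floor(f1*n) samples (ties share the lower
    class).  The default (0.3, 0.3, 0.4) puts deciles 1-3 low, 4-6
    intermediate, 7-10 high.
    """
    values = np.asarray(prs.values if isinstance(prs, pd.Series) else prs, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n < 10:
        raise ValueError(f"need at least 10 scores for decile cutoffs, got {n}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9) or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    if np.all(values == values[0]):
        raise ValueError("all scores identical; quantile cutoffs are degenerate")
    s = np.sort(values)
    k_low = int(np.floor(fractions[0] * n))
    k_high = int(np.floor((fractions[0] + fractions[1]) * n))
    k_low = max(k_low, 1)
    k_high = max(k_high, k_low)
    return RiskCutoffs(c_low=float(s[k_low - 1]), c_high=float(s[k_high - 1]))


def assign_risk_class(prs: pd.Series | np.ndarray, cutoffs: RiskCutoffs) -> pd.Series:
    """score <= c_low -> low; c_low < score <= c_high -> intermediate;
    score > c_high -> high."""
    if not (np.isfinite(cutoffs.c_low) and np.isfinite(cutoffs.c_high)):
        raise ValueError("cutoffs must be finite")
    values = prs if isinstance(prs, pd.Series) else pd.Series(np.asarray(prs, dtype=float))
    out = pd.Series("intermediate", index=values.index, dtype="object")
    out[values <= cutoffs.c_low] = "low"
    out[values > cutoffs.c_high] = "high"
    out[values.isna()] = pd.NA
    return out


class RiskRatioResult(NamedTuple):
    rr: float
    ci_low: float
    ci_high: float
    events_high: int
    n_high: int
    events_low: int
    n_low: int
    pvalue: float


def risk_ratio(
    events_high: int, n_high: int, events_low: int, n_low: int, z: float = 1.96
) -> RiskRatioResult:
    """Risk ratio of the outcome in the high- vs low-risk class.

    The 95% CI is the Katz log-normal interval and the two-sided p comes
    from the log-RR z statistic.  When either event cell is zero, 0.5 is
    added to all four cells (continuity correction).
    """
    if events_high > n_high or events_low > n_low:
        raise ValueError("event count exceeds group size")
    if n_high < 1 or n_low < 1:
        raise ValueError("both groups must be non-empty")
    a, n1, c, n0 = float(events_high), float(n_high), float(events_low), float(n_low)
    if a == 0 or c == 0:
        a, n1, c, n0 = a + 0.5, n1 + 0.5, c + 0.5, n0 + 0.5
    rr = (a / n1) / (c / n0)
    se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    log_rr = math.log(rr)
    ci_low = math.exp(log_rr - z * se)
    ci_high = math.exp(log_rr + z * se)
    p = 2.0 * stats.norm.sf(abs(log_rr) / se) if se > 0 else 1.0
    return RiskRatioResult(
        rr=rr,
        ci_low=ci_low,
        ci_high=ci_high,
        events_high=events_high,
        n_high=n_high,
        events_low=events_low,
        n_low=n_low,
        pvalue=float(p),
    )


def wilcoxon_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a location difference.

    Returns (W, p) where W is the rank-sum of ``group_a`` in the pooled
    sample.  Exact enumeration of all rank assignments when both groups
    have at most 8 observations; tie-corrected normal approximation (via
    Mann-Whitney U) otherwise.  If every value is identical the test is
    uninformative and p = 1 is returned with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    w_obs = float(ranks[:na].sum())
    if np.all(pooled == pooled[0]):
        logger.warning("wilcoxon_test: all values identical; test uninformative")
        return w_obs, 1.0
    if na <= 8 and len(b) <= 8:
        mean_w = na * (n + 1) / 2.0
        dev = abs(w_obs - mean_w)
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), na):
            w = ranks[list(comb)].sum()
            if abs(w - mean_w) >= dev - 1e-9:
                count += 1
            total += 1
        return w_obs, count / total
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return w_obs, float(p)


def roc_auc(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    """Area under the ROC curve: the probability a random positive outranks
    a random negative, with half credit for ties (Mann-Whitney identity)."""
    y = np.asarray(binary_labels, dtype=int)
    x = np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("both label classes must be present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, x))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (per-positive and per-negative
    placement values)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if equal, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], binary_labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """DeLong test for two correlated (paired) ROC curves.

    Returns (auc_a, auc_b, z, p) with a two-sided p.  The covariance of the
    paired AUCs is estimated from the structural components, so the
    correlation induced by scoring the same samples is accounted for.
    Identical score vectors give z = 0, p = 1.
    """
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if not (len(xa) == len(xb) == len(y)):
        raise ValueError("paired scores and labels must have equal length")
    if len(set(y)) < 2:
        raise ValueError("both label classes must be present")
    auc_a, v10_a, v01_a = _placements(xa, y)
    auc_b, v10_b, v01_b = _placements(xb, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate AUC variance with unequal AUCs")
    zstat = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zstat))
    return auc_a, auc_b, float(zstat), float(p)


def delong_variance(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    """DeLong variance of a single AUC (structural components)."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    _, v10, v01 = _placements(x, y)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


@dataclass
class ReclassTable:
    """3x3 cross-tabulation of risk classes under two scores.

    Rows are classes under score A, columns under score B; marginals equal
    the per-score class counts on the shared sample set.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(
            index=RISK_CLASSES, columns=RISK_CLASSES, fill_value=0
        ).astype(int)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def moved_up(self, from_class: str) -> int:
        i = RISK_CLASSES.index(from_class)
        return int(self.counts.iloc[i, i + 1 :].sum())

    def moved_down(self, from_class: str) -> int:
        i = RISK_CLASSES.index(from_class)
        return int(self.counts.iloc[i, :i].sum())

    def row_total(self, from_class: str) -> int:
        return int(self.counts.loc[from_class].sum())


def reclassification_table(
    classes_a: pd.Series, classes_b: pd.Series, subset: pd.Index | Sequence[str] | None = None
) -> ReclassTable:
    """Cross-tabulate risk classes under score A (rows) and score B
    (columns) on the shared (optionally filtered) sample set."""
    idx = classes_a.index
    if not idx.sort_values().equals(classes_b.index.sort_values()):
        raise ValueError("class vectors cover different sample sets")
    if subset is not None:
        idx = pd.Index(subset)
        missing = idx.difference(classes_a.index)
        if len(missing):
            raise ValueError(f"subset sample(s) absent from class vectors: {list(missing)[:5]}")
    a = classes_a.loc[idx]
    b = classes_b.loc[idx]
    counts = pd.crosstab(a, b).reindex(index=RISK_CLASSES, columns=RISK_CLASSES, fill_value=0)
    return ReclassTable(counts=counts)


def reclassification_summary(
    tables: ReclassTable | Sequence[ReclassTable], from_class: str = "low"
) -> float:
    """Fraction of ``from_class`` samples (under score A) assigned a higher
    class by score B.  Multiple tables are pooled: numerators and
    denominators are summed before dividing."""
    if isinstance(tables, ReclassTable):
        tables = [tables]
    moved = sum(t.moved_up(from_class) for t in tables)
    total = sum(t.row_total(from_class) for t in tables)
    if total == 0:
        raise ValueError(f"no samples in class {from_class!r}")
    return moved / total


def concordance_fraction(
    classes_a: pd.Series, classes_b: pd.Series, subset: pd.Index | Sequence[str] | None = None
) -> float:
    """Fraction of samples placed in the high class by both scores or the
    low class by both scores (intermediate agreement does not count)."""
    table = reclassification_table(classes_a, classes_b, subset=subset)
    if table.n == 0:
        raise ValueError("empty subset")
    both = table.counts.loc["high", "high"] + table.counts.loc["low", "low"]
    return both / table.n


def as_percent(fraction: float) -> int:
    """Round a fraction to an integer percent, half away from zero."""
    return int(math.floor(fraction * 100.0 + 0.5))
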