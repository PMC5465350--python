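"""Class-comparison statistics: Pearson on averages, Mann-Whitney on scores,
gene assignment and Fisher's exact test on regulatory-association proportions.

All reported P values are two-tailed and uncorrected; an optional
Benjamini-Hochberg adjustment can be applied to a result table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import AlignmentConfig
from .shapes import FEATURES

logger = logging.getLogger(__name__)

__all__ = ["ClassComparison", "compare_class_averages", "compare_score_distributions",
           "assign_genes", "association_enrichment", "fisher_exact_2x2",
           "benjamini_hochberg"]


@dataclass(frozen=True)
class ClassComparison:
    class_a: str
    class_b: str
    statistic_name: str
    statistic: float
    pvalue: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0 <= self.pvalue <= 1:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def _standardized_flat(avg: np.ndarray, keep: np.ndarray) -> np.ndarray:
    values = np.asarray(avg, dtype=float)[:, keep]
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    values = np.divide(values - mean, sd, out=np.zeros_like(values), where=sd > 0)
    return values.reshape(-1)


def _average_keep_mask(width: int, config: AlignmentConfig) -> np.ndarray:
    keep = np.ones(width, dtype=bool)
    e = config.center_exclusion // 2
    center = config.half
    keep[center - e:center + e + 1] = False
    return keep


def compare_class_averages(
    avg_a: np.ndarray,
    avg_b: np.ndarray,
    class_a: str = "a",
    class_b: str = "b",
    config: AlignmentConfig | None = None,
    per_feature: bool = False,
):
    """Pearson correlation of two class-average feature matrices.

    Both (4, W) averages are restricted to the alignment interval's
    non-excluded positions, z-standardized per feature, flattened and
    correlated without any relative shifting; the two-tailed P value comes
    from the t distribution with n - 2 degrees of freedom.  Constant input
    leaves r undefined (NaN), reported as such.  With ``per_feature`` a
    list of four single-feature comparisons is returned instead.
    """
    config = config or AlignmentConfig()
    avg_a = np.asarray(avg_a, dtype=float)
    avg_b = np.asarray(avg_b, dtype=float)
    if avg_a.shape != avg_b.shape:
        raise ValueError("class averages must share the same (feature, position) grid")
    keep = _average_keep_mask(avg_a.shape[1], config)

    def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if x.std() == 0 or y.std() == 0:
            logger.warning("constant input to Pearson comparison: r undefined")
            return float("nan"), float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = sps.pearsonr(x, y)
        return float(r), float(p)

    if per_feature:
        out = []
        for f, feat in enumerate(FEATURES):
            r, p = _pearson(avg_a[f, keep], avg_b[f, keep])
            out.append(ClassComparison(class_a, class_b, f"pearson_r[{feat}]", r, p))
        return out
    r, p = _pearson(_standardized_flat(avg_a, keep), _standardized_flat(avg_b, keep))
    return ClassComparison(class_a, class_b, "pearson_r", r, p,
                           extras={"n": int(keep.sum() * avg_a.shape[0])})


def compare_score_distributions(
    scores_a, scores_b, class_a: str = "a", class_b: str = "b",
    exact_max_n: int = 8,
) -> ClassComparison:
    """Two-sided Mann-Whitney U comparison of two score distributions.

    Uses exact enumeration when both samples have at most ``exact_max_n``
    observations and no ties, otherwise the tie-corrected normal
    approximation with continuity correction.  Fully tied data yields
    U = n_a * n_b / 2 and p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each class needs at least one score")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return ClassComparison(class_a, class_b, "mannwhitney_U",
                               len(a) * len(b) / 2.0, 1.0,
                               extras={"n_a": len(a), "n_b": len(b), "method": "degenerate"})
    has_ties = np.unique(pooled).size < len(pooled)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return ClassComparison(class_a, class_b, "mannwhitney_U",
                           float(res.statistic), float(min(res.pvalue, 1.0)),
                           extras={"n_a": len(a), "n_b": len(b), "method": method})


def assign_genes(
    sites,
    genes: pd.DataFrame,
    max_distance: int = 1000,
    tss_only: bool = False,
) -> pd.DataFrame:
    """Map each site to its closest gene within ``max_distance`` bp.

    Distance runs from the peak maximum to the nearest gene boundary (0
    inside the gene body), or to the TSS alone when ``tss_only`` is set
    (the start for ``+`` strand genes, the last base for ``-``).  Ties
    break toward the leftmost gene start.  Sites with no gene within range
    get a null assignment.
    """
    if genes.empty:
        logger.warning("empty gene annotation: no site receives a gene")
        return pd.DataFrame(
            [(s.site_id, s.class_label, None, np.nan) for s in sites],
            columns=["site_id", "class_label", "gene_id", "distance"])
    rows = []
    by_chrom = {str(c): sub.reset_index(drop=True) for c, sub in genes.groupby("chrom")}
    for site in sites:
        sub = by_chrom.get(site.chrom)
        if sub is None:
            rows.append((site.site_id, site.class_label, None, np.nan))
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        p = site.peak_max
        if tss_only:
            strand = sub["strand"].to_numpy() if "strand" in sub else np.full(len(sub), "+")
            tss = np.where(strand == "-", end - 1, start)
            dist = np.abs(p - tss)
        else:
            dist = np.where(p < start, start - p, np.where(p >= end, p - (end - 1), 0))
        order = np.lexsort((start, dist))
        best = order[0]
        if dist[best] <= max_distance:
            rows.append((site.site_id, site.class_label,
                         str(sub["gene_id"].iloc[best]), float(dist[best])))
        else:
            rows.append((site.site_id, site.class_label, None, np.nan))
    return pd.DataFrame(rows, columns=["site_id", "class_label", "gene_id", "distance"])


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds ratio, p)."""
    odds, p = sps.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(odds), float(p)


def association_enrichment(
    assignments: pd.DataFrame,
    table: pd.DataFrame,
    tf: str,
    test_classes=("fast", "slow"),
    control_classes=("free_mnase", "random"),
    evidence: str = "pooled",
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Fisher's exact comparison of regulatory-association proportions.

    For every class the proportion of gene-assigned sites whose gene has a
    documented-or-proposed association with ``tf`` is computed (``evidence``
    may restrict to ``"documented"`` or ``"proposed"``); each test class is
    compared against each control class on the 2x2 associated/not table.
    Rows flag comparisons with p below ``alpha`` (0.1 by default).
    """
    if evidence == "pooled":
        relevant = table[table["tf"] == tf]
    else:
        relevant = table[(table["tf"] == tf) & (table["evidence"] == evidence)]
    associated_genes = set(relevant["gene_id"])
    assigned = assignments.dropna(subset=["gene_id"])
    counts: dict[str, tuple[int, int]] = {}
    for class_label, sub in assigned.groupby("class_label"):
        hits = int(sub["gene_id"].isin(associated_genes).sum())
        counts[str(class_label)] = (hits, len(sub))
    rows = []
    for test in test_classes:
        if test not in counts:
            logger.warning("class %s has no assigned genes; comparisons skipped", test)
            continue
        for control in control_classes:
            if control not in counts:
                logger.warning("class %s has no assigned genes; comparisons skipped", control)
                continue
            a_hit, a_n = counts[test]
            b_hit, b_n = counts[control]
            odds, p = fisher_exact_2x2([[a_hit, a_n - a_hit], [b_hit, b_n - b_hit]])
            rows.append((test, control, a_hit, a_n, a_hit / a_n, b_hit, b_n, b_hit / b_n,
                         odds, p, p < alpha))
    return pd.DataFrame(rows, columns=[
        "test_class", "control_class", "test_associated", "test_total", "test_proportion",
        "control_associated", "control_total", "control_proportion",
        "odds_ratio", "pvalue", "significant"])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
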