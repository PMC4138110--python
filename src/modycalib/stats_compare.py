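"""Inter-method and inter-gene statistics.

Three report shapes: a Spearman rank-correlation matrix between methods
(computed on disease-label records, pairwise-complete), per-gene descriptive
matrices with a one-way ANOVA across genes, and a pairwise method comparison
by the average difference of gene-level MCCs with a paired t-test.

The paired t-test across gene-level MCCs treats genes as the pairing unit;
with 7 calibrated genes that is 6 degrees of freedom, so these p-values are
coarse and no multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationCell",
    "GeneStats",
    "MCCComparisonCell",
    "spearman_matrix",
    "gene_descriptives",
    "anova_across_genes",
    "mcc_pairwise_comparison",
]


@dataclass(frozen=True)
class CorrelationCell:
    method_a: str
    method_b: str
    rho: float
    p: float
    n_pairs: int
    insufficient: bool = False


@dataclass(frozen=True)
class GeneStats:
    """Descriptives for one (gene, method) cell: mean+/-SD, N, five-number."""

    gene: str
    method: str
    mean: float
    sd: float  # NaN when n == 1 (sample SD undefined)
    n: int
    max: float
    q75: float
    median: float
    q25: float
    min: float


@dataclass(frozen=True)
class MCCComparisonCell:
    method_a: str
    method_b: str
    avg_diff: float  # mean over shared genes of MCC_b - MCC_a
    p: float
    n_genes: int
    degenerate: bool = False  # zero-variance differences


def spearman_matrix(score_matrix: pd.DataFrame, min_pairs: int = 3
                    ) -> dict[tuple[str, str], CorrelationCell]:
    """Pairwise Spearman's rho with two-sided p for every method pair.

    Pairwise-complete cases, average ranks for ties, p from the large-sample
    t approximation.  Cells with fewer than ``min_pairs`` complete
    observations are flagged insufficient (rho/p NaN).  Returns both
    orientations plus unit diagonal cells.
    """
    methods = list(score_matrix.columns)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    out: dict[tuple[str, str], CorrelationCell] = {}
    for m in methods:
        n = int(score_matrix[m].notna().sum())
        out[(m, m)] = CorrelationCell(m, m, 1.0, 0.0, n)
    for a, b in itertools.combinations(methods, 2):
        xa = score_matrix[a].to_numpy(dtype=float)
        xb = score_matrix[b].to_numpy(dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        n = int(ok.sum())
        if n < min_pairs:
            cell = CorrelationCell(a, b, math.nan, math.nan, n, True)
        else:
            rho, p = stats.spearmanr(xa[ok], xb[ok])
            cell = CorrelationCell(a, b, float(rho), float(p), n)
        out[(a, b)] = cell
        out[(b, a)] = CorrelationCell(b, a, cell.rho, cell.p, n,
                                      cell.insufficient)
    return out


def gene_descriptives(score_matrix: pd.DataFrame, genes: pd.Series
                      ) -> list[GeneStats]:
    """Per-(gene, method) mean, sample SD, N and five-number summary.

    Sample SD uses the n-1 denominator and is NaN for singleton cells;
    quantiles use linear interpolation between order statistics.  Empty
    cells are not emitted.
    """
    out: list[GeneStats] = []
    g = np.asarray(genes)
    for gene in pd.unique(g):
        mask = g == gene
        for m in score_matrix.columns:
            v = score_matrix.loc[mask, m].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if v.size == 0:
                continue
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            out.append(GeneStats(
                gene=str(gene), method=str(m),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else math.nan,
                n=int(v.size),
                max=float(v.max()), q75=float(q75), median=float(med),
                q25=float(q25), min=float(v.min()),
            ))
    return out


def anova_across_genes(score_matrix: pd.DataFrame, genes: pd.Series,
                       method: str) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of one method's scores grouped by gene.

    Returns (F, p).  Requires >=2 genes with >=2 scored observations each.
    """
    g = np.asarray(genes)
    groups = []
    for gene in pd.unique(g):
        v = score_matrix.loc[g == gene, method].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size >= 2:
            groups.append(v)
    if len(groups) < 2:
        raise ValueError(
            f"{method}: ANOVA needs >=2 genes with >=2 scored values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # no variance at all: F defined as 0 by convention
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def mcc_pairwise_comparison(gene_mccs: pd.DataFrame
                            ) -> dict[tuple[str, str], MCCComparisonCell]:
    """Pairwise average MCC differences with paired two-sided t-tests.

    ``gene_mccs`` is a (genes x methods) frame of gene-level MCCs (NaN for
    uncalibrated cells).  For each ordered pair (a, b) the cell holds the
    mean over shared genes of MCC_b - MCC_a, so avg_diff(a,b) =
    -avg_diff(b,a).  Zero-variance differences report p = 1.0 with a
    degeneracy flag; pairs sharing fewer than 2 genes are flagged with NaN.
    """
    methods = list(gene_mccs.columns)
    out: dict[tuple[str, str], MCCComparisonCell] = {}
    for a, b in itertools.combinations(methods, 2):
        xa = gene_mccs[a].to_numpy(dtype=float)
        xb = gene_mccs[b].to_numpy(dtype=float)
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        n = int(ok.sum())
        if n < 2:
            cell = MCCComparisonCell(a, b, math.nan, math.nan, n, True)
        else:
            d = xb[ok] - xa[ok]
            avg = float(d.mean())
            if np.ptp(d) <= 1e-12:  # constant up to float noise
                # constant differences: zero variance, paired t degenerate
                cell = MCCComparisonCell(a, b, avg, 1.0 if avg == 0 else 0.0,
                                         n, True)
            else:
                _, p = stats.ttest_rel(xb[ok], xa[ok])
                cell = MCCComparisonCell(a, b, avg, float(p), n)
        out[(a, b)] = cell
        out[(b, a)] = MCCComparisonCell(b, a, -cell.avg_diff, cell.p,
                                        cell.n_genes, cell.degenerate)
    return out
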