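"""Validation of PRE scores against cell-sorted expression.

Counts are normalized by median-of-ratios: each gene's reference is its
geometric mean across samples (over genes with all-positive counts), each
sample's size factor is the median of its count/reference ratios, and
normalized counts are raw counts divided by the size factor. Per-bucket
expression is the mean normalized count over that bucket's samples.

The validation statistic is the Pearson correlation between a bucket's
gene-level PRE and a bucket's expression on their gene overlap, computed for
every (PRE bucket, expression bucket) pair. A matched pair (same cell type on
both axes) showing the highest correlation in its row/column is the expected
signature of cell-specific regulatory scoring. Significance is assessed by
permuting gene labels of the expression vector (two-sided on |r|, add-one
empirical p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def median_of_ratios(counts: pd.DataFrame, pseudocount: float = 0.0):
    """Median-of-ratios normalization of a gene x sample count matrix.

    Returns ``(normalized, size_factors)``. Requires at least one gene with
    positive counts in every sample (the reference set); otherwise raises
    with a hint to use ``pseudocount``.
    """
    mat = counts.to_numpy(dtype=float) + pseudocount
    if (mat < 0).any():
        raise ValueError("median_of_ratios: negative counts")
    if mat.shape[1] == 1:
        return counts.astype(float), pd.Series([1.0], index=counts.columns, name="size_factor")
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "median_of_ratios: no gene has positive counts in every sample; "
            "consider pseudocount > 0"
        )
    ref = np.exp(np.log(mat[all_positive]).mean(axis=1))
    ratios = mat[all_positive] / ref[:, None]
    factors = np.median(ratios, axis=0)
    normalized = counts.astype(float) / factors
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    logger.info(
        "median_of_ratios: %d/%d reference genes, size factors %.3g..%.3g",
        int(all_positive.sum()),
        mat.shape[0],
        factors.min(),
        factors.max(),
    )
    return normalized, size_factors


def bucket_expression(normalized: pd.DataFrame, sample_buckets: Mapping[str, str]) -> pd.DataFrame:
    """Mean normalized expression per gene per bucket, given a sample ->
    bucket labelling."""
    labels = pd.Series({s: sample_buckets[s] for s in normalized.columns})
    return normalized.T.groupby(labels).mean().T


@dataclass
class CorrelationReport:
    pre_bucket: str
    expression_bucket: str
    r: float
    p_perm: float
    n_genes: int
    n_perm: int
    seed: int | None = None


def correlate(
    pre: pd.Series,
    expr: pd.Series,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    log_expression: bool = False,
    pre_bucket: str = "",
    expression_bucket: str = "",
) -> CorrelationReport:
    """Pearson correlation between gene-level PRE and expression on their
    gene overlap, with a gene-label permutation p-value (two-sided on |r|).
    """
    genes = pre.index.intersection(expr.index)
    if len(genes) < 3:
        raise ValueError(f"correlate: only {len(genes)} overlapping genes (need >= 3)")
    x = pre.loc[genes].to_numpy(dtype=float)
    y = expr.loc[genes].to_numpy(dtype=float)
    if log_expression:
        y = np.log1p(y)
    r = float(stats.pearsonr(x, y).statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.dot(xc, rng.permutation(yc)) / denom
    p_perm = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
    return CorrelationReport(
        pre_bucket=pre_bucket,
        expression_bucket=expression_bucket,
        r=r,
        p_perm=p_perm,
        n_genes=int(len(genes)),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )


def correlation_grid(
    pre_wide: pd.DataFrame,
    expr_by_bucket: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    log_expression: bool = False,
) -> pd.DataFrame:
    """All (PRE bucket x expression bucket) correlations in one long table.

    ``pre_wide`` is a gene x bucket PRE matrix (see
    :func:`prenet.pre_scoring.gene_pre_wide`), ``expr_by_bucket`` a gene x
    bucket expression matrix. Matched and mismatched pairs are all computed;
    the highest-r pair per expression bucket is the one the scoring claims.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for pb in pre_wide.columns:
        for eb in expr_by_bucket.columns:
            report = correlate(
                pre_wide[pb],
                expr_by_bucket[eb],
                n_perm=n_perm,
                seed=rng,
                log_expression=log_expression,
                pre_bucket=str(pb),
                expression_bucket=str(eb),
            )
            rows.append(
                {
                    "pre_bucket": pb,
                    "expression_bucket": eb,
                    "matched": pb == eb,
                    "r": report.r,
                    "p_perm": report.p_perm,
                    "n_genes": report.n_genes,
                }
            )
    return pd.DataFrame(rows)
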