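"""Predicted Regulatory Effect (PRE) scoring.

Each regulatory-evidence row gets a signed, normalized *weighted weight*

    WW = sign(class) * n_experiments / total_experiments(bucket)

with sign +1 for PEX (promoter/enhancer/transcription-activating), -1 for R
(repressive) and 0 for ZQI (inert/quiescent). Normalizing by the bucket's
total experiment count removes bias in favour of well-studied cell types.
Weighted weights are summed across all SNPs of an associated region (leads
plus LD proxies), giving the PRE score per gene, per region, per cell bucket:

    PRE(g, r, b) = sum over SNPs s in region r, features f of s targeting g
                   in bucket b of  d(s) * WW(f)

where d(s) is the subject's risk-allele dosage at s (d = 1 everywhere for the
population-level score, so the individual score with all-ones dosage equals
the population score exactly). A positive PRE means the associated region is
predicted to promote the gene's transcription in that cell type; negative
means repression.

eQTL records are integrated as pseudo-features with one supporting experiment
and sign equal to the risk-allele effect direction; they participate in the
bucket totals like any other evidence row.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_SIGN = {"PEX": 1.0, "ZQI": 0.0, "R": -1.0}

PRE_COLUMNS = ["target_gene", "region_id", "bucket", "pre"]


def eqtl_pseudo_features(eqtl: pd.DataFrame) -> pd.DataFrame:
    """Embed eQTL records as catalogue rows: class PEX for a positive
    risk-allele effect on expression, R for negative, n_experiments = 1."""
    return pd.DataFrame(
        {
            "snp_id": eqtl["snp_id"].astype(str),
            "feature_id": "eqtl:" + eqtl["snp_id"].astype(str) + ":" + eqtl["target_gene"].astype(str),
            "feature_type": "eQTL",
            "reg_class": np.where(eqtl["effect_sign"] > 0, "PEX", "R"),
            "cell_raw": "eQTL",
            "bucket": eqtl["bucket"].astype(str),
            "n_experiments": 1,
            "target_gene": eqtl["target_gene"].astype(str),
        }
    )


def merge_eqtl(catalogue: pd.DataFrame, eqtl: pd.DataFrame | None) -> pd.DataFrame:
    if eqtl is None or len(eqtl) == 0:
        return catalogue
    return pd.concat([catalogue, eqtl_pseudo_features(eqtl)], ignore_index=True)


def bucket_totals(
    catalogue: pd.DataFrame,
    eqtl: pd.DataFrame | None = None,
    include_zqi: bool = True,
) -> dict[str, float]:
    """Total experiment count per bucket, the WW normalization denominator.

    ZQI rows carry zero weight but count toward the denominator by default
    ("total number of experiments conducted"); set ``include_zqi=False`` to
    restrict the denominator to signed (PEX/R) evidence.
    """
    cat = merge_eqtl(catalogue, eqtl)
    if len(cat) == 0:
        raise ValueError("bucket_totals: empty catalogue")
    if not include_zqi:
        cat = cat[cat["reg_class"] != "ZQI"]
    totals = cat.groupby("bucket")["n_experiments"].sum().astype(float).to_dict()
    return totals


def compute_ww(reg_class: str, n_experiments: int, bucket: str, totals: Mapping[str, float]) -> float:
    """Weighted weight of one evidence row: sign(class) * n / bucket total."""
    if bucket not in totals:
        raise KeyError(f"bucket {bucket!r} has no experiment total")
    total = totals[bucket]
    if total <= 0:
        raise ZeroDivisionError(f"bucket {bucket!r} total is {total}")
    return CLASS_SIGN[reg_class] * float(n_experiments) / float(total)


def _ww_column(cat: pd.DataFrame, totals: Mapping[str, float]) -> pd.Series:
    missing = set(cat["bucket"]) - set(totals)
    if missing:
        raise KeyError(f"buckets without experiment totals: {sorted(missing)}")
    sign = cat["reg_class"].map(CLASS_SIGN)
    denom = cat["bucket"].map(totals).astype(float)
    return sign * cat["n_experiments"].astype(float) / denom


def snp_region_table(region_snps: Mapping[int, set]) -> pd.DataFrame:
    """Long (snp_id, region_id) table from a region -> SNP-set mapping. A SNP
    proxying leads in several regions appears once per region."""
    rows = [
        (str(snp), int(region))
        for region, snps in region_snps.items()
        for snp in snps
    ]
    return pd.DataFrame(rows, columns=["snp_id", "region_id"])


def compute_pre(
    region_snps: Mapping[int, set],
    catalogue: pd.DataFrame,
    totals: Mapping[str, float],
    eqtl: pd.DataFrame | None = None,
    dosage: Mapping[str, float] | None = None,
    missing_dosage: float = 1.0,
) -> pd.DataFrame:
    """Sum weighted weights into PRE scores per (gene, region, bucket).

    Parameters
    ----------
    region_snps
        region_id -> set of SNP ids (leads plus LD proxies), from
        :func:`prenet.catalog_io.expand_ld`.
    catalogue, totals
        Evidence table and its bucket experiment totals. Pass the same
        ``eqtl`` to both this function and :func:`bucket_totals` so the
        pseudo-features are normalized consistently.
    dosage
        Optional subject risk-allele dosage per SNP in [0, 2]. Omitted SNPs
        get ``missing_dosage`` (default 1, the population-level convention);
        the number imputed is logged. With ``dosage=None`` every SNP
        contributes with weight 1 (population-level PRE).

    Returns
    -------
    Long DataFrame ``(target_gene, region_id, bucket, pre)`` with one row per
    gene/region/bucket combination that has at least one evidence row.
    """
    cat = merge_eqtl(catalogue, eqtl)
    pairs = snp_region_table(region_snps)
    merged = cat.merge(pairs, on="snp_id", how="inner")
    if len(merged) == 0:
        return pd.DataFrame(columns=PRE_COLUMNS).astype({"region_id": int, "pre": float})
    ww = _ww_column(merged, totals)
    if dosage is not None:
        d = merged["snp_id"].map(dosage)
        n_missing = int(d.isna().sum())
        if n_missing:
            logger.info(
                "compute_pre: %d evidence rows at SNPs absent from the dosage "
                "vector, imputed dosage=%g",
                n_missing,
                missing_dosage,
            )
        d = d.fillna(missing_dosage).astype(float)
        if ((d < 0) | (d > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        ww = ww * d
    out = (
        merged.assign(_ww=ww)
        .groupby(["target_gene", "region_id", "bucket"], as_index=False)["_ww"]
        .sum()
        .rename(columns={"_ww": "pre"})
    )
    return out[PRE_COLUMNS]


def aggregate_gene_pre(pre: pd.DataFrame) -> pd.DataFrame:
    """Collapse the region axis: per (gene, bucket), sum PRE over regions.

    Genes drawing score from multiple associated regions are logged.
    """
    if len(pre) == 0:
        return pd.DataFrame(columns=["target_gene", "bucket", "pre"])
    multi = (
        pre.groupby(["target_gene", "bucket"])["region_id"].nunique()
    )
    n_multi = int((multi > 1).sum())
    if n_multi:
        logger.info("aggregate_gene_pre: %d (gene, bucket) pairs span multiple regions", n_multi)
    return (
        pre.groupby(["target_gene", "bucket"], as_index=False)["pre"].sum()
    )


def gene_pre_wide(gene_pre: pd.DataFrame) -> pd.DataFrame:
    """Gene x bucket matrix (genes as rows) for heatmap-style consumers."""
    return gene_pre.pivot_table(
        index="target_gene", columns="bucket", values="pre", fill_value=0.0
    )


def pre_percentile_cutoff(values, q: float) -> float:
    """Linear-interpolation percentile of a bucket's PRE distribution.

    Downstream selection keeps genes with ``pre > cutoff`` **and** ``pre > 0``
    (strict inequalities; ties at the cutoff are excluded).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("pre_percentile_cutoff: empty value collection")
    return float(np.percentile(arr, q, method="linear"))


def select_high_pre(gene_pre: pd.DataFrame, bucket: str, q: float = 25.0) -> set[str]:
    """Genes in ``bucket`` with positive PRE strictly above the q-th percentile
    of that bucket's full (signed) PRE distribution."""
    sub = gene_pre[gene_pre["bucket"] == bucket]
    if len(sub) == 0:
        return set()
    cutoff = pre_percentile_cutoff(sub["pre"].to_numpy(), q)
    keep = sub[(sub["pre"] > cutoff) & (sub["pre"] > 0)]
    return set(keep["target_gene"])
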