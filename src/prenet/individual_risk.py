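"""Per-subject PRE matrices, intra-individual risk networks and case-control
comparison.

The population-level PRE treats every associated risk allele as present once;
here the same weighted-weight sum is multiplied by each subject's risk-allele
dosage (0-2 per SNP), giving genotype-dependent scores. Thresholding a
subject's per-bucket gene scores at a PRE percentile and intersecting with
the cell-specific interactome yields that subject's risk network; its
edge/LCC metrics are ranked across the cohort and compared between cases and
controls with a one-sided Mann-Whitney U test (cases stochastically greater).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import catalog_io, network_enrichment, pre_scoring

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["n_nodes", "n_edges", "lcc_nodes", "lcc_edges"]


def read_dosage_table(path) -> pd.DataFrame:
    """Subject x SNP risk-allele dosage matrix from a TSV whose first column
    is the subject id and remaining columns are SNP ids."""
    df = pd.read_csv(path, sep="\t", compression="infer", index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise catalog_io.ValidationError(f"{path}: missing dosage values")
    if (values < 0).any() or (values > 2).any():
        raise catalog_io.ValidationError(f"{path}: dosages must lie in [0, 2]")
    return df.astype(float)


def read_vcf_dosages(path, effects: pd.DataFrame) -> pd.DataFrame:
    """Risk-allele dosages from a VCF, for the SNPs in ``effects``.

    Dosage counts copies of the declared risk allele: when the risk allele is
    the ALT allele the genotype's alt count is used directly; when it is the
    REF allele the count is flipped (2 - alt). Sites where the risk allele
    matches neither REF nor ALT are skipped with a warning.
    """
    from cyvcf2 import VCF

    risk = dict(zip(effects["snp_id"].astype(str), effects["risk_allele"].astype(str)))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    n_flipped = n_skipped = 0
    for variant in vcf:
        vid = variant.ID
        if vid not in risk:
            continue
        allele = risk[vid]
        alt = variant.ALT[0] if variant.ALT else None
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alt_count = np.where(
            variant.gt_types == 3, 2.0, np.where(variant.gt_types == 1, 1.0, 0.0)
        )
        if allele == alt:
            columns[vid] = alt_count
        elif allele == variant.REF:
            columns[vid] = 2.0 - alt_count
            n_flipped += 1
        else:
            n_skipped += 1
    if n_flipped:
        logger.info("read_vcf_dosages: flipped %d sites where the risk allele is REF", n_flipped)
    if n_skipped:
        logger.warning(
            "read_vcf_dosages: skipped %d sites whose risk allele matches neither REF nor ALT",
            n_skipped,
        )
    return pd.DataFrame(columns, index=pd.Index(samples, name="subject_id"))


def subject_pre(
    dosage: Mapping[str, float],
    region_snps: Mapping[int, set],
    catalogue: pd.DataFrame,
    totals: Mapping[str, float],
    eqtl: pd.DataFrame | None = None,
    missing_dosage: float = 1.0,
) -> pd.DataFrame:
    """One subject's PRE matrix: the population computation with the
    subject's dosage vector (see :func:`prenet.pre_scoring.compute_pre`)."""
    return pre_scoring.compute_pre(
        region_snps,
        catalogue,
        totals,
        eqtl=eqtl,
        dosage=dosage,
        missing_dosage=missing_dosage,
    )


def cohort_gene_pre(
    dosages: pd.DataFrame,
    region_snps: Mapping[int, set],
    catalogue: pd.DataFrame,
    totals: Mapping[str, float],
    eqtl: pd.DataFrame | None = None,
    missing_dosage: float = 1.0,
) -> pd.DataFrame:
    """Gene-level PRE for every subject at once.

    Builds the SNP x (gene, bucket) weighted-weight matrix once and applies
    the whole cohort's dosage matrix as a single matrix product; equivalent
    to calling :func:`subject_pre` + aggregation per subject, row for row.

    Returns a long DataFrame ``(subject_id, target_gene, bucket, pre)``.
    """
    cat = pre_scoring.merge_eqtl(catalogue, eqtl)
    pairs = pre_scoring.snp_region_table(region_snps)
    merged = cat.merge(pairs, on="snp_id", how="inner")
    if len(merged) == 0:
        return pd.DataFrame(columns=["subject_id", "target_gene", "bucket", "pre"])
    ww = pre_scoring._ww_column(merged, totals)
    weights = (
        merged.assign(_ww=ww)
        .groupby(["snp_id", "target_gene", "bucket"], as_index=False)["_ww"]
        .sum()
    )
    w_mat = weights.pivot_table(
        index="snp_id", columns=["target_gene", "bucket"], values="_ww", fill_value=0.0
    )
    snp_ids = w_mat.index
    d = pd.DataFrame(
        {s: dosages[s] if s in dosages.columns else missing_dosage for s in snp_ids},
        index=dosages.index,
    )
    n_missing = sum(s not in dosages.columns for s in snp_ids)
    if n_missing:
        logger.info(
            "cohort_gene_pre: %d scored SNPs absent from genotypes, imputed dosage=%g",
            n_missing,
            missing_dosage,
        )
    scores = d.to_numpy() @ w_mat.to_numpy()
    out = pd.DataFrame(scores, index=dosages.index, columns=w_mat.columns)
    long = out.stack(["target_gene", "bucket"], future_stack=True).rename("pre").reset_index()
    long.columns = ["subject_id", "target_gene", "bucket", "pre"]
    return long


def subject_network(
    subject_gene_pre: pd.DataFrame,
    interactome: nx.Graph,
    q: float = 25.0,
    min_lcc_nodes: int = network_enrichment.DEFAULT_MIN_LCC_NODES,
) -> network_enrichment.NetworkMetrics:
    """Risk-network metrics for one subject in one cell bucket: select genes
    with positive PRE above the subject's q-th percentile in that bucket and
    measure the induced subnetwork."""
    bucket = interactome.graph.get("bucket")
    selected = pre_scoring.select_high_pre(subject_gene_pre, bucket, q)
    _, metrics = network_enrichment.extract_subnetwork(interactome, selected, min_lcc_nodes)
    if not selected:
        logger.info("subject_network(%s): empty selection (all-zero or negative PRE)", bucket)
    return metrics


def cohort_networks(
    dosages: pd.DataFrame,
    region_snps: Mapping[int, set],
    catalogue: pd.DataFrame,
    totals: Mapping[str, float],
    interactomes: Mapping[str, nx.Graph],
    status: Mapping[str, str] | pd.Series | None = None,
    q: float = 25.0,
    eqtl: pd.DataFrame | None = None,
    min_lcc_nodes: int = network_enrichment.DEFAULT_MIN_LCC_NODES,
) -> pd.DataFrame:
    """Per-subject, per-bucket risk-network metrics for a whole cohort.

    Returns one row per (subject, bucket) with the four connectivity metrics,
    the subject's case/control status if given, and the percentile rank of
    each metric across the cohort within the same bucket.
    """
    gene_pre = cohort_gene_pre(dosages, region_snps, catalogue, totals, eqtl=eqtl)
    adj_cache = {
        b: {v: set(g[v]) for v in g.nodes} for b, g in interactomes.items()
    }
    node_sets = {b: set(g.nodes) for b, g in interactomes.items()}
    rows = []
    for subject, sub_pre in gene_pre.groupby("subject_id", sort=False):
        for bucket in interactomes:
            selected = pre_scoring.select_high_pre(sub_pre, bucket, q)
            members = selected & node_sets[bucket]
            n_edges, lcc_n, lcc_e = network_enrichment._induced_metrics(
                members, adj_cache[bucket]
            ) if members else (0, 0, 0)
            rows.append(
                {
                    "subject_id": subject,
                    "bucket": bucket,
                    "n_selected": len(selected),
                    "n_nodes": len(members),
                    "n_edges": n_edges,
                    "lcc_nodes": lcc_n,
                    "lcc_edges": lcc_e,
                    "eligible": lcc_n > min_lcc_nodes,
                }
            )
    out = pd.DataFrame(rows)
    # subjects with no evidence rows at all still get zero-metric rows
    missing = set(map(str, dosages.index)) - set(out["subject_id"].astype(str))
    if missing:
        extra = [
            {
                "subject_id": s, "bucket": b, "n_selected": 0, "n_nodes": 0,
                "n_edges": 0, "lcc_nodes": 0, "lcc_edges": 0, "eligible": False,
            }
            for s in sorted(missing)
            for b in interactomes
        ]
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    if status is not None:
        status = pd.Series(status)
        out["status"] = out["subject_id"].map(status)
    for metric in METRIC_COLUMNS:
        out[f"{metric}_pctile"] = out.groupby("bucket")[metric].transform(
            lambda v: 100.0 * (v.to_numpy()[:, None] >= v.to_numpy()[None, :]).mean(axis=1)
        )
    return out


def percentile_rank(values: pd.Series | Sequence[float], subject) -> float:
    """Cohort percentile of one subject's metric: 100 x (#values <= subject's
    value) / cohort size. The top subject is at the 100th percentile; an
    all-tied cohort puts everyone at 100."""
    values = pd.Series(values)
    if len(values) < 2:
        raise ValueError("percentile_rank: need at least 2 subjects")
    x = float(values.loc[subject])
    return float(100.0 * (values.to_numpy() <= x).mean())


@dataclass
class CaseControlResult:
    bucket: str
    metric: str
    n_cases: int
    n_controls: int
    statistic: float
    p_value: float
    median_cases: float
    median_controls: float
    direction: str


def case_control_compare(
    profiles: pd.DataFrame,
    bucket: str,
    metric: str = "lcc_edges",
    case_label: str = "case",
    control_label: str = "control",
) -> CaseControlResult:
    """One-sided Mann-Whitney U test of cases stochastically greater than
    controls on a risk-network metric, with normal approximation and tie
    correction."""
    sub = profiles[profiles["bucket"] == bucket]
    cases = sub.loc[sub["status"] == case_label, metric].to_numpy(dtype=float)
    controls = sub.loc[sub["status"] == control_label, metric].to_numpy(dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(
            f"case_control_compare({bucket}): empty group "
            f"(cases={len(cases)}, controls={len(controls)})"
        )
    res = stats.mannwhitneyu(cases, controls, alternative="greater", method="asymptotic")
    med_ca, med_co = float(np.median(cases)), float(np.median(controls))
    return CaseControlResult(
        bucket=bucket,
        metric=metric,
        n_cases=len(cases),
        n_controls=len(controls),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_cases=med_ca,
        median_controls=med_co,
        direction="cases_greater" if med_ca > med_co else
        ("controls_greater" if med_co > med_ca else "tied_medians"),
    )
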