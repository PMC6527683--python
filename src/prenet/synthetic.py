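"""Self-contained synthetic inputs with planted, parameterized signal.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised end to end without any download:

* a regulatory-evidence catalogue in which a set of designated *causal*
  genes receives promoter/enhancer (PEX) features at ``pex_enrichment`` times
  the background rate, in one designated *signal* cell bucket only, and only
  through genome-wide (GW) tier SNPs (the statistically-replicated SR tier
  gets half the enrichment, the non-replicated NR tier none);
* a protein interactome with Erdos-Renyi background plus a planted module on
  the causal genes at ``planted_density_multiplier`` times the background
  edge probability;
* a genotyped cohort whose cases carry a shifted risk-allele frequency at
  SNPs in causal regions;
* cell-sorted expression counts whose per-bucket means increase with the
  same bucket's population PRE (each cell type coupled to its own scores
  only), with sample-specific sequencing depths and multiplicative noise.

Everything is drawn from one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so generated tables are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import catalog_io, pre_scoring

PEX_TYPES = ("enhancer", "promoter", "TFBS", "DHS", "H3K27ac")
R_TYPES = ("H3K27me3", "repressor", "H3K9me3")
ZQI_TYPES = ("quiescent", "insulator")

RAW_CELLS = {
    "T": ("CD4_T_primary", "CD8_T_primary"),
    "B": ("B_lymphocyte_primary",),
    "M": ("CD14_monocyte_primary",),
    "CNS": ("brain_cortex", "astrocyte_primary"),
    "L": ("lung_fibroblast_primary",),
}
CANCER_CELL = "HeLa_S3"

TIER_REGION_OFFSET = {"GW": 0, "SR": 1000, "NR": 2000}


@dataclass
class SimConfig:
    """Study conditions of the synthetic fixture (defaults are the conditions
    all planted-signal tests run under)."""

    n_regions: int = 30
    snps_per_region: int = 5
    n_genes: int = 200
    buckets: tuple = ("T", "B", "M", "CNS", "L")
    signal_bucket: str = "T"
    causal_gene_fraction: float = 0.15
    pex_enrichment: float = 10.0
    # mean background feature counts per (SNP, gene, bucket) cell, by class
    pex_rate: float = 0.08
    r_rate: float = 0.06
    zqi_rate: float = 0.04
    geometric_p: float = 0.5
    ppi_nodes: int = 200
    background_edge_prob: float = 0.04
    planted_module_size: int = 30
    planted_density_multiplier: float = 5.0
    n_subjects: int = 250
    case_fraction: float = 0.8
    case_dosage_shift: float = 0.15
    samples_per_bucket: int = 6
    expression_effect: float = 1.0
    expression_noise_sd: float = 0.3
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        n_causal = round(self.causal_gene_fraction * self.n_genes)
        if n_causal > self.n_genes:
            raise ValueError("more causal genes than genes")
        if self.planted_module_size > n_causal:
            raise ValueError(
                f"planted_module_size={self.planted_module_size} exceeds the "
                f"{n_causal} causal genes"
            )
        if self.planted_module_size > self.ppi_nodes:
            raise ValueError("planted module larger than the PPI")
        if self.ppi_nodes < self.n_genes:
            raise ValueError("ppi_nodes must cover all genes")
        if self.planted_density_multiplier < 1:
            raise ValueError("density multiplier must be >= 1")
        for p in (
            self.causal_gene_fraction,
            self.background_edge_prob,
            self.case_fraction,
            self.geometric_p,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class SyntheticData:
    config: SimConfig
    effects_by_tier: dict
    proxies: pd.DataFrame
    catalogue_raw: pd.DataFrame   # as written to disk, EXCLUDED rows included
    catalogue: pd.DataFrame       # class/bucket assigned, EXCLUDED dropped
    bucket_map: dict
    eqtl: pd.DataFrame
    ppi: nx.Graph
    causal_genes: list
    module_genes: list
    dosages: pd.DataFrame
    status: pd.Series
    counts: pd.DataFrame
    sample_buckets: dict
    genes: list = field(default_factory=list)


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def _tier_enrichment(config: SimConfig, tier: str) -> float:
    if tier == "GW":
        return config.pex_enrichment
    if tier == "SR":
        return (1.0 + config.pex_enrichment) / 2.0
    return 1.0


def simulate_catalogue(config: SimConfig, rng: np.random.Generator):
    """Effect lists, LD proxies, evidence catalogue, bucket map and eQTL
    table, with PEX enrichment planted on causal genes in the signal bucket."""
    config.validate()
    genes = _gene_names(config.n_genes)
    n_causal = round(config.causal_gene_fraction * config.n_genes)
    causal = sorted(rng.choice(genes, size=n_causal, replace=False).tolist())
    causal_set = set(causal)
    region_genes = {r: [] for r in range(config.n_regions)}
    for i, g in enumerate(genes):
        region_genes[i % config.n_regions].append(g)

    bucket_map = {
        raw: bucket for bucket, raws in RAW_CELLS.items() if bucket in config.buckets
        for raw in raws
    }
    bucket_map[CANCER_CELL] = catalog_io.EXCLUDED

    effects_by_tier: dict[str, pd.DataFrame] = {}
    proxy_rows = []
    # (snp, gene, tier-enrichment) skeleton shared by the vectorized draws below
    snp_col, gene_col, enrich_col = [], [], []
    for tier in ("GW", "SR", "NR"):
        enrich = _tier_enrichment(config, tier)
        eff_rows = []
        for r in range(config.n_regions):
            region_id = TIER_REGION_OFFSET[tier] + r
            snps = [f"rs{tier}{r}_{j}" for j in range(config.snps_per_region)]
            lead = snps[0]
            eff_rows.append(
                {
                    "snp_id": lead,
                    "chrom": str(r % 22 + 1),
                    "pos": int(rng.integers(1, 250_000_000)),
                    "risk_allele": str(rng.choice(list("ACGT"))),
                    "tier": tier,
                    "region_id": region_id,
                }
            )
            for proxy in snps[1:]:
                proxy_rows.append(
                    {"lead_snp": lead, "proxy_snp": proxy, "r2": float(rng.uniform(0.3, 1.0))}
                )
            for snp in snps:
                for gene in region_genes[r]:
                    snp_col.append(snp)
                    gene_col.append(gene)
                    enrich_col.append(enrich)
        effects_by_tier[tier] = pd.DataFrame(eff_rows)

    snp_arr = np.array(snp_col)
    gene_arr = np.array(gene_col)
    enrich_arr = np.array(enrich_col)
    causal_mask = np.isin(gene_arr, list(causal_set))

    pieces = []
    for bucket in config.buckets:
        raws = np.array(RAW_CELLS[bucket])
        for base_rate, types, boosted in (
            (config.pex_rate, np.array(PEX_TYPES), True),
            (config.r_rate, np.array(R_TYPES), False),
            (config.zqi_rate, np.array(ZQI_TYPES), False),
        ):
            rates = np.full(len(snp_arr), base_rate)
            if boosted and bucket == config.signal_bucket:
                rates[causal_mask] *= enrich_arr[causal_mask]
            n_feat = rng.poisson(rates)
            idx = np.repeat(np.arange(len(snp_arr)), n_feat)
            total = len(idx)
            if not total:
                continue
            pieces.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_arr[idx],
                        "feature_type": types[rng.integers(len(types), size=total)],
                        "cell_raw": raws[rng.integers(len(raws), size=total)],
                        "n_experiments": rng.geometric(config.geometric_p, size=total),
                        "target_gene": gene_arr[idx],
                    }
                )
            )

    # a sprinkling of cancer-cell-line rows that bucketing must drop
    n_cancer = int(rng.poisson(20))
    if n_cancer:
        pieces.append(
            pd.DataFrame(
                {
                    "snp_id": [
                        f"rsGW{int(r)}_0"
                        for r in rng.integers(config.n_regions, size=n_cancer)
                    ],
                    "feature_type": np.array(PEX_TYPES)[
                        rng.integers(len(PEX_TYPES), size=n_cancer)
                    ],
                    "cell_raw": CANCER_CELL,
                    "n_experiments": rng.geometric(config.geometric_p, size=n_cancer),
                    "target_gene": np.array(genes)[rng.integers(len(genes), size=n_cancer)],
                }
            )
        )

    catalogue_raw = pd.concat(pieces, ignore_index=True)
    catalogue_raw.insert(
        1, "feature_id", [f"F{i:06d}" for i in range(1, len(catalogue_raw) + 1)]
    )
    proxies = pd.DataFrame(proxy_rows)

    # eQTL records for a handful of causal genes in the signal bucket
    eqtl_rows = []
    for gene in causal[: max(1, len(causal) // 5)]:
        r = genes.index(gene) % config.n_regions
        eqtl_rows.append(
            {
                "snp_id": f"rsGW{r}_0",
                "target_gene": gene,
                "bucket": config.signal_bucket,
                "effect_sign": 1,
            }
        )
    eqtl = pd.DataFrame(eqtl_rows, columns=catalog_io.EQTL_COLUMNS)
    return effects_by_tier, proxies, catalogue_raw, bucket_map, eqtl, causal, genes


def simulate_ppi(config: SimConfig, causal_genes, genes, rng: np.random.Generator) -> nx.Graph:
    """Erdos-Renyi background plus a planted dense module on the first
    ``planted_module_size`` causal genes."""
    config.validate()
    nodes = list(genes) + [f"P{i:04d}" for i in range(config.ppi_nodes - len(genes))]
    module = sorted(causal_genes)[: config.planted_module_size]
    module_set = set(module)
    p_bg = config.background_edge_prob
    p_mod = min(1.0, p_bg * config.planted_density_multiplier)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    in_module = np.fromiter((nodes[i] in module_set for i in range(n)), bool, n)
    pair_p = np.where(in_module[iu] & in_module[ju], p_mod, p_bg)
    mask = rng.random(len(pair_p)) < pair_p
    graph.add_edges_from((nodes[i], nodes[j]) for i, j in zip(iu[mask], ju[mask]))
    graph.graph["module"] = module
    return graph


def simulate_cohort(
    config: SimConfig,
    effects_by_tier,
    proxies,
    catalogue,
    causal_genes,
    genes,
    rng: np.random.Generator,
):
    """Genotype dosages with case-enriched risk alleles, status labels, and
    expression counts coupled to each bucket's own population PRE."""
    config.validate()
    causal_regions = {genes.index(g) % config.n_regions for g in causal_genes}
    snp_ids = []
    shifted = []
    for tier in ("GW", "SR", "NR"):
        for r in range(config.n_regions):
            for j in range(config.snps_per_region):
                snp_ids.append(f"rs{tier}{r}_{j}")
                shifted.append(tier == "GW" and r in causal_regions)
    freqs = rng.uniform(0.2, 0.8, size=len(snp_ids))
    n_cases = round(config.case_fraction * config.n_subjects)
    subjects = [f"SUBJ{i:04d}" for i in range(config.n_subjects)]
    status = pd.Series(
        ["case"] * n_cases + ["control"] * (config.n_subjects - n_cases),
        index=pd.Index(subjects, name="subject_id"),
        name="status",
    )
    case_freqs = np.where(
        shifted, np.minimum(freqs + config.case_dosage_shift, 0.98), freqs
    )
    dosage = np.empty((config.n_subjects, len(snp_ids)), dtype=float)
    for i, subj in enumerate(subjects):
        f = case_freqs if status.iloc[i] == "case" else freqs
        dosage[i] = rng.binomial(2, f)
    dosages = pd.DataFrame(dosage, index=status.index, columns=snp_ids)

    # Expression profiles cover every interactome protein, as whole-
    # transcriptome profiles would; only the scored genes get the planted
    # coupling to their own bucket's population PRE (matched cell only).
    profiled = list(genes) + [f"P{i:04d}" for i in range(config.ppi_nodes - len(genes))]
    totals = pre_scoring.bucket_totals(catalogue)
    region_snps = catalog_io.expand_ld(effects_by_tier["GW"], proxies, r2_min=0.5)
    pre = pre_scoring.compute_pre(region_snps, catalogue, totals)
    wide = pre_scoring.gene_pre_wide(pre_scoring.aggregate_gene_pre(pre))
    wide = wide.reindex(index=genes, columns=list(config.buckets), fill_value=0.0)
    z = (wide - wide.mean()) / wide.std(ddof=0).replace(0.0, 1.0)
    z = z.reindex(index=profiled, fill_value=0.0)

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(profiled))
    )
    samples = []
    sample_buckets = {}
    count_cols = {}
    for bucket in config.buckets:
        for s in range(config.samples_per_bucket):
            name = f"{bucket}_s{s}"
            samples.append(name)
            sample_buckets[name] = bucket
            depth = rng.uniform(0.5, 2.0)
            mean = (
                baseline
                * np.exp(config.expression_effect * z[bucket].to_numpy())
                * np.exp(rng.normal(0.0, config.expression_noise_sd, size=len(profiled)))
                * depth
            )
            count_cols[name] = rng.poisson(mean)
    counts = pd.DataFrame(count_cols, index=pd.Index(profiled, name="gene"))
    return dosages, status, counts, sample_buckets


def simulate(config: SimConfig | None = None) -> SyntheticData:
    """Generate one complete, internally consistent fixture."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    (
        effects_by_tier,
        proxies,
        catalogue_raw,
        bucket_map,
        eqtl,
        causal,
        genes,
    ) = simulate_catalogue(config, rng)
    class_map = catalog_io.default_class_map()
    reg_class = catalogue_raw["feature_type"].map(class_map)
    bucket = catalogue_raw["cell_raw"].map(bucket_map)
    catalogue = catalogue_raw.assign(reg_class=reg_class, bucket=bucket)
    catalogue = catalogue[catalogue["bucket"] != catalog_io.EXCLUDED].reset_index(drop=True)
    catalogue = catalogue[catalog_io.CATALOGUE_COLUMNS]
    ppi = simulate_ppi(config, causal, genes, rng)
    dosages, status, counts, sample_buckets = simulate_cohort(
        config, effects_by_tier, proxies, catalogue, causal, genes, rng
    )
    return SyntheticData(
        config=config,
        effects_by_tier=effects_by_tier,
        proxies=proxies,
        catalogue_raw=catalogue_raw,
        catalogue=catalogue,
        bucket_map=bucket_map,
        eqtl=eqtl,
        ppi=ppi,
        causal_genes=causal,
        module_genes=list(ppi.graph["module"]),
        dosages=dosages,
        status=status,
        counts=counts,
        sample_buckets=sample_buckets,
        genes=genes,
    )


def write_fixture(data: SyntheticData, outdir) -> Path:
    """Write every table of a fixture as the plain-text formats the readers
    accept, plus a manifest recording the config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tier, effects in data.effects_by_tier.items():
        catalog_io.write_table(effects, outdir / f"effects_{tier}.tsv")
    catalog_io.write_table(data.proxies, outdir / "proxies.tsv")
    catalog_io.write_table(data.catalogue_raw, outdir / "catalogue.tsv")
    catalog_io.write_mapping(data.bucket_map, outdir / "bucket_map.yaml")
    catalog_io.write_table(data.eqtl, outdir / "eqtl.tsv")
    catalog_io.write_ppi(data.ppi, outdir / "ppi.tsv")
    data.dosages.reset_index().to_csv(outdir / "dosages.tsv", sep="\t", index=False)
    data.status.reset_index().to_csv(outdir / "status.tsv", sep="\t", index=False)
    data.counts.reset_index().to_csv(outdir / "counts.tsv", sep="\t", index=False)
    catalog_io.write_mapping(data.sample_buckets, outdir / "sample_buckets.yaml")
    manifest = {
        "config": dataclasses.asdict(data.config),
        "seed": data.config.seed,
        "causal_genes": data.causal_genes,
        "module_genes": data.module_genes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
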