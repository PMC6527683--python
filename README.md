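# prenet

Cell-specific **predicted regulatory effect (PRE)** scoring and risk-network
analysis for GWAS-associated loci.

Most GWAS hits are non-coding tags for regulatory variation whose effects are
cell-type-specific, so "nearest gene" prioritization misses both the gene and
the cell that matter. `prenet` is for statistical geneticists and systems
biologists who have (a) lists of associated SNPs with LD proxies, (b) a
regulatory-feature catalogue linking SNPs to target genes per cell type,
(c) a protein interactome, and optionally (d) cohort genotypes and
cell-sorted expression. It turns those into per-cell gene scores, tests of
subnetwork connectivity, and per-individual risk networks.

## The score and the test

Each catalogue row (SNP → feature → gene, in cell bucket *b*, supported by
*n* experiments) carries a signed weighted weight

```
WW = s · n / N_b        s = +1 (promoter/enhancer/transcription, PEX)
                        s = −1 (repressive, R), s = 0 (inert, ZQI)
```

with *N_b* the bucket's total experiment count (removes bias toward
well-studied cells). Summing over all SNPs of an associated region (leads
plus LD proxies at r² ≥ 0.5) gives the PRE per gene, per region, per cell
bucket; with genotypes, each SNP's term is multiplied by the subject's
risk-allele dosage (0–2).

Genes with positive PRE above the bucket's 25th percentile are intersected
with the cell's expression-filtered interactome; the subnetwork's edge count
and largest-connected-component (LCC) metrics are compared with 10,000
equally sized uniform node draws, p = (#null ≥ obs + 1)/(reps + 1).
Cohort case/control differences in per-subject network metrics use a
one-sided Mann–Whitney U. PRE is validated against cell-sorted expression by
Pearson correlation with gene-label permutation.

## Worked example

Everything below runs from a synthetic dataset with planted signal
(30 causal genes with enriched enhancer evidence in T cells, forming a dense
module in the interactome):

```bash
prenet simulate --out fixture --seed 3 --n-subjects 30
prenet enrich \
    --effects fixture/effects_GW.tsv --tier GW \
    --proxies fixture/proxies.tsv \
    --catalogue fixture/catalogue.tsv --bucket-map fixture/bucket_map.yaml \
    --ppi fixture/ppi.tsv --buckets T,B --reps 1000 --seed 1 \
    --out run_enrich
```

prints one row per cell bucket (columns abridged here):

```
bucket  n_selected  n_edges  lcc_nodes  lcc_edges  p_edges   null_mean_edges
     B          51       47         41         46  0.943057           57.656
     T          75      168         71        168  0.000999          124.143
```

The T-cell (signal) subnetwork has 168 edges where random 75-node draws
average 124, p ≈ 1/1001 — the planted module is recovered — while the
no-signal B bucket's 47 edges sit below its null mean (p ≈ 0.94). With `--status fixture/status.tsv`,
`prenet individual` adds per-subject network metrics, cohort percentiles
and the case–control Mann–Whitney comparison; `prenet validate` writes the
PRE × expression correlation grid whose matched-cell entries dominate;
`prenet grid` sweeps SNP tier × LD threshold × PRE percentile.

Every run directory contains a `manifest.json` with config, seed and input
checksums. The same functionality is available as a library
(`prenet.pre_scoring.compute_pre`, `prenet.network_enrichment.enrichment_test`,
`prenet.individual_risk.cohort_networks`,
`prenet.expression_validation.correlation_grid`, ...).

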