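# Methods

## The model

`prenet` scores genes under GWAS-associated regions by the regulatory
evidence that links associated variants to them, separately for each cell
type, and then asks whether the high-scoring genes of a cell type encode
proteins that are unexpectedly connected in a protein-interaction network.

### Predicted regulatory effect (PRE)

Every evidence row of the regulatory catalogue links one SNP to one target
gene through one regulatory feature observed in one cell type, supported by
`n` independent experiments. Features are classed as PEX
(promoter/enhancer/transcription-activating), R (repressive) or ZQI
(inert/quiescent). A row's *weighted weight* is

    WW = s(class) * n / N_b,      s(PEX) = +1, s(R) = -1, s(ZQI) = 0,

where `N_b` is the total experiment count of cell bucket `b`. Dividing by
`N_b` removes the bias toward heavily assayed cell types; since ZQI rows are
experiments that were *conducted*, they are counted in `N_b` by default
(flag-controlled). The PRE of gene `g` in region `r` and bucket `b` is

    PRE(g, r, b) = sum over SNPs s in region r (leads + LD proxies),
                   features f of s targeting g in bucket b of d(s) * WW(f),

with `d(s)` the risk-allele dosage at `s`. Population-level scores use
`d = 1` everywhere (the risk allele considered present once); individual
scores use the subject's dosage in [0, 2], so a subject homozygous for every
risk allele scores exactly twice the population value and all-ones dosage
reproduces it identically. PRE is linear in dosage and in catalogue rows,
and invariant to rescaling all experiment counts of a bucket by a common
factor.

Regions are the unit of association: each contains one or more independent
lead SNPs, expanded by LD proxies at `r2 >= r2_min` (0.5 for the main
analysis, 0.1/0.8 for sensitivity). Leads count as their own proxies
(r2 = 1) so every region is non-empty at any threshold.

eQTL records are embedded as pseudo-features with one supporting experiment
and sign equal to the effect direction, included in the bucket totals; the
embedding is minimal and switchable off.

### Connectivity of high-PRE genes

For each cell bucket the global interactome is first restricted to proteins
expressed in that cell. Genes with **positive** PRE strictly above the q-th
percentile of the bucket's gene-level PRE distribution (q = 25 by default;
10/50 in sensitivity analyses) are selected; genes with negative scores are
treated as not actively transcribed. The induced subgraph's total edges,
largest-connected-component (LCC) node count and LCC edge count are compared
against the same metrics of `reps` (default 10,000) equally sized node sets
drawn uniformly without replacement from the same cell interactome. The
p-value is the add-one estimator `(#null >= obs + 1) / (reps + 1)`, which is
never zero and conservatively super-uniform when the statistic is discrete.
Subnetworks whose LCC has <= 15 nodes are flagged ineligible (noise filter).

Two deliberate conventions: LCC ties break by edge count, then by the
lexicographically smallest node set, so reports are platform-stable; and a
degree-binned null sampler plus a sample-from-the-global-PPI option exist
behind flags for robustness checks, but the default null is plain uniform
sampling from the cell-filtered graph.

### Individual risk networks

Per-subject PRE is the same computation with the subject's dosages (missing
genotypes impute dosage 1, the population default, with a logged count; a
zero policy is selectable). Thresholding each subject's own per-bucket score
distribution at the PRE-25 cutoff and intersecting with the cell interactome
yields the subject's risk network; its metrics are ranked across the cohort
(percentile = 100 x fraction of subjects with value <= own; the top subject
is the 100th percentile) and compared between cases and controls with a
one-sided Mann-Whitney U (cases stochastically greater, asymptotic normal
approximation with tie correction). The test choice is ours: the comparison
is of discrete, tied edge counts, for which a distribution-free rank test is
appropriate.

### Expression validation

Counts from cell-sorted RNA-seq are normalized by median-of-ratios (per-gene
geometric-mean reference over genes positive in every sample; per-sample
size factor = median count/reference ratio). Per-bucket expression is the
mean of normalized counts over the bucket's samples (an aggregation the
method leaves open; the mean is the simplest consistent choice). The
validation statistic is the Pearson correlation between a bucket's gene-level
PRE and a bucket's expression on their gene overlap, for all bucket pairs;
significance is a gene-label permutation test, two-sided on |r|, with the
add-one estimator. Cell-specific scoring predicts the matched pair of each
row/column to carry the largest correlation. Log-transforming expression
first is available behind a flag, off by default.

## Synthetic study data

The fixture generator produces every input from one seed, byte-identically:

* **Catalogue** - three SNP tiers (GW/SR/NR), 30 regions x 5 SNPs each
  (1 lead + 4 proxies at r2 ~ U(0.3, 1)), 200 genes partitioned across
  regions. Thirty designated causal genes receive PEX features at 10x the
  background rate, in one designated signal bucket (T) only, at full
  strength through GW SNPs, half through SR, none through NR. Background
  rates per (SNP, gene, bucket) are PEX 0.08 / R 0.06 / ZQI 0.04, chosen so
  that (a) essentially every causal gene carries evidence (mean ~3 causal
  PEX features) while (b) background evidence stays sparse and cell-specific
  and PRE-25 selections remain a minority of scored genes, as in real
  catalogues where most gene-cell scores are neutral. Experiment counts are
  geometric (heavy-tailed, as in public catalogues); a sprinkling of cancer
  cell-line rows exercises the exclusion path.
* **Interactome** - Erdos-Renyi background over exactly the 200 scored
  genes at edge probability 0.04 (mean degree 8), with a planted module on
  30 causal genes at 5x that density. Restricting the PPI to the scored
  gene universe makes a null-bucket selection exactly exchangeable with the
  uniform node draws of the permutation null, so the no-signal arm of the
  power analysis is exactly calibrated; the cost is that the fixture does
  not model the real situation of an interactome much larger than the
  scored set, where selections drawn only from scored genes carry a small
  systematic module excess. Passing tests therefore demonstrate calibration
  and power of the statistic itself, not robustness to that
  universe-mismatch bias.
* **Cohort** - 250 subjects (200 cases / 50 controls). Control dosages are
  Binomial(2, f) with f ~ U(0.2, 0.8) per SNP; cases' risk-allele frequency
  is shifted +0.15 at GW SNPs in causal regions.
* **Expression** - six samples per bucket; per-gene lognormal baselines
  (log-sd 1), sample depths U(0.5, 2), Poisson counts with multiplicative
  lognormal noise (sd 0.3) around `baseline * exp(z)`, where `z` is the
  standardized PRE of the same bucket. Every bucket is coupled to its own
  scores only, producing the diagonal-dominant correlation structure the
  validation expects.

What the generator does **not** emulate: realistic LD structure (proxies are
symbolic), genome coordinates, degree-heterogeneous (scale-free)
interactomes, negative-binomial overdispersion beyond the lognormal noise,
population structure or relatedness.

## Numerical choices

* Percentiles use linear interpolation; selection uses strict `>` at the
  cutoff plus strict positivity, so ties at the cutoff are excluded
  deterministically.
* Induced-subgraph metrics in the null sampler run on a boolean adjacency
  matrix with vectorized breadth-first sweeps for graphs up to 4000 nodes,
  and on neighbor sets beyond; both paths are cross-checked against
  networkx component enumeration.
* All randomness flows through `numpy.random.Generator` seeded per stage;
  every report records its seed and replicate count.
* Exact invariances (row duplication, PEX/R swap, all-ones dosage) hold to
  float summation order (<= 1e-15 absolute in tests).

## Problem sizes used in the checks

The automated checks run the pipeline at the fixture defaults above
(200 genes, 200-node interactome, 250-subject cohorts) with 100 independent
seeds for power/recovery rates, 500 trials x 500 replicates for null
calibration and 1000 replicates per connectivity test — sizes chosen so the
whole battery completes in a few minutes on one CPU while leaving the
binomial noise of the reported rates around one percentage point.

## Known limitations

* The feature-class map ships as an editable default; real catalogue exports
  should supply their own vocabulary mapping.
* The null-bucket calibration statement above is exact only under the
  scored-universe interactome; with a larger PPI the uniform null is mildly
  anticonservative for selections restricted to scored genes.
* eQTL weighting (one pseudo-experiment per record) is the minimal
  embedding; the original pipeline's arithmetic for eQTL evidence is not
  specified and may differ.
* CNS-style heterogeneous buckets (many source tissues pooled) are modeled
  only as one more label; the smoothing effect of pooling distinct
  regulatory programs is not emulated.
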