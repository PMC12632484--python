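# Methods

This note documents the models and procedures implemented in
`scclonal`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that affect
results.

## Synthetic study design

The generator plants a complete two-clone tumor study and is the
reference condition for every default and test in the package.

**Genome.** 12 chromosomes of 60 Mb (3,000 bins of 20 kb each; 72
aggregation windows of 10 Mb). Coordinates are 0-based half-open. Sex
chromosomes are not simulated; all SNP work is autosomal. The
12-chromosome default (rather than a handful of large chromosomes) is
deliberate: model-order selection penalties scale with the number of
aggregated windows d, and d = 72 keeps AIC/BIC selection stable at the
~1,000-cell default (see *Model selection* below). Chromosome count and
length are config fields.

**Clone profiles.** Haplotype-resolved profiles descend from a diploid
(1,1) ancestor. Trunk events shared by all clones: a 30 Mb gain
(2,1), a 20 Mb hemizygous loss (1,0), and chromosome-wide copy-neutral
LOH (2,0) — the configuration that yields pseudobulk VAF 1 for a
variant on the retained haplotype. Clone-private events include a
mirrored allelic-imbalance segment (clone 0 = (1,2), clone 1 = (2,1),
total 3 on both sides), a clone-1-private copy-neutral LOH that removes
the haplotype carrying a trunk driver variant (driver reversion), and
random segmental gains/losses (rejected if any haplotype would fall
below 0). Subclones add one gain each; WGD profiles are exactly 2× the
parent baseline plus one post-WGD gain, so genuine WGD cells retain an
odd-CN window and survive the artifact filter.

**Cell composition** (n = 1,000 by default): 18% diploid, 1%
pseudo-diploid, tumor cells split 30/70 between the two clones, 40% of
clone 1 whole-genome doubled, 3% doublets, 5% replication-noisy, 3%
degraded, 1% all-even artifact cells. Planted doublets are diploid–
tumor or distinct-clone tumor–tumor pairs — the collision classes the
removal stage models; a same-clone pair is bin-for-bin identical to a
WGD cell and no CN rule can separate them.

**Noise model.** Observed CN = true CN plus ±1 integer flips with
per-bin probability `rate × CN/2` (rate 0.02 by default, 0.45 for
noisy cells). Scaling the flip rate with copy number reproduces two
observed phenomena: per-bin variability grows with mean copy number
(positive mean–sd regression slope) and WGD clusters show the largest
intra-cluster pairwise distances. Degraded (apoptotic-like) cells
receive both random segmental dropout (30–70% of windows set to CN
0/1) and the elevated flip rate — dropout alone yields artificially
smooth profiles that no bin-to-bin statistic could flag. Per-call
quality is drawn so ~5% of calls fall below 15; ~3% of bins get
mappability below 0.90.

**Allele counts.** Heterozygous phased SNPs at 1/Mb; per-cell depth at
each SNP is Poisson with mean `snp_depth_mean × CN/2` (default 12,
≈120 reads per cell per 10 Mb bin — calibrated so single-cell
haplotype splits are informative at desk scale; real droplet scDNA-seq
is far sparser and relies on the same pooling machinery at the cluster
level). B-haplotype reads are binomial at B/(A+B), error-adjusted.
Variant sites carry per-cell alt/ref counts at ~2 reads/cell (sparse,
like real droplet data); trunk variants are placed in regions still
(1,1) in every clone so their VAFs are comparable across clones, and
private variants on a haplotype the carrier retains — unobservable
variants would never appear in a candidate-site list.

**Spatial data.** ~2,000 spots on a grid: a stromal ring around a
central tumor rectangle split into contiguous, disjoint clone
territories. Counts are Poisson with gene means scaled by
`purity × CN/2 + (1 − purity)` (purity 0.85 in tumor spots); 30
stromal and 30 immune signature genes are 5× elevated in stroma and
10× depressed in tumor cells. ~2 genes/Mb with genomic positions.

**What the generator does not emulate:** read-level data (FASTQ/BAM),
GC and replication-timing waves, phasing switch errors (a knob exists
but defaults to off), platform-specific spot geometry, cell-cycle
expression programs, and inter-sample batch effects. Tests passing on
this generator demonstrate that the algorithms recover planted
structure under calibrated noise — not that they are robust to every
artifact of real instruments.

## QC

DIMAPD is implemented as the **mean** absolute difference between
consecutive unmasked same-chromosome bin calls divided by the cell's
mean CN (scale-free, 0 for constant profiles, 1.0 for 1,3,1,3…). The
median variant of this statistic is uninformative on integer call
matrices: with a ~2% per-bin error rate virtually every consecutive
difference is zero, so every clean cell scores exactly 0.

The noisy-cell threshold fits a Gaussian to the per-cell score
distribution by **moments** (mean/sd) and flags upper-tail p < 0.1.
The contaminated tail inflates the fitted scale — that is the point:
clean cells sit many fitted-sigmas below the threshold (≈0 removed),
while replicating, noisy and degraded cells sit far outside. A robust
(median/MAD) fit would recover the clean distribution itself and by
construction discard ~10% of clean cells; it remains available as
`robust=True`. A degenerate (zero-variance) fit flags nothing and
warns. Low ploidy confidence flags a cell regardless of score; when
the column is absent all cells are treated as confident (warned).

## Clustering and model selection

Cells are aggregated to mean ploidy over 500-bin windows (masked calls
excluded; all-masked windows missing, imputed to the column mean only
for the clustering step). K-means (10 restarts per k, seeded) runs for
k = 1..20 on the full component space (all principal components are
kept by default — the aggregated dimension is already small; a
truncation parameter exists for wide inputs).

Each partition is scored with a spherical-Gaussian log-likelihood
evaluated at a **fixed, data-wide variance scale** σ² = RSS(k=1)/(nd):
−2 lnL = RSS(k)/σ² + nd·ln(2πσ²), AIC = −2 lnL + 2p and
BIC = −2 lnL + p·ln n with p = k·d + 1. Fixing the variance scale
makes the criteria compare how much of the total variance each
partition explains. With a profiled (per-k re-estimated) variance,
splitting a pure-noise Gaussian cluster always gains ≈0.637·n in
−2 lnL against a fixed 2d penalty, so AIC would select k_max on any
well-separated data; at the fixed scale the likelihood gain collapses
once real structure is exhausted and AIC elbows sharply at the number
of distinct CN profiles. BIC's heavier penalty (ln n > 2) leaves rare
subpopulations unsplit, so BIC-selected k ≤ AIC-selected k — the
underclustering direction expected for this criterion family.

Finite-sample behaviour worth knowing: for a genuinely structureless
cluster, k-means can still capture sampling noise, and AIC splits such
clusters once their size exceeds roughly 1.5–2× the window dimension
(≈110–150 cells at d = 72). Large homogeneous clusters therefore
subcluster liberally — mirroring the behaviour of this criterion
family on real data, where second-round clustering routinely yields
many subclusters. Downstream stages key off first-level clusters and
cluster-kind classification, so this liberality does not propagate.

Cluster kinds: diploid = modal rounded CN 2 over ≥90% of windows;
WGD = mean ploidy 1.7–2.3× another cluster's with cosine similarity of
flat-relative deviations ≥0.9 after doubling; the rest are tumor
baselines. DAPC is PCA followed by LDA on cluster labels.

## Doublets and artifacts

Doublet profiles: baseline + 2 per baseline cluster; element-wise sum
per unordered baseline pair (exactly 3 profiles for two baselines). A
cell is removed when its mean absolute deviation to a doublet profile
is below 0.35 **and** below its distance to every singlet cluster
profile; the 0.35 default was calibrated on the default simulation
(sensitivity ≥0.95 at FPR ≤0.01) and is monotone — lowering it only
retains more cells. A first-round cluster whose own profile matches a
doublet profile (a collision-dominated cluster) is excluded from the
singlet reference set; diploid and WGD clusters are exempt from that
rule because a WGD profile equals a same-clone tumor–tumor sum by
arithmetic. The odd-region filter removes non-diploid cells lacking
any 10 Mb window of odd modal CN (all-even profiles are the signature
of calling a genome at twice its ploidy); the diploid cluster is
exempt since an all-2 genome is genuine.

## Haplotype CN, LOH, mirrored events, reversion

Per cell and 10 Mb bin, SNP reads are pooled and the integer split
(a, b) with a + b = rounded total CN maximises the binomial likelihood
of B-haplotype reads at success probability b/total, clipped to
[0.01, 0.99] (the error floor avoids zero-likelihood degeneracy at
monoallelic splits); ties break toward balance; zero depth → unknown.
Cluster consensus is the modal (a, b) per bin. LOH segments merge
consecutive bins with min(a,b) = 0 and the same lost haplotype,
classed by retained copies (1 hemizygous, 2 copy-neutral, ≥3
amplified). Mirrored segments are maximal runs where two cluster
consensuses swap an unbalanced split ((a,b) vs (b,a), a ≠ b). A
reversion is called for (variant, cluster) when the cluster's LOH
spans the site with the variant-bearing haplotype lost, its pseudobulk
VAF is ≤0.02, and another cluster carries the variant at VAF ≥0.1;
unphased variants return "inconclusive". Full evolutionary-link
modelling (global EM across clones, phase-switch correction) is out of
scope: downstream uses here depend only on the per-bin split, which is
testable against exhaustive enumeration.

## Pseudo-diploid detection

For diploid-cluster cells, the deviation vector is rounded coarse CN
minus 2; the score against each tumor baseline is the Pearson
correlation of deviation vectors, plus the fraction of the cell's
gained bins that lie in clone-gained bins. Classification requires
score > 0.15 and ≥3 deviating windows. The threshold was calibrated on
the default simulation (10 seeds): clone deviation profiles contain
many bins absent from any single pseudo-diploid cell, which dilutes
the correlation (planted-cell scores center near 0.38), while true
diploid cells never reach 3 deviating 10 Mb windows under the default
noise — so the false-positive rate is ~0 at any threshold and the
threshold trades only sensitivity.

## Phylogeny

Distances are Manhattan (L1) on CN vectors — per cell at 1 Mb or per
subcluster at mean 20 kb resolution — with pairwise exclusion of
missing bins and rescaling to the full bin count. The tree is
neighbor-joining (the greedy agglomerative search for the balanced
minimum-evolution criterion), followed by branch-length re-estimation
by weighted least squares under Pauplin's balanced weights
(w_ij = 2^(1−topological distance)) and nearest-neighbor-interchange
moves accepted while the balanced tree length decreases. Negative
branch estimates are clamped to zero with the deficit pushed to child
edges (count logged). Rooting splits the outgroup's pendant edge at
its midpoint, preserving all leaf-to-leaf path lengths. On additive
matrices the output path-length matrix reproduces the input to
<1e−9. Note that WGD taxa necessarily attach on long branches far from
their parent clone: the L1 offset of a doubled genome (≈ the sum of
all copies) dwarfs subclone differences, so WGD–parent relations come
from the doubling-rule classification, not tree adjacency.

## Spatial concordance

Counts are scaled to a fixed 10,000-count target and log1p-transformed
(the fixed target makes normalization invariant to global rescaling;
downstream scores are rank-based or reference-relative, so the
variance-stabilisation refinement of regression-based normalisation is
not needed here). Purity is a logistic map of the averaged stromal and
immune single-sample enrichment scores (rank-based, weight 0), with
center 0.15 and steepness 15 calibrated on synthetic mixtures so that
pure tumor spots score >0.9 and stroma <0.1; the 0.7 cut then splits
tumor from reference spots with margin on both sides. Spots exactly at
the threshold go to the reference side.

CN inference: per gene, relative expression = normalized value minus
the reference-spot mean, clipped at 3 reference sd; a centered moving
average over 21 genes smooths along the genome per chromosome (21
genes ≈ 10 Mb at the synthetic ~2 genes/Mb density — the genomic span
that a ~100-gene window covers at real expressed-gene density, which
is why the function default is 101). After smoothing, the reference
smoothed baseline is re-subtracted per gene (cancelling the skew bias
of log-Poisson noise) and each spot's smoothed profile is
median-centered (cancelling compositional/library offsets between
cell-type programs; valid while most of the genome is copy-neutral).
Tumor spots are partitioned by Leiden (k-NN graph, k = 15, resolution
0.5, seeded), and each subgroup's mean profile is decoded per
chromosome by a 3-state Gaussian HMM with state means ±0.2, variance
estimated from reference-spot smoothed profiles, and stay probability
1 − 1e−4; decoding is an explicit Viterbi pass cross-checked against
exhaustive path search in tests.

Subgroup profiles are aggregated to 10 Mb bins and Pearson-correlated
with clone deviation profiles; assignment requires a 0.1 margin over
the runner-up, else "ambiguous". Baseline clusters whose deviation
profiles correlate ≥0.9 (subclones of one clone) are pooled
cell-count-weighted before matching, since expression cannot resolve
few-bin subclone differences. Positional enrichment builds gene sets
from clone-private gained regions (≥10 genes), scores spots by the
ssGSEA difference, and tests it against a 200-permutation random-set
null via a normal approximation, two-sided, Bonferroni-corrected
across spots — the normal approximation is what allows Bonferroni-
scale p-values from a permutation-sized null. The cell-cycle scorer is
the standard expression-bin-matched control design; a phase is called
only when its score exceeds 0.1 on the log scale, otherwise G1 (an
argmax without margin would assign random phases to noise).

## Problem sizes and determinism

Defaults: 1,000 cells × 36,000 bins, 720 SNPs, 13 variant sites,
2,000 spots × 1,500 genes; the full pipeline runs in ~30 s on one
core. The test suite exercises the same structure at 300 cells / 600
spots and runs the model-order recovery experiment at 200 cells × 20
seeds; these sizes are the package's chosen desk-scale study
conditions. All randomness derives from the config seed via named
`numpy` generator streams, so a fixed seed reproduces every output
byte-for-byte, including the pipeline report.

## Known limitations

* The AIC criterion subclusters large homogeneous clusters (see
  above); interpret subclusters below the first level as candidate
  structure, not guaranteed clones.
* Haplotype splits assume error-free phasing; switch errors would
  fragment LOH segments.
* The purity map's calibration constants are tied to signature
  strength in the synthetic mixtures; on real panels the logistic
  center/steepness should be re-calibrated against histology, as the
  0.7 threshold itself was in the source protocol.
* Doublets involving WGD cells and same-clone collisions are
  undetectable by profile arithmetic and are out of the removal
  stage's scope.
* Expression-based CN inference cannot distinguish total CN 2 from 3
  in low-purity spots and does not detect WGD (dosage is ratio-based);
  concordance with scDNA is at the clone-profile level.
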