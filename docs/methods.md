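# Methods

`nbmeth` implements a methylation-array subgrouping pipeline for
neuroblastoma-style tumour cohorts: probe-level QC of Infinium 450k-type
beta values, resampling-consensus t-SNE/k-means cluster discovery with
per-sample stability scoring, copy-number inference from combined probe
intensities, cluster-specific differentially methylated region (DMR)
detection, and cluster-feature association plus survival comparison. A
synthetic-cohort generator with complete ground truth makes every stage
testable without access to controlled patient data.

## Preprocessing

Beta values are the canonical array methylation score,
β = M / (M + U + offset), with M and U the methylated and unmethylated
intensities and offset = 100 by default (the offset is not part of any
published formula for this pipeline's inputs; it is the array ecosystem's
convention and is configurable). Probes are removed, in order, when they

1. fail detection (detection p > 0.01 in ≥ 50% of samples; the 50% boundary
   is inclusive),
2. are flagged cross-reactive,
3. lie on the X or Y chromosome (clustering only — the copy-number path
   keeps them), or
4. have a proximal common SNP (distance ≤ 2 bp from the CpG and minor
   allele frequency ≥ 5%, both boundaries inclusive).

The filter report attributes each removed probe to the first rule that
removed it. Clustering then uses the `top_k` (default 10,000) probes with
the largest sample standard deviation (ddof = 1); ties break on probe id.

## Consensus clustering

Samples are compared with d(i, j) = 1 − weighted Pearson correlation over
the selected probes. The probe weights are not fixed by any published
formula; the default weights each probe by its cross-sample SD (consistent
with variance-driven probe selection), and `probe_weights="uniform"` reduces
exactly to ordinary Pearson — the equivalence is pinned by a test against a
textbook implementation.

The distance matrix is embedded by exact t-SNE (theta = 0) in two and three
dimensions (perplexity 30, up to 5,000 optimisation steps in production
runs) and each embedding is partitioned by k-means for k = 2…10 with ten
greedy k-means++ restarts. Stability is assessed by resampling: each of
`n_iter` (default 256) iterations clusters a random 80% subsample, assigns
every held-out sample the label of its nearest sampled neighbour under the
precomputed distance (a full-cohort labelling per iteration), and aligns
the result to the full-data reference partition of that (dimension, k) cell
by maximum-weight bipartite matching (Hungarian algorithm) on the label
contingency table. An alignment anchor is needed to make modal scores
well-defined; the full-data partition is a convention of this
implementation.

Per sample, the modal score is the frequency of its most common aligned
label across iterations. Failed iterations (embedding errors) are excluded
from the denominator, and a cell is marked invalid when fewer than 90% of
its iterations succeed; with no failures — the tested regime — the score is
exactly max label frequency / n_iter. Cell reproducibility is the mean
modal score, and the silhouette of the modal partition is computed on the
original distance matrix, not on the embedding (partition quality in data
space; samples in singleton clusters score 0). The selected (dimension, k)
maximises the summed ranks of reproducibility and average silhouette over
valid cells; ties prefer smaller k, then smaller dimension. Silhouette is
undefined for a single cluster, so the grid starts at k = 2. A sample is
*classifiable* when its modal score strictly exceeds 0.70 and its
silhouette is strictly positive; non-classifiable samples are excluded from
all per-cluster analyses downstream.

Seeding: one master seed; the reference run and every (iteration, dim, k)
combination use seeds derived through `numpy.random.SeedSequence`, so any
grid cell is reproducible in isolation.

## Copy-number inference

Combined intensities (M + U) are normalised against a reference panel of
copy-neutral samples: the per-probe reference profile is the median across
panel members, each query sample is globally rescaled so its median total
matches the profile's median, and per-probe log2 ratios are taken. Probes
are binned greedily along each chromosome arm; a bin closes once it spans
≥ 50,000 bases *and* contains ≥ 15 probes, a trailing incomplete bin merges
into its left neighbour, and an arm that cannot satisfy the minima emits no
bins. The bin value is the median probe ratio.

Event calling works from bins: an arm is called gained/lost when its median
bin value exceeds ±0.1 (the calling threshold is an analyst choice — the
binning convention this follows leaves calling to the user — and is
configurable); a whole-chromosome aberration (WCA) requires both arms
non-neutral in the same direction (single-armed chromosomes, e.g.
acrocentrics, are called on the available arm); a segmental aberration
(SCA) is a run of ≥ 3 consecutive same-direction out-of-threshold bins on a
chromosome without a WCA, so WCA and SCA are mutually exclusive per
chromosome; focal amplification/homozygous deletion requires a bin
overlapping a listed gene beyond ±1.0.

## DMR detection

For each cluster, a one-vs-rest contrast over classifiable samples computes
per-CpG deltas (cluster mean β − rest mean β) and Welch t-test p-values,
with Benjamini–Hochberg FDR across tested CpGs (CpGs constant in both
groups are flagged and skipped). Significant CpGs (FDR < 0.05) sharing a
delta sign are grouped along each chromosome while consecutive gaps stay
≤ 1 kb; groups of ≥ 2 CpGs whose mean delta exceeds 0.30 in absolute value
(strict) become DMRs. The transparent grouping rule replaces
kernel-smoothed region callers; the gap and minimum-CpG defaults mirror
their conventions, and the Δβ > 0.3 retention rule is the pipeline's
primary filter. Each DMR is annotated with its nearest gene by minimal
interval distance (0 when overlapping, ties to the lexicographically
smallest name); DMRs farther than 20 kb from every gene stay unlinked and
are dropped from gene-level summaries.

## Association and survival statistics

Cluster-feature specificity uses Pearson chi-squared tests (no continuity
correction by default; a Yates flag exists for 2×2 tables since ecosystem
defaults differ — the headline associations are robust to the choice).
"Infant" means age < 1.5 years at diagnosis, boundary exclusive. Samples of
unknown status are excluded per feature before testing. Methylation–
expression relationships use Spearman rank correlation (average ranks on
ties, t-approximation p). Survival uses the Kaplan–Meier product-limit
estimator with a 5-year extraction for progression-free survival, and the
standard unweighted log-rank test (df = K − 1) across subgroups.
Multivariable Cox regression is out of scope.

## Synthetic cohorts

The generator emulates the statistical structure of a 450k neuroblastoma
cohort; its defaults are the conditions under which the pipeline is tested.

- **Manifest** — probes laid out in CpG-island-like clusters (sizes
  1 + Poisson(7), spacing 30–300 bp) spread across autosomes proportionally
  to hg19 chromosome length; acrocentric p arms carry no probes; 2% of
  probes flagged cross-reactive and 2% given a proximal-SNP annotation;
  focal loci referenced by configured copy-number events always receive a
  dense 25-probe cluster so bins cover them.
- **Methylation** — a bimodal baseline (55% unmethylated ~U(0.04, 0.12),
  35% methylated ~U(0.82, 0.95), 10% intermediate) shared by all clusters;
  each of five clusters owns 25 DMR blocks of 8 consecutive CpGs whose
  baseline is harmonised to a coherent state and shifted by ±0.35 in the
  owning cluster (blocks sit on uniformly methylated islands, so the
  planted shift never clips at the [0, 1] support). With 8,000 probes this
  places ~12% of probes as subgroup-discriminating, standing in for the
  enrichment of subgroup signal among the most variable probes of real
  arrays. Per-sample β is Beta-distributed around the archetype with
  concentration 60 (SD ≈ 0.03–0.06, the support-respecting noise model).
- **Intensities** — per-probe baseline totals lognormal(log 4000, 0.2) with
  lognormal(0, 0.15) per-sample noise; copy-number events multiply M and U
  jointly by 2^shift so β is copy-neutral to first order (arm/whole gains
  and losses at |log2| = 0.35–0.4, focal events at 1.5, with per-cluster
  carrier sets and penetrances mirroring the recurrent neuroblastoma
  aberration pattern: 1p−/17q+/MYCN-amp, 11q−/3p−/4p−/whole-7+, numeric
  whole-chromosome gains in the infant-like and WCA-rich clusters). The
  emitted β matrix is recomputed from the emitted intensities, so the two
  views are exactly consistent. Ten copy-neutral reference samples share
  the probe baseline.
- **Ambiguity** — a configurable fraction of samples is drawn as convex
  mixtures of two cluster archetypes (weight ~U(0.35, 0.65)), modelling
  non-classifiable samples; their true label is the first mixture
  component.
- **Clinical and survival** — covariates are drawn per cluster (an
  infant-dominated low/intermediate-risk cluster, a MYCN-amplified
  high-risk cluster, three stage-4 high-risk clusters); survival is
  exponential per cluster (0.2/yr, ≈37% event-free at 5 years, except
  0.06/yr ≈ 74% for the infant-like cluster) with independent exponential
  censoring at 0.08/yr.
- **Detection p-values** — U(0, 0.005) for sound probes; 0.2% of probes
  fail (p ~ U(0.02, 1)) in 60% of samples.

What the simulator does **not** model: raw idat chemistry and background
correction, batch/plate effects, tumour purity and stromal contamination,
probe type I/II bias, and spatially correlated noise. Passing recovery
tests therefore demonstrates the correctness of the algorithms under their
stated assumptions, not the clinical performance of the pipeline on real
arrays.

## Problem sizes for the bundled checks

The test suite and `scripts/acceptance.py` run desk-scale versions of the
production configuration: consensus recovery uses cohorts of n = 120 over a
(dimension ∈ {2, 3}) × (k ∈ 2…8) grid with 64 resampling iterations and
t-SNE capped at 1,000 optimisation steps (the embeddings converge well
before the cap at these sizes); classifiability sweeps use a single-cell
grid; copy-number recovery uses 50 carriers over 6,000 probes; DMR recovery
uses two-group cohorts of 40 + 40 samples with within-group SD ≈ 0.05; null
calibration uses 200 simulations. Larger runs only sharpen the same
estimates.

## Numerical choices and degenerate inputs

- Distances are symmetrised and clipped to [0, 2]; a sample with zero
  weighted variance raises an error naming the sample.
- sklearn's precomputed-metric t-SNE mutates its input; the wrapper always
  passes a defensive copy. Perplexity must satisfy perplexity < (n − 1)/3,
  enforced on the subsample size for consensus runs.
- k-means ties and initialisation follow scikit-learn's greedy k-means++;
  the number of restarts (10) trades determinism-by-seed against local
  optima.
- Label alignment with unequal cluster counts keeps unmatched labels as
  fresh ids rather than merging them.
- Chi-squared tests reject tables with a zero marginal; Spearman rejects
  constant vectors; the log-rank test requires two non-empty groups;
  survival times must be finite and nonnegative.

## Known limitations

- The selection rule (rank-sum of reproducibility and silhouette) can be
  indifferent among k ≥ true k when extra clusters stay empty in the modal
  partition; the smaller-k tie rule resolves this conservatively.
- Arm calls use a fixed ±0.1 log2 threshold; no purity or ploidy
  adjustment is attempted, so heavily contaminated samples would be
  under-called on real data.
- The DMR caller tests CpGs independently (no spatial smoothing), which is
  transparent but slightly less powerful than kernel-based callers at equal
  FDR for sparse regions.
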