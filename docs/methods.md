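# Methods

This note documents the models and procedures behind landracekit, the
assumptions they rest on, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Pipeline model

The package analyzes a germplasm collection of a clonally propagated,
outcrossing diploid crop, genotyped at genome-wide biallelic SNPs coded as
allele dosages (0/1/2, missing allowed). The core assumption is that two
samples of the same clone differ only through observation noise — miscalled
heterozygotes from low sequencing depth, occasional somatic mutations
between plants of one clone, and missing calls — while distinct clones,
being products of sexual recombination, differ at a large fraction of
loci. Deduplication is therefore a threshold problem: within-clone
distances cluster near zero, between-clone distances cluster far away, and
known replicate pairs locate the boundary empirically.

### Quality control

Loci are dropped when more than `max_missing` (default 0.05) of calls are
missing, when monomorphic, or when the minor allele frequency
`min(p, 1−p)` with `p = Σg / (2 n_called)` falls below `min_maf` (default
0.05). Removal is attributed to the first failing filter in the order
missing → monomorphic → MAF, so report counts partition the removed loci. A
locus whose every call is heterozygous carries both alleles and is *not*
monomorphic. Samples with more than 5.5% missing calls over the retained
loci are then dropped. Filters run once, in that order, with no iteration
to a fixed point: iterating would make the removal counts depend on the
iteration order and is not how such panels are curated in practice.
Missing data is never imputed for distance computation — with highly
diverse material, imputation would shrink genuine differences.

### Distance and clone calling

The normalized Hamming distance `d(i,j) = Σ_l |g_il − g_jl| / (2 n_ij)`
uses pairwise-complete deletion (`n_ij` = loci called in both samples).
This is robust to per-sample missingness but means the triangle inequality
is not guaranteed; the package asserts symmetry and the [0, 1] range
instead. The implementation decomposes `|g_i − g_j|` over dosage-state
indicator matrices, reducing the full matrix to six matrix products whose
integer-valued sums are exact in double precision — it agrees cell-for-cell
with a brute-force double loop.

The duplicate threshold is the smallest multiple of `granularity` (default
0.001) strictly greater than the maximum distance observed among known
replicate pairs, so every known replicate pair satisfies `d < threshold`.
Clone groups are connected components of the sub-threshold graph — single
linkage, making clone identity transitive, which matches how a dendrogram
cut at a fixed height groups leaves. Representatives minimize missing
calls, with lexicographic tie-breaks for determinism.

Zone accounting counts *collection events*: replicate re-entries of one
accession collapse to a single entry, a clone found in k zones counts once
in each, and collected samples identical to a reference breeding line are
struck from landrace uniqueness counts (an improved variety mistaken for a
landrace is not a landrace).

### Diversity and differentiation

Shannon's index is computed on clone-abundance counts per zone in natural
log units; with k clones observed it is bounded by ln k, reached at uniform
abundances. Pairwise Fst defaults to Weir & Cockerham's (1984) θ as a
multilocus ratio of averages `Σa / Σ(a+b+c)`, using per-locus sample
sizes, allele frequencies and observed heterozygote proportions; loci
uncalled in either zone of a pair are skipped, as are loci where the pooled
called count is ≤ 2 (the variance components are undefined there). Small
negative θ estimates are legitimate under no differentiation and are not
clipped. A plain Nei Gst estimator (`1 − ΣHs/ΣHt`, ratio of sums) is
provided as an alternative. By default both run on the deduplicated set —
one representative per clone per zone — because clonal copies are
pseudo-replicates of one genotype and would deflate within-zone variance; a
flag restores all-sample behaviour for comparison.

Nei's (1972) standard distance aggregates identity sums across loci before
the ratio (`I = J_xy / √(J_x J_y)`, `D = −ln I`): per-locus aggregation is
undefined at fixed differences, ratio-of-sums is not. `D` is clamped at a
configurable maximum (default 10) when `I` underflows. The zone tree is
Saitou–Nei neighbor joining with the Studier–Keppler Q criterion; negative
branch lengths are clamped to zero with the deficit moved to the sister
branch, preserving the joined pair's path length. On tree-additive input
the result reproduces the input distances to ~1e-9.

### Structure

Ordination needs complete data, so missing dosages are mean-imputed per
locus (imputed cells sit at the locus centroid and add no variance); loci
are centered but not scaled, the default of the standard DAPC tooling.
PCA eigenvalues come from an SVD of the centered matrix and equal the
sample-covariance eigenvalues; variance fractions are reported over all
computed axes and sum to 1. DAPC fits a linear discriminant analysis on
the retained principal-component scores with zones as priors, yielding at
most (groups − 1) discriminant functions; groups of one sample are
rejected because the within-group covariance is undefined. The sample
dendrogram defaults to UPGMA (ultrametric, so a fixed-height duplicate cut
is meaningful), with NJ as an option. The minimum spanning network is
built over clone representatives; every non-tree edge that ties (within
1e-9) the heaviest edge on its tree path — i.e. could replace it in another
minimum spanning tree — is retained as a reticulation.

### Survey analysis

A landrace is *dual purpose* when fresh consumption and flour processing
both appear anywhere among its ranked uses; fresh or flour alone classify
accordingly; neither gives *unknown*. Free-text use vocabulary is
normalized ("household food roots" → fresh consumption, "household food
processed" → flour). Trait scores use 0 as a "don't know" code; the
default correlation policy treats 0 as missing with pairwise-complete
deletion, because a don't-know is not a quality judgment — a flag includes
the zeros for sensitivity analysis, and this is the main ambiguity of the
survey design. Percentages are rounded half-up to match the integer
reporting style; raw values are always emitted alongside. Land-size and
years-growing bands are <1, 1–4.9, 5–9.9, ≥10 acres and <5, 5–19, 20–49,
≥50 years, with "not stated" kept as its own category.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Zone allele frequencies** follow the Balding–Nichols construction:
  ancestral `p ~ Uniform(0.1, 0.5)`, zone frequency
  `p_z ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with default `F = 0.05`, giving
  `E[p_z] = p`, `Var(p_z) = F p(1−p)`. Loci are independent (no linkage
  disequilibrium).
* **Clones and copies.** Ten founder clones per zone (desk scale), each a
  `Binomial(2, p_z)` multilocus genotype; copies per clone follow
  {1: 0.72, 2: 0.18, 3: 0.07, 4: 0.03}, so ~28% of clones are collected
  more than once; 7% of clones are additionally planted in a second (and
  occasionally third) zone, so cross-zone sharing statistics have known
  truth.
* **Observation channel.** Every observed copy independently miscalls each
  heterozygous locus to either homozygote with probability ε (default
  0.01, the dominant artifact of high-multiplexing sequencing at low
  depth) and loses each call with probability 0.05. The error is
  asymmetric het→hom by design; dosage errors on homozygotes are rare at
  sequencing depths where dosage calling is attempted at all.
* **Replicate design.** Four biological groups (sizes 3, 2, 2 on reference
  landraces and 2 on a breeding line) and twelve technical groups (on five
  reference landraces, four breeding lines and three collected
  accessions, one of size 3) — 20 within-group pairs in all. Biological
  extra copies mutate each locus with probability μ = 0.001 (dosage
  resampled from the zone frequency), emulating somatic divergence between
  distant plants of one clone. Technical repeat copies carry an elevated
  miscall rate (factor 2.0), reproducing the empirical pattern that
  re-genotyped material is noisier than fresh material — technical
  replicate distances then average ~1.5× biological ones.
* **References.** Half the reference landraces duplicate collected
  founders (so reference matching has planted truth), one pair of
  references shares a founder (a planted synonym pair), and one collected
  sample duplicates a breeding line (a planted mislabeled improved
  variety).
* **Survey.** Trait scores discretize a latent Gaussian with a target
  correlation matrix at equal-probability quintile cuts; discretization
  attenuates correlations by ≈ 0.89, so the default latent cooking–taste
  correlation of 0.92 yields an observed ≈ 0.82. Each score independently
  becomes "don't know" (0) with probability 0.08. Zone-specific
  fresh-vs-flour primary-use propensities and a dual-purpose secondary-use
  rate of 0.354 put the expected use classes near 38/34/24/4% for
  fresh/dual/flour/unknown.
* **Determinism.** One root seed; frequencies, population design,
  observation noise and the survey draw from separate seed substreams, so
  components can be re-run independently yet reproducibly.

What the generator does **not** emulate: linkage disequilibrium, locus- or
sample-specific error-rate heterogeneity beyond the technical factor,
genotype-dependent missingness, pedigree relatedness between distinct
clones (all founders are unrelated draws), or free-text survey noise.
Passing tests on synthetic data therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every artifact
of a real genotyping campaign — in real panels, close pedigree relatives
(parent–offspring from the soil seed bank) are the main threat to a clean
threshold gap and must be reviewed on the dendrogram.

## Numerical choices

* Distances are exact rational sums; no tolerance is needed for the
  brute-force equivalence.
* Distance-matrix symmetry is enforced on read within 1e-8; MSN tie
  detection uses 1e-9; NJ negative-branch clamping moves the deficit to
  the sister branch so path lengths are preserved.
* Threshold calibration rounds *up* to the next granularity multiple using
  a 1e-9-rounded quotient, so a maximum lying exactly on a multiple still
  moves strictly above.
* Q-criterion and linkage ties break toward the smallest indices; group
  ids order by smallest member id — all outputs are deterministic.

## Known limitations

* **Calibration margin at desk scale.** With 1000 loci the per-pair noise
  standard deviation of within-clone distances (≈ 0.0015) exceeds the
  0.001 calibration granularity, so a max-of-20-replicate-pairs threshold
  covers the ~30 same-distribution duplicate pairs of a default collection
  in most but not all datasets: the acceptance script's
  `clone_recovery_rate_20_seeds` typically reports 0.90–0.95, with
  failures being single split duplicate pairs a few ten-thousandths above
  the cutoff. The margin grows as `1/√L`: at the 20,000-locus scale of a
  real campaign the same rule is ~3× safer relative to noise. Users
  calibrating on few replicate pairs should prefer more pairs over a finer
  granularity.
* Pairwise-complete distances can violate the triangle inequality under
  extreme missingness patterns.
* The Nei Gst option is the plain estimator without small-sample bias
  correction; use WC84 (the default) for small per-zone sample sizes.
* DAPC assignment accuracies are in-sample (no cross-validation) and
  optimistic when many axes are retained relative to sample count.
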