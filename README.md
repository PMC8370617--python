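# landracekit

Genotype-based deduplication and diversity analysis of clonal crop
germplasm collections.

## The problem

National germplasm collection campaigns for clonally propagated crops
(cassava being the motivating case) gather hundreds of named landraces from
farmers' fields. Names are unreliable: the same clone circulates under many
local names, and distinct clones share names. Before a collection can be
conserved, deduplicated and characterized, every accession must be
fingerprinted — typically with genome-wide SNP dosages — and samples must be
partitioned into *clones* (identical multilocus genotypes up to genotyping
noise). landracekit is a toolkit for curators, breeders and population
geneticists who run that analysis: SNP quality control, pairwise genetic
distances, replicate-calibrated clone calling, per-zone sharing and
diversity accounting, population structure, and analysis of the farmer
survey data collected alongside the plants.

## The methods

* **Distance.** For diploid allele dosages `g ∈ {0,1,2}` the normalized
  Hamming distance is `d(i,j) = Σ_l |g_il − g_jl| / (2 n_ij)`, summed over
  loci called in both samples (`n_ij` of them). A heterozygote/homozygote
  mismatch counts 1 allele, opposite homozygotes count 2.
* **Clone calling.** Known biological and technical replicate pairs give an
  empirical ceiling for within-clone distance; the duplicate threshold is
  the smallest multiple of 0.001 strictly above the maximum replicate
  distance. Clone groups are connected components of the graph with an edge
  wherever `d < threshold` (single linkage), with one representative per
  group (fewest missing calls, ties by id).
* **Diversity and differentiation.** Shannon's `H = −Σ p_i ln p_i` on clone
  abundances per zone; pairwise Fst between zones as Weir & Cockerham's
  (1984) multilocus θ (ratio of averages of variance components `a/(a+b+c)`),
  with a Nei Gst option; Nei's (1972) standard distance
  `D = −ln(J_xy / √(J_x J_y))` between zone allele-frequency profiles; and an
  unweighted neighbor-joining tree of zones.
* **Structure.** PCA of centered dosages; DAPC (linear discriminant analysis
  on retained principal components with zones as priors); UPGMA/NJ
  dendrograms; and a minimum spanning network over multilocus genotypes with
  tied alternative edges kept as reticulations.
* **Survey.** Use classification (fresh / dual-purpose / flour / unknown)
  from ranked uses, 0–5 trait-score distributions ("0 = don't know"),
  pairwise Pearson correlations between traits, and respondent profiles.
* **Synthetic data.** A generator produces zone-structured genotypes under
  the Balding–Nichols model (`p_z ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`), clonal
  copies with heterozygote-miscall and missingness channels, a realistic
  replicate design, and correlated ordinal survey scores — together with the
  true clone partition, so recovery is measurable exactly.

## Worked example

```python
from landracekit import (
    SimulationConfig, simulate_population, run_qc, hamming_distance,
    replicate_pair_distances, calibrate_threshold, call_clones,
    evaluate_recovery, zone_summary, diversity_report,
)

cfg = SimulationConfig(seed=1)
genotypes, meta, truth = simulate_population(cfg)
genotypes, qc = run_qc(genotypes)
print(f"{qc.n_snps_out} of {qc.n_snps_in} SNPs retained after QC")

dist = hamming_distance(genotypes)
reps = replicate_pair_distances(dist, meta)
threshold = calibrate_threshold(reps.distances)
print(f"max replicate distance {max(reps.distances):.5f} -> cutoff {threshold}")

clones = call_clones(dist, threshold, G=genotypes)
summary = zone_summary(clones, meta)
print(f"{summary.n_unique_excl_references} unique landraces "
      f"({evaluate_recovery(clones, truth).ari:.2f} ARI vs simulated truth)")

report = diversity_report(genotypes, clones, meta)
print("max pairwise Fst:", report.fst.max().max().round(3))
```

prints

```
537 of 1000 SNPs retained after QC
max replicate distance 0.01104 -> cutoff 0.012
70 unique landraces (1.00 ARI vs simulated truth)
max pairwise Fst: 0.062
```

Reading: of 1000 simulated SNPs, 537 survive the missingness / monomorphy /
minor-allele-frequency filters. The 20 replicate pairs bound genotyping
noise at 0.01104, so any sample pair closer than 0.012 is the same clone;
the 119 collected samples collapse to 70 unique landraces, exactly matching
the generator's planted truth (adjusted Rand index 1.0). Zone
differentiation peaks at Fst ≈ 0.06, close to the simulated F = 0.05.

The same pipeline runs from the shell:

```sh
landracekit simulate --seed 1 --out-dir sim/
landracekit qc    --dosage sim/dosage.csv --out-dosage qc.csv --report qc.json
landracekit dist  --dosage qc.csv --out dist.csv
landracekit clones --distance dist.csv --metadata sim/metadata.tsv \
    --dosage qc.csv --out-dir clones/
landracekit diversity --dosage qc.csv --metadata sim/metadata.tsv \
    --partition clones/partition.tsv --out-dir diversity/
landracekit survey --survey sim/survey.tsv --out-dir survey/
```

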