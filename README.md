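# lakerad

Population genomics of marine-lake metapopulations from ddRAD data.

Marine lakes are landlocked bodies of seawater connected to the adjacent sea
only through caves or porous rock. Because the lakes formed together after
the Last Glacial Maximum (~8,000–10,000 years ago) and differ in how strongly
they exchange water with the sea, they act as natural replicates for asking
what structures populations of poorly dispersing benthic animals such as
sponges: geographic distance (isolation-by-distance), local environment
(isolation-by-environment), the permeability of the seascape barrier
(isolation-by-resistance), or founder events followed by drift and priority
effects.

`lakerad` implements the full analysis chain for this design, plus a
synthetic-data generator with exact truth tables so every stage is testable
without any sequencing data:

1. **`synthetic_data`** — coalescent simulation (msprime) of a sea source
   population seeding lake populations through founder bottlenecks, with
   lake–sea migration scaled by the tidal-connection fraction c ∈ [0, 1];
   ddRAD loci flanked by the SphI cut-site remnant (`GCATGC`); barcoded
   150 bp single-end reads with per-base errors and negative-binomial depth;
   planted GC-rich contaminant loci and low-complexity repeat loci; lake
   metadata tables.
2. **`rad_assembly`** — demultiplexing (≤1 barcode mismatch, cut-site
   validation), adapter/quality trimming, greedy identity clustering into
   loci (min. 3 reads), DUST-style low-complexity masking and the >60%-N
   rule, a de novo reference from loci shared by ≥70% of individuals, a
   >55%-GC contaminant screen plus exact k-mer screen, and unique gapless
   read assignment.
3. **`genotyping`** — genotype likelihoods under a symmetric error model,
   EM allele frequencies, posterior calls under a Hardy–Weinberg prior
   (posterior ≥ 0.95), indel-window/depth-percentile/missingness site
   filters, one-random-SNP-per-locus thinning, and the
   {3×, 10×} × {30%, 10%, 5%, 1%} coverage–missingness sensitivity grid.
4. **`popgen_stats`** — π, He, Ho; pairwise Nei G<sub>ST</sub> and the
   standardized fixation index G″<sub>ST</sub> (F′<sub>ST</sub>) with
   permutation p-values; hierarchical AMOVA (1000 permutations); PCA on the
   genotype covariance matrix; folded site-frequency spectra; relative
   directional migration networks (migrant-pool construction, threshold
   0.2, 1000 bootstraps).
5. **`demography`** — exact expected SFS under piecewise-constant N<sub>e</sub>
   and a stairway-style composite-likelihood fit with a 12.5/87.5%
   bootstrap envelope (μ = 1.1 × 10⁻⁸ per site per generation, generation
   time 1 year).
6. **`seascape`** — tidal-amplitude fractions and connection categories
   (low ≤ 0.4, medium 0.5–0.7, high 0.8–1, lagoons "open"); geographic
   (haversine), environmental (PCA on standardized temperature/salinity),
   and connection-resistance distance matrices; Mantel tests
   (10,000 permutations, exact enumeration for small matrices) on
   linearized genomic distance F′<sub>ST</sub>/(1−F′<sub>ST</sub>);
   Spearman correlations of diversity with lake predictors.
7. **`io` / `pipeline` / `cli`** — FASTQ/FASTA/VCF/TSV/GraphML round-trips,
   a single-config pipeline driver with a provenance manifest, and the
   `lakerad` command-line tool.

## The statistics at the core

Pairwise differentiation uses Nei's G<sub>ST</sub> = (H_T − H_S)/H_T from
sample-size-corrected gene diversities, standardized as (k = 2):

    G''_ST = k (H_T − H_S) / ((k H_T − H_S)(1 − H_S))

so that within-population diversity no longer bounds the index. The expected
unfolded SFS under piecewise-constant N_e(t) with n sampled alleles is

    E[ξ_i] = μ L Σ_k  k E[T_k] P(i|k),
    P(i|k) = C(n−i−1, k−2) / C(n−1, k−1),

with E[T_k] computed exactly by epoch-wise integration of the lineage-count
death chain (matrix exponentials); the stairway fit maximizes the Poisson
composite likelihood of the folded bins over per-epoch N_e.

## Worked example

Summaries of the packaged Indo-Pacific marine-lake survey, and a two-lake
simulation showing how connection shapes differentiation:

```python
import numpy as np
from lakerad import (DemographyConfig, simulate_metapopulation, truth_genotype_calls,
                     pairwise_fst, summarize_profiles, INDO_PACIFIC_SURVEY)

summary = summarize_profiles(INDO_PACIFIC_SURVEY)
print(f"lake temperature: {summary['lake_temperature_mean']:.1f} +/- {summary['lake_temperature_sd']:.1f} C")
print(f"lake salinity:    {summary['lake_salinity_mean']:.1f} +/- {summary['lake_salinity_sd']:.1f} ppt")
print(f"individuals passing QC: {summary['total_individuals']}"
      f" (lineage B: {summary['individuals_per_lineage']['B']})")
print(f"connection categories: {summary['category_counts']}")

cfg = DemographyConfig(
    n_lakes=2, n_sea=1, founder_size=500, ancestral_size=10_000,
    founding_time=9000.0, migration_rate_base=1e-3,
    connection_scaling={"lake1": 0.1, "lake2": 0.8},
    mutation_rate=5e-7, n_loci=200, locus_length=138,
    n_contaminant=0, n_repeat=0, seed=42,
)
sample = simulate_metapopulation(cfg, {"sea1": 8, "lake1": 8, "lake2": 8})
calls = truth_genotype_calls(sample)
labels = {i: sample.populations[i] for i in sample.individuals}
fst = pairwise_fst(calls, labels, n_perm=99, seed=0)
print("standardized F'ST (G''ST):")
print(fst["fst_std"].round(3))
```

prints

```
lake temperature: 30.8 +/- 1.2 C
lake salinity:    27.3 +/- 2.7 ppt
individuals passing QC: 125 (lineage B: 105)
connection categories: {'low': 4, 'medium': 3, 'high': 2}
standardized F'ST (G''ST):
       lake1  lake2   sea1
lake1  0.000  0.790  0.667
lake2  0.790  0.000  0.113
sea1   0.667  0.113  0.000
```

The nine lakes are warmer and fresher than the lagoons (30.8 ± 1.2 °C and
27.3 ± 2.7 ppt versus 29 °C and 33.5 ppt), and of 125 individuals passing
QC, 105 belong to lineage B. In the simulation, the weakly connected lake
(c = 0.1) is strongly differentiated from the sea (F′ST ≈ 0.67) after nine
millennia at founder size, while the well-connected lake (c = 0.8) stays
close to it (F′ST ≈ 0.11).

The full pipeline runs from a shell:

```
lakerad init-config --out config.yaml --seed 1
lakerad all --config config.yaml --out run/
```

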