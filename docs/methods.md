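# Methods

This note documents the models behind `lakerad`, the defaults and why they
were chosen, the numerical decisions, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Demographic model of the synthetic metapopulation

The generator emulates post-glacial marine-lake formation. Backwards in
time, every lake population merges into the first sea population at
`founding_time` (default 9,000 years; lakes formed ~8,000–10,000 years
ago), before which only the sea populations exist; additional sea
populations split from the first at `sea_split_time` (default 50,000
years). Forwards in time this is a star-shaped founder scenario: each lake
is seeded from the sea and then persists at `founder_size` diploids
(default 500), a sustained bottleneck relative to the sea's
`ancestral_size` (default 10,000). Migration between a lake and the sea is
`migration_rate_base * c`, where c is the lake's tidal-amplitude fraction —
this encodes the isolation-by-resistance hypothesis the seascape module
tests. The default base rate of 10⁻³ per generation represents a weakly
connected metapopulation; experiments that need a no-migration or
strongly-connected scenario set it explicitly.

Key genetic defaults are the field-standard values for the system: mutation
rate 1.1 × 10⁻⁸ per site per generation (regression-based estimate for a
~300 Mb sponge genome), generation time 1 year. Simulations are coalescent
(msprime), one non-recombining locus per RAD tag, with binary mutations
mapped onto random locus sequences as ancestral/derived bases. Truth tables
(per-population derived-allele frequencies, pairwise Hudson F_ST as a
ratio of averages, and the configured N_e trajectories) are computed from
the realized sample, so downstream estimators can be validated exactly.

Some desk-scale experiments raise the mutation rate (e.g. 2–5 × 10⁻⁷) so
that a few hundred short loci yield order-10³ SNPs; this rescales θ without
changing the shape of any statistic being tested, and each experiment
states the rate it uses.

## ddRAD library model

Loci are `SphI` remnant (`GCATGC`) plus a 138 bp body (150 bp reads minus a
6 bp inline barcode), matching single-end ddRAD reads that start at the
rare-cutter site. Host loci are drawn at ~40% GC and rejected above 52%, so
every host locus is at or below the 55% GC screen; planted contaminants are
drawn above 60% GC, giving the screen a known answer. Planted repeat loci
are perfect dinucleotide repeats that the DUST-style masker must remove.
Per-(individual, locus) depth is negative binomial with mean 20 (the
pipeline preset; field libraries in this design average ~24×, with a
3–82× range motivating the overdispersion, dispersion default 5). Errors
are independent per-base substitutions (default 0.005); quality strings
encode the error rate as a constant Phred score. Not emulated: PCR
duplicates, paired ends, quality-score variation along the read, indel
sequencing errors, reference bias, or real contaminant genomes — so
passing tests demonstrate correctness of the algorithms under the stated
error model, not robustness to every artifact of real libraries. Declared
indel truth positions exercise the indel-window site filter without
introducing alignment gaps (read assignment is gapless by design).

## Assembly decisions

- Greedy centroid clustering at identity 0.90 (configurable); reads are
  processed in abundance-then-lexicographic order and join the first
  centroid at or above the threshold, which makes the catalog independent
  of input read order.
- Consensus is per-column majority with `N` on ties.
- Sharing rule: a locus enters the reference iff present in ≥ 70% of
  individuals (fraction comparison, applied before the contaminant
  screens, following the stage order of the processing chain).
- DUST-style masking: triplet redundancy score over 64 bp windows,
  threshold 2.0; windows above threshold become `N`; the >60%-N rule then
  discards mostly-masked loci (kept at exactly 60%). N triplets are not
  re-scored, so masking is stable under repetition.
- Read assignment is gapless, anchored at coordinate 0, unique-best with
  ≤ 5 mismatches; masked reference positions are wildcards. Ties are
  discarded as multi-mapping, mirroring a uniquely-mapping-reads policy.

## Genotyping decisions

The error model is the symmetric GATK-style likelihood
P(b|g) = (g/2)·p_alt + (1−g/2)·p_ref with p_x = 1−ε or ε/3 (ε default
0.01, fixed rather than read from quality strings — only relative
posteriors at the 0.95 threshold matter downstream). Candidate sites need
a pooled alternate count of ≥ 2; a third allele above 20% of site depth
marks a multi-allelic site, which is dropped and logged. Allele
frequencies are a per-site EM fixed point (tolerance 10⁻⁸, ≤ 100
iterations) over individuals with nonzero depth; the HWE prior uses the
global (not per-population) frequency, mirroring reference-panel-free
usage. Calls require posterior ≥ 0.95 and depth ≥ 3 (or 10 in the strict
grid arm). Site filters run in a fixed order: declared-indel window
(±10 bp), pooled site depth outside the nearest-rank [1st, 99th]
percentiles, missingness above the threshold, and monomorphic-after-
calling. The grid {3×, 10×} × {30%, 10%, 5%, 1%} is nested by
construction, so SNP counts are provably monotone along both axes.

## Population statistics

- H_S and H_T use the small-sample corrections (2n/(2n−1) within
  populations; H_T adds H_S/(2 ñ k) with ñ the harmonic mean sample
  size). Multi-locus ratios are ratios of averages.
- The standardized index is the recommended G″_ST computed pairwise
  (k = 2): G″_ST = k(H_T−H_S)/((kH_T−H_S)(1−H_S)). Negative estimates are
  clamped to 0 and recorded; monomorphic pairs are NaN with a flag.
- AMOVA uses squared Euclidean distance on 0/1/2 allele counts with
  pairwise-complete loci, Excoffier-style sums of squares and
  unequal-sample-size coefficients, and the standard permutation schemes
  (individuals among populations within groups; whole populations among
  groups). Reported components are truncated at zero with a warning, but
  permutation p-values compare the *raw* Φ statistics — truncation puts an
  atom at zero that would otherwise make null p-values non-uniform.
- PCA centers per site, mean-imputes missing cells, and eigendecomposes
  the individual covariance; optional 1/√(p(1−p)) standardization.
- The relative migration network uses the hypothetical-migrant-pool
  construction: for each ordered pair, the pool has the mean allele
  frequencies, and migration into a population is the Wright Nm implied by
  the (frequency-based, uncorrected) G_ST between that population and the
  pool; all directed values are divided by the global maximum, edges below
  0.2 are dropped, and bootstrap support over loci is the fraction of
  replicates in which the re-normalized edge stays above the threshold.

## Demographic inference

The expected SFS under piecewise-constant N_e is exact: within each finite
epoch, occupancy times of the lineage-count death chain come from an
augmented matrix exponential; the infinite last epoch contributes 1/λ_k
per reachable state. The fit fixes breakpoints at pair-coalescence
quantiles of a constant-N_e pilot (Watterson) and optimizes per-epoch
log₁₀ N_e (L-BFGS-B, bounds 10¹–10⁸) against a *Poisson* composite
likelihood of the folded bins given μL. A multinomial likelihood
conditional on S was considered and rejected: a constant trajectory has
scale-invariant folded proportions, so conditioning on S leaves a flat
ridge along uniform rescalings of N_e and the overall scale would be
unidentifiable. A mild smoothness penalty on adjacent log₁₀ N_e
differences (weight 1.0, roughly 10⁻³ of the data term at typical S) ties
epochs beyond the sample's coalescent horizon to their neighbors — the
package's analogue of the model selection full stairway implementations
perform; it vanishes on constant trajectories, so the self-consistency
check is unaffected. Bootstraps resample segregating sites (multinomial over
bins at fixed S) and refit; after one-SNP-per-locus thinning this
coincides with resampling loci. The envelope is the 12.5/87.5 percentile
band, clipped to bracket the point estimate.

Resolution caveat: breakpoints from an inflated pilot N_e make the most
recent epoch wide, so a bottleneck's *timing* is recovered only at epoch
granularity; its *magnitude* (post-founding vs pre-founding N_e) is the
robust signal, and that is what the recovery experiment asserts. The
experiment uses a 20× bottleneck (10,000 → 500) at 400 generations: at the
lakes' actual ~9,000-generation age with N_e = 500, essentially no sampled
lineage survives into the pre-founding era (P ≈ e⁻⁹), so no SFS method
could recover the ancestral size — the recent bottleneck scenario is the
identifiable analogue.

## Seascape analysis

Connection categories follow the survey thresholds (low ≤ 0.4, medium
0.5–0.7, high 0.8–1, lagoons "open"); fractions in the scheme's gaps
((0.4, 0.5), (0.7, 0.8)) are flagged and assigned to the nearer band.
The connection-resistance distance is d(i,j) = ((1−c_i)+(1−c_j))/2 — the
source equation for this distance lives in prior work and is not fully
specified here, so the implemented form is the documented mean of
isolation scores, which honors the required ordering (isolated pairs
farthest, open pairs at zero, mixed pairs in between) and is configurable.
Geographic distances are great-circle (haversine, R = 6,371,000 m);
least-cost sea paths are out of scope. Environmental distance is Euclidean
on all PCA axes of z-scored temperature and salinity (a rotation, hence
equal to z-score distance — kept as PCA to allow more variables). The
Mantel test is one-sided (positive association) with the add-one
permutation estimator; an exact mode enumerates all label permutations for
small matrices. Spearman correlations use tie-corrected ranks, with
|ρ| ≥ 0.5 flagged strong and α = 0.01.

The packaged `INDO_PACIFIC_SURVEY` table records the nine-lake/two-lagoon
reference survey (coordinates are not included there; geographic tests use
generated or user-supplied coordinates). One lake has no tidal-fraction
measurement and is excluded from connection matrices with a warning; its
category comes from the survey.

## Problem sizes in tests and the acceptance script

The suite and `scripts/acceptance.py` use desk-scale sizes chosen to keep
each check sharp but cheap: the end-to-end preset is 4 lakes + 1 sea,
500 loci, 10 individuals per population at 20× mean depth; Watterson and
SFS oracles use 8,000–10,000 short loci; the bottleneck recovery runs 20
(tests) or 10 (script) seeded replicates; Mantel calibration uses 500
(tests) or 200 (script) independent-matrix replicates at 199 permutations;
AMOVA null calibration uses 500 replicates at 99 permutations. All
randomness is seeded; the pipeline manifest records every seed and
threshold, and identical configs give byte-identical manifests.

## Known limitations

- Gapless assignment cannot place reads from indel-bearing haplotypes;
  indels are handled only as declared positions for site masking.
- The genotype-likelihood model ignores per-base quality variation and
  mapping quality.
- Stairway-style epochs are fixed after the pilot fit rather than
  re-estimated; very recent demographic events are smoothed into the first
  epoch.
- The migrant-pool migration network is a relative measure; absolute
  migration rates are not identified, and the GST variant is the only one
  implemented.
- AMOVA excludes missing genotypes pairwise without rescaling locus
  counts, which slightly down-weights individuals with much missing data.
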