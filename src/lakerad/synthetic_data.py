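"""Synthetic marine-lake metapopulations and ddRAD libraries.

This module generates everything the downstream pipeline consumes, with a
known truth: a coalescent metapopulation (one or more open-sea source
populations seeding lake populations through founder events, with
connection-scaled lake-sea migration), ddRAD locus sequences flanked by an
SphI cut-site remnant, barcoded single-end reads with a per-base error
model and negative-binomial per-locus depth, planted GC-rich contaminant
loci and low-complexity repeat loci, and lake metadata tables in the style
of field surveys of Indo-Pacific marine lakes.

The demographic scenario emulated is post-glacial lake formation: each lake
splits from a sea population ``founding_time`` years ago and persists at a
small founder size, so lake samples carry the signature of a sustained
bottleneck.  Migration between a lake and the sea is the base rate
multiplied by the lake's tidal-connection fraction c in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .rad_assembly import ReadRecord

__all__ = [
    "DemographyConfig",
    "SyntheticGenome",
    "MetapopulationSample",
    "simulate_metapopulation",
    "truth_genotype_calls",
    "generate_ddrad_reads",
    "generate_lake_metadata",
    "SPHI_SITE",
    "MLUCI_SITE",
]

# restriction enzyme recognition motifs (standard definitions)
SPHI_SITE = "GCATGC"
MLUCI_SITE = "AATT"

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_IDX[_b] = _i


@dataclass
class DemographyConfig:
    """Demographic and genomic parameters of the synthetic metapopulation.

    Defaults encode the study conditions this generator emulates: nine
    marine lakes and two sea (lagoon) populations, lakes founded ~9000
    years ago (1-year generation time) after the Last Glacial Maximum,
    a per-generation mutation rate of 1.1e-8, and per-lake founder
    bottlenecks.

    ``connection_scaling`` maps each lake name to its tidal-connection
    fraction c in [0, 1]; lake-sea migration is
    ``migration_rate_base * c`` (c = 1 for sea-sea migration).
    """

    n_lakes: int = 9
    n_sea: int = 2
    founding_time: float = 9000.0  # years before present
    founder_size: int = 500  # diploid Ne per lake after founding
    ancestral_size: int = 10_000  # diploid Ne of sea populations
    migration_rate_base: float = 1e-3  # per-generation migrant fraction
    connection_scaling: dict = field(default_factory=dict)
    mutation_rate: float = 1.1e-8  # per site per generation
    generation_time: float = 1.0  # years
    seed: int = 1
    # genome / library structure
    n_loci: int = 500
    locus_length: int = 138  # locus body length, excluding the cut remnant
    n_contaminant: int = 10
    n_repeat: int = 5
    sea_split_time: float = 50_000.0  # years; seas share an ancestor here

    def __post_init__(self) -> None:
        if self.founder_size < 1:
            raise ValueError("founder_size must be >= 1")
        for name, val in (
            ("migration_rate_base", self.migration_rate_base),
            ("mutation_rate", self.mutation_rate),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for lake, c in self.connection_scaling.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"connection value for {lake} must be in [0, 1]")

    @property
    def sea_names(self) -> list:
        return [f"sea{i + 1}" for i in range(self.n_sea)]

    @property
    def lake_names(self) -> list:
        return [f"lake{i + 1}" for i in range(self.n_lakes)]

    @property
    def population_names(self) -> list:
        return self.sea_names + self.lake_names

    def connection(self, pop: str) -> float:
        if pop in self.sea_names:
            return 1.0
        return self.connection_scaling.get(pop, 1.0)


@dataclass
class SyntheticGenome:
    """RAD locus sequences plus planted-problem bookkeeping.

    Every locus begins with the SphI cut-site remnant; host loci have GC
    fraction <= 0.55 and contaminant loci strictly > 0.55, so the GC screen
    downstream has a known answer.  ``truth_variants`` maps locus id to a
    list of (position, ancestral base, derived base); ``truth_indels`` maps
    locus id to a declared indel position (for the indel-window site
    filter).
    """

    loci: dict  # locus_id -> full sequence (remnant + body)
    contaminant_ids: set
    repeat_ids: set
    truth_variants: dict
    truth_indels: dict = field(default_factory=dict)

    @property
    def host_ids(self) -> list:
        return [
            lid
            for lid in self.loci
            if lid not in self.contaminant_ids and lid not in self.repeat_ids
        ]


@dataclass
class MetapopulationSample:
    """Realized sample: haplotypes at each locus plus exact truth tables."""

    config: DemographyConfig
    genome: SyntheticGenome
    individuals: list  # individual labels; haplotypes 2i, 2i+1 belong to i
    populations: dict  # individual -> population name
    # locus_id -> (n_haplotypes, locus_length) uint8 ASCII matrix (host loci)
    haplotypes: dict
    truth_frequencies: pd.DataFrame  # locus, position, population, derived_freq
    truth_fst: pd.DataFrame  # pairwise Hudson FST from realized frequencies
    truth_ne: pd.DataFrame  # population, time_years, Ne

    def haplotype_pair(self, individual: str, locus_id: str) -> np.ndarray:
        i = self.individuals.index(individual)
        return self.haplotypes[locus_id][2 * i : 2 * i + 2]


# ---------------------------------------------------------------------------
# genome construction


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASE_ARR[idx].tobytes().decode("ascii")


def _bounded_gc_sequence(
    rng: np.random.Generator, length: int, gc: float, lo: float, hi: float
) -> str:
    """Random sequence with realized GC fraction inside (lo, hi]."""
    for _ in range(1000):
        seq = _random_sequence(rng, length, gc)
        frac = (seq.count("G") + seq.count("C")) / length
        if lo < frac <= hi:
            return seq
    raise RuntimeError("could not draw sequence with requested GC bounds")


def generate_genome(config: DemographyConfig, rng: np.random.Generator) -> SyntheticGenome:
    """Host, contaminant, and repeat locus sequences with known labels."""
    loci: dict = {}
    contaminants: set = set()
    repeats: set = set()
    body = config.locus_length
    for i in range(config.n_loci):
        lid = f"H{i:05d}"
        # remnant itself is GC-rich; keep the full locus at <= 0.55 GC
        seq = SPHI_SITE + _bounded_gc_sequence(rng, body, 0.40, 0.0, 0.52)
        loci[lid] = seq
    for i in range(config.n_contaminant):
        lid = f"C{i:05d}"
        seq = SPHI_SITE + _bounded_gc_sequence(rng, body, 0.68, 0.60, 1.0)
        loci[lid] = seq
        contaminants.add(lid)
    for i in range(config.n_repeat):
        lid = f"R{i:05d}"
        unit = "AT" if i % 2 == 0 else "CA"
        seq = (SPHI_SITE + unit * (body // 2 + 1))[: body + len(SPHI_SITE)]
        loci[lid] = seq
        repeats.add(lid)
    # verify contaminant separability by construction
    from .rad_assembly import gc_fraction

    for lid, seq in loci.items():
        frac = gc_fraction(seq)
        if lid in contaminants:
            assert frac > 0.55
        elif lid not in repeats:
            assert frac <= 0.55
    return SyntheticGenome(
        loci=loci,
        contaminant_ids=contaminants,
        repeat_ids=repeats,
        truth_variants={},
    )


# ---------------------------------------------------------------------------
# coalescent simulation


def build_demography(config: DemographyConfig) -> msprime.Demography:
    gen = config.generation_time
    dem = msprime.Demography()
    for name in config.sea_names:
        # sea1 is the ancestral side of the splits; keep it active from t=0
        dem.add_population(
            name=name, initial_size=config.ancestral_size, initially_active=True
        )
    for name in config.lake_names:
        dem.add_population(name=name, initial_size=config.founder_size)
    if config.n_lakes:
        dem.add_population_split(
            time=config.founding_time / gen,
            derived=config.lake_names,
            ancestral="sea1",
        )
    if config.n_sea > 1:
        dem.add_population_split(
            time=config.sea_split_time / gen,
            derived=config.sea_names[1:],
            ancestral="sea1",
        )
    for lake in config.lake_names:
        rate = config.migration_rate_base * config.connection(lake)
        if rate > 0:
            dem.set_symmetric_migration_rate([lake, "sea1"], rate)
    if config.n_sea > 1 and config.migration_rate_base > 0:
        for i, a in enumerate(config.sea_names):
            for b in config.sea_names[i + 1 :]:
                dem.set_symmetric_migration_rate([a, b], config.migration_rate_base)
    dem.sort_events()
    return dem


def simulate_metapopulation(
    config: DemographyConfig, sample_sizes: dict
) -> MetapopulationSample:
    """Simulate haplotypes at every host locus under the configured demography.

    ``sample_sizes`` maps population name -> number of diploid individuals
    sampled.  Mutations are placed by the coalescent on independent
    non-recombining loci; each segregating site is written into the locus
    body as ancestral/derived bases, and the truth tables (derived allele
    frequency per population per site, pairwise Hudson FST, and the
    configured Ne trajectories) are exact for the realized sample.
    Identical configs and seeds give identical output.
    """
    for pop, n in sample_sizes.items():
        if pop not in config.population_names:
            raise ValueError(f"unknown population {pop!r}")
        if n <= 0:
            raise ValueError(f"sample size for population {pop!r} must be positive")

    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    dem = build_demography(config)
    pops = [p for p in config.population_names if p in sample_sizes]
    samples = [
        msprime.SampleSet(sample_sizes[p], population=p, ploidy=2) for p in pops
    ]
    individuals: list = []
    populations: dict = {}
    for p in pops:
        for k in range(sample_sizes[p]):
            name = f"{p}_i{k:02d}"
            individuals.append(name)
            populations[name] = p
    n_hap = 2 * len(individuals)

    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.locus_length,
        recombination_rate=0,
        num_replicates=config.n_loci,
        random_seed=config.seed,
    )
    mut_seeds = np.random.default_rng(config.seed + 1).integers(
        1, 2**31 - 1, size=config.n_loci
    )
    remnant = SPHI_SITE
    host_ids = genome.host_ids
    haplotypes: dict = {}
    freq_rows: list = []
    pop_slices = {}
    start = 0
    for p in pops:
        pop_slices[p] = slice(2 * start, 2 * (start + sample_sizes[p]))
        start += sample_sizes[p]

    # per-pair accumulators for Hudson FST (ratio of averages over sites)
    pair_num: dict = {}
    pair_den: dict = {}

    for i, ts in enumerate(reps):
        lid = host_ids[i]
        if config.mutation_rate > 0:
            mts = msprime.sim_mutations(
                ts,
                rate=config.mutation_rate,
                random_seed=int(mut_seeds[i]),
                model=msprime.BinaryMutationModel(),
                discrete_genome=True,
            )
        else:
            mts = ts
        base = np.frombuffer(
            genome.loci[lid][len(remnant) :].encode("ascii"), dtype=np.uint8
        )
        hap = np.tile(base, (n_hap, 1))
        variants = []
        for var in mts.variants():
            pos = int(var.site.position)
            geno = np.asarray(var.genotypes)
            if geno.min() == geno.max():
                continue  # back-mutated to monomorphic
            anc = genome.loci[lid][len(remnant) + pos]
            anc_idx = int(_ASCII_TO_IDX[ord(anc)])
            der_idx = (anc_idx + int(rng.integers(1, 4))) % 4
            der = chr(int(_BASE_ARR[der_idx]))
            carriers = geno != 0
            hap[carriers, pos] = ord(der)
            variants.append((pos, anc, der))
            for p in pops:
                sl = pop_slices[p]
                freq_rows.append(
                    (lid, pos, p, float(carriers[sl].mean()))
                )
            for ai in range(len(pops)):
                for bi in range(ai + 1, len(pops)):
                    a, b = pops[ai], pops[bi]
                    pa = carriers[pop_slices[a]].mean()
                    pb = carriers[pop_slices[b]].mean()
                    na = 2 * sample_sizes[a]
                    nb = 2 * sample_sizes[b]
                    num = (
                        (pa - pb) ** 2
                        - pa * (1 - pa) / (na - 1)
                        - pb * (1 - pb) / (nb - 1)
                    )
                    den = pa * (1 - pb) + pb * (1 - pa)
                    pair_num[(a, b)] = pair_num.get((a, b), 0.0) + num
                    pair_den[(a, b)] = pair_den.get((a, b), 0.0) + den
        genome.truth_variants[lid] = variants
        haplotypes[lid] = hap

    # declared indel positions on a subset of host loci (site-filter truth;
    # sequences themselves stay gapless)
    n_indel = max(1, config.n_loci // 20) if config.n_loci else 0
    indel_loci = rng.choice(host_ids, size=min(n_indel, len(host_ids)), replace=False)
    for lid in indel_loci:
        genome.truth_indels[str(lid)] = int(
            rng.integers(10, config.locus_length - 10)
        )

    truth_frequencies = pd.DataFrame(
        freq_rows, columns=["locus", "position", "population", "derived_freq"]
    )
    fst_rows = []
    for (a, b), num in pair_num.items():
        den = pair_den[(a, b)]
        fst = num / den if den > 0 else np.nan
        fst_rows.append((a, b, fst))
    truth_fst = pd.DataFrame(fst_rows, columns=["pop1", "pop2", "hudson_fst"])

    ne_rows = []
    gen = config.generation_time
    for p in pops:
        if p in config.lake_names:
            ne_rows.append((p, 0.0, config.founder_size))
            ne_rows.append((p, config.founding_time, config.ancestral_size))
        else:
            ne_rows.append((p, 0.0, config.ancestral_size))
    truth_ne = pd.DataFrame(ne_rows, columns=["population", "time_years", "Ne"])

    return MetapopulationSample(
        config=config,
        genome=genome,
        individuals=individuals,
        populations=populations,
        haplotypes=haplotypes,
        truth_frequencies=truth_frequencies,
        truth_fst=truth_fst,
        truth_ne=truth_ne,
    )


def truth_genotype_calls(sample: MetapopulationSample):
    """Exact genotype calls (0/1/2 derived copies) at every truth variant.

    Bypasses reads and genotyping entirely; useful for statistics on the
    simulated truth itself.
    """
    from .genotyping import GenotypeCalls, Site

    sites: list = []
    cols: list = []
    n_ind = len(sample.individuals)
    for lid in sorted(sample.haplotypes):
        hap = sample.haplotypes[lid]
        for pos, anc, der in sample.genome.truth_variants[lid]:
            carrier = (hap[:, pos] == ord(der)).astype(np.int8)
            geno = carrier[0::2] + carrier[1::2]
            sites.append(Site(lid, pos, anc, der))
            cols.append(geno)
    geno = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((n_ind, 0), dtype=np.int8)
    )
    return GenotypeCalls(
        individuals=list(sample.individuals),
        sites=sites,
        genotypes=geno,
        site_depth=np.full(len(sites), 2 * n_ind),
    )


# ---------------------------------------------------------------------------
# read generation


def _apply_errors(
    mat: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent per-base substitution errors on an ASCII uint8 matrix."""
    if error_rate <= 0 or mat.size == 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return mat
    idx = _ASCII_TO_IDX[mat[mask]]
    shifted = (idx + rng.integers(1, 4, size=n_err)) % 4
    mat[mask] = _BASE_ARR[shifted]
    return mat


def generate_ddrad_reads(
    sample: MetapopulationSample,
    barcodes: dict,
    depth_mean: float = 8.0,
    error_rate: float = 0.005,
    read_length: int = 150,
    seed: int = 0,
    dispersion: float = 5.0,
):
    """Emit barcoded single-end FASTQ-style reads for every individual.

    Each read is ``barcode + cut-site remnant + locus body prefix`` cut to
    ``read_length``, with independent per-base substitution errors at
    ``error_rate`` and per-(individual, locus) depth drawn from a negative
    binomial with the given mean and dispersion (``dispersion`` is the NB
    shape; larger is closer to Poisson).  Contaminant and repeat loci are
    emitted identically for all individuals (they have no host variation).
    Quality strings encode the error model as a constant Phred score
    ``round(-10 log10 error_rate)`` (40 when ``error_rate`` is 0).

    Returns ``(reads, depth_table)`` where ``depth_table`` is a DataFrame
    (individual, locus, depth); the number of reads emitted equals the sum
    of the depth column exactly.
    """
    bl = {len(b) for b in barcodes.values()}
    if len(bl) != 1:
        raise ValueError("all barcodes must have the same length")
    (bar_len,) = bl
    if read_length < bar_len + len(SPHI_SITE):
        raise ValueError(
            "read_length shorter than barcode + cut-site remnant"
        )
    missing = [i for i in sample.individuals if i not in barcodes]
    if missing:
        raise ValueError(f"no barcode for individuals: {missing[:3]}")

    rng = np.random.default_rng(seed)
    q = 40 if error_rate <= 0 else int(round(-10 * np.log10(error_rate)))
    qual_char = chr(33 + max(2, min(q, 41)))
    genome = sample.genome
    individuals = sample.individuals
    n_ind = len(individuals)
    nb_p = dispersion / (dispersion + depth_mean)

    reads: list = []
    depth_rows: list = []
    remnant_arr = np.frombuffer(SPHI_SITE.encode("ascii"), dtype=np.uint8)
    locus_ids = sorted(genome.loci)
    for lid in locus_ids:
        depths = rng.negative_binomial(dispersion, nb_p, size=n_ind)
        total = int(depths.sum())
        for ind, d in zip(individuals, depths):
            depth_rows.append((ind, lid, int(d)))
        if total == 0:
            continue
        if lid in sample.haplotypes:
            hap = sample.haplotypes[lid]
            owner = np.repeat(np.arange(n_ind), depths)
            which = rng.integers(0, 2, size=total)
            bodies = hap[2 * owner + which].copy()
        else:
            body = np.frombuffer(
                genome.loci[lid][len(SPHI_SITE) :].encode("ascii"), dtype=np.uint8
            )
            owner = np.repeat(np.arange(n_ind), depths)
            bodies = np.tile(body, (total, 1))
        full = np.empty((total, remnant_arr.size + bodies.shape[1]), dtype=np.uint8)
        full[:, : remnant_arr.size] = remnant_arr
        full[:, remnant_arr.size :] = bodies
        full = _apply_errors(full, error_rate, rng)
        keep = read_length - bar_len
        full = full[:, :keep]
        qual = qual_char * full.shape[1]
        bars = np.stack(
            [
                np.frombuffer(barcodes[individuals[int(o)]].encode("ascii"), np.uint8)
                for o in owner
            ]
        )
        bars = _apply_errors(bars.copy(), error_rate, rng)
        counter: dict = {}
        for row, bar, o in zip(full, bars, owner):
            ind = individuals[int(o)]
            k = counter.get(ind, 0)
            counter[ind] = k + 1
            seq = bar.tobytes().decode("ascii") + row.tobytes().decode("ascii")
            reads.append(
                ReadRecord(
                    id=f"{lid}:{ind}:{k}",
                    sequence=seq,
                    qualities=qual_char * bar_len + qual,
                )
            )
    depth_table = pd.DataFrame(depth_rows, columns=["individual", "locus", "depth"])
    return reads, depth_table


def default_barcodes(individuals, length: int = 6, seed: int = 77) -> dict:
    """Deterministic barcode table with pairwise Hamming distance >= 3."""
    rng = np.random.default_rng(seed)
    chosen: list = []
    arrs: list = []
    while len(chosen) < len(individuals):
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= 3 for a in arrs):
            arrs.append(cand)
            chosen.append(_BASE_ARR[cand].tobytes().decode("ascii"))
    return dict(zip(individuals, chosen))


# ---------------------------------------------------------------------------
# lake metadata


def generate_lake_metadata(
    n_lakes: int, seed: int, n_lagoons: int = 2
) -> pd.DataFrame:
    """Synthetic lake-profile table in the style of a marine-lake survey.

    Lake values are drawn within empirical survey ranges (temperature
    29-32.4 C, salinity 23.5-33.5 ppt, tidal fraction c in [0.1, 0.8]);
    lagoons get category "open" (c taken as 1.0), sea-like temperature and
    salinity.  Connection categories are recomputed from c with the
    low (<= 0.4) / medium (0.5-0.7) / high (0.8-1) thresholds.
    """
    if n_lakes < 2:
        raise ValueError("n_lakes must be >= 2")
    from .seascape import categorize_connection

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lakes):
        c = float(np.round(rng.uniform(0.1, 0.8), 1))
        rows.append(
            {
                "code": f"Lake{i + 1:02d}",
                "lat": float(np.round(rng.uniform(-2.5, 2.5), 4)),
                "lon": float(np.round(rng.uniform(117.0, 131.0), 4)),
                "area_m2": float(np.round(rng.lognormal(np.log(5e4), 1.2), 0)),
                "max_depth_m": float(np.round(rng.uniform(2, 20), 0)),
                "temperature_c": float(np.round(rng.uniform(29.0, 32.4), 1)),
                "salinity_ppt": float(np.round(rng.uniform(23.5, 33.5), 1)),
                "tidal_fraction": c,
                "category": categorize_connection(c),
            }
        )
    for i in range(n_lagoons):
        rows.append(
            {
                "code": f"Sea{i + 1:02d}",
                "lat": float(np.round(rng.uniform(-12.5, 2.5), 4)),
                "lon": float(np.round(rng.uniform(117.0, 131.0), 4)),
                "area_m2": np.nan,
                "max_depth_m": np.nan,
                "temperature_c": float(np.round(rng.uniform(28.5, 29.5), 1)),
                "salinity_ppt": float(np.round(rng.uniform(33.0, 33.5), 1)),
                "tidal_fraction": 1.0,
                "category": "open",
            }
        )
    return pd.DataFrame(rows)
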