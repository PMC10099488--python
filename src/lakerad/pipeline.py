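"""End-to-end pipeline driver: simulate -> assemble -> genotype -> stats ->
demography -> seascape.

A single :class:`PipelineConfig` carries every stage's thresholds and
seeds (round-tripping losslessly through YAML); :func:`run_pipeline`
executes the toggled stages in order into write-once stage directories and
records a provenance manifest of seeds, thresholds, and artifact
checksums, so two runs of the same config produce identical manifests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .demography import fit_stairway, trajectory_table
from .genotyping import (
    GenotypingConfig,
    call_genotypes,
    estimate_allele_frequencies,
    filter_sites,
    genotype_likelihoods,
    run_filter_grid,
    thin_one_snp_per_locus,
)
from .popgen_stats import (
    amova,
    diversity,
    folded_sfs,
    pairwise_fst,
    pca_covariance,
    relative_migration_network,
)
from .rad_assembly import (
    build_reference,
    cluster_loci,
    demultiplex,
    screen_contaminants,
    trim_reads,
)
from .seascape import (
    connection_distance_matrix,
    environment_distance_matrix,
    geographic_distance_matrix,
    linearize_fst,
    mantel,
)
from .synthetic_data import (
    DemographyConfig,
    default_barcodes,
    generate_ddrad_reads,
    generate_lake_metadata,
    simulate_metapopulation,
)

__all__ = ["PipelineConfig", "run_pipeline", "small_preset"]

STAGES = ("simulate", "assemble", "genotype", "stats", "demography", "seascape")


@dataclass
class PipelineConfig:
    """All stage parameters and seeds of one pipeline run."""

    demography: DemographyConfig = field(default_factory=DemographyConfig)
    samples_per_population: int = 10
    # read generation; mean depth mirrors the ~24x average coverage of
    # field ddRAD libraries so the 10x grid row is meaningful
    depth_mean: float = 20.0
    error_rate: float = 0.005
    read_length: int = 150
    barcode_length: int = 6
    # assembly
    identity_threshold: float = 0.90
    min_support: int = 3
    min_share_fraction: float = 0.7
    gc_max: float = 0.55
    max_mismatches: int = 5
    # genotyping
    genotyping: GenotypingConfig = field(default_factory=GenotypingConfig)
    run_grid: bool = True
    # stats
    fst_permutations: int = 99
    amova_permutations: int = 199
    network_bootstraps: int = 100
    network_threshold: float = 0.2
    # demography
    stairway_epochs: int = 5
    stairway_bootstraps: int = 20
    stairway_populations: tuple = ()
    # seascape
    mantel_permutations: int = 9999
    # toggles and seeds
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    seeds: dict = field(
        default_factory=lambda: {s: i + 1 for i, s in enumerate(STAGES)}
    )
    write_fastq: bool = False

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stairway_populations"] = list(self.stairway_populations)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["demography"] = DemographyConfig(**d["demography"])
        d["genotyping"] = GenotypingConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["genotyping"].items()
            }
        )
        d["stairway_populations"] = tuple(d.get("stairway_populations", ()))
        return cls(**d)


def small_preset(seed: int = 1) -> PipelineConfig:
    """Demo-scale preset: 4 lakes + 1 sea, 500 loci, 10 individuals each."""
    dem = DemographyConfig(
        n_lakes=4,
        n_sea=1,
        n_loci=500,
        seed=seed,
    )
    cfg = PipelineConfig(demography=dem, samples_per_population=10)
    cfg.seeds = {s: seed * 100 + i for i, s in enumerate(STAGES)}
    cfg.stairway_populations = ("lake1",)
    return cfg


def _stage_dir(outdir: Path, index: int, name: str, overwrite: bool) -> Path:
    d = outdir / f"{index:02d}_{name}"
    if d.exists() and any(d.iterdir()) and not overwrite:
        raise FileExistsError(f"stage directory {d} already has artifacts")
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: PipelineConfig, outdir, overwrite: bool = False) -> dict:
    """Run the toggled stages in order; returns the in-memory artifacts.

    Each stage writes its tables into ``outdir/NN_stage/`` exactly once and
    registers checksums in ``manifest.json``.  A stage failure propagates
    after the preceding stages' reports are on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = lio.Manifest()
    art: dict = {"config": config}
    on = config.stages

    # ---- simulate -------------------------------------------------------
    if on.get("simulate", True):
        seed = config.seeds["simulate"]
        d = _stage_dir(outdir, 1, "simulate", overwrite)
        dem = config.demography
        metadata = generate_lake_metadata(
            max(dem.n_lakes, 2), seed, n_lagoons=dem.n_sea
        )
        codes = {}
        lakes = metadata[metadata["category"] != "open"].reset_index(drop=True)
        seas = metadata[metadata["category"] == "open"].reset_index(drop=True)
        for i, name in enumerate(dem.lake_names):
            codes[name] = str(lakes.loc[i, "code"])
            dem.connection_scaling[name] = float(lakes.loc[i, "tidal_fraction"])
        for i, name in enumerate(dem.sea_names):
            codes[name] = str(seas.loc[i, "code"])
        sample_sizes = {
            p: config.samples_per_population for p in dem.population_names
        }
        sample = simulate_metapopulation(dem, sample_sizes)
        barcodes = default_barcodes(
            sample.individuals, length=config.barcode_length, seed=seed + 7
        )
        reads, depth_table = generate_ddrad_reads(
            sample,
            barcodes,
            depth_mean=config.depth_mean,
            error_rate=config.error_rate,
            read_length=config.read_length,
            seed=seed + 13,
        )
        pd.DataFrame(
            [(i, b) for i, b in barcodes.items()], columns=["individual", "barcode"]
        ).to_csv(d / "barcodes.tsv", sep="\t", index=False)
        sample.truth_frequencies.to_csv(d / "truth_frequencies.tsv", sep="\t", index=False)
        sample.truth_fst.to_csv(d / "truth_fst.tsv", sep="\t", index=False)
        metadata.to_csv(d / "lake_metadata.tsv", sep="\t", index=False)
        outputs = [
            d / "barcodes.tsv",
            d / "truth_frequencies.tsv",
            d / "truth_fst.tsv",
            d / "lake_metadata.tsv",
        ]
        if config.write_fastq:
            lio.write_fastq(reads, d / "reads.fastq")
            outputs.append(d / "reads.fastq")
        manifest.record(
            "simulate",
            seed,
            {
                "n_loci": dem.n_loci,
                "n_lakes": dem.n_lakes,
                "n_sea": dem.n_sea,
                "depth_mean": config.depth_mean,
                "error_rate": config.error_rate,
            },
            outputs,
        )
        art.update(
            sample=sample,
            reads=reads,
            barcodes=barcodes,
            metadata=metadata,
            codes=codes,
            depth_table=depth_table,
        )

    # ---- assemble -------------------------------------------------------
    if on.get("assemble", True):
        d = _stage_dir(outdir, 2, "assemble", overwrite)
        sample = art["sample"]
        assigned, log_demux = demultiplex(art["reads"], art["barcodes"])
        catalogs = {}
        log_trim: list = []
        for ind, rds in assigned.items():
            trimmed, dropped = trim_reads(rds)
            log_trim.extend(dropped)
            catalogs[ind] = cluster_loci(
                trimmed,
                identity_threshold=config.identity_threshold,
                min_support=config.min_support,
            )
        reference = build_reference(
            catalogs,
            min_share_fraction=config.min_share_fraction,
            identity_threshold=config.identity_threshold,
        )
        reference, removed = screen_contaminants(reference, gc_max=config.gc_max)
        from .rad_assembly import assign_reads

        stacks, log_assign = assign_reads(
            assigned, reference, max_mismatches=config.max_mismatches
        )
        lio.write_fasta(
            {l.locus_id: l.representative for l in reference.retained},
            d / "reference.fasta",
        )
        report = {
            "reads_in": len(art["reads"]),
            "demultiplex_discards": len(log_demux),
            "trim_discards": len(log_trim),
            "assignment_discards": len(log_assign),
            "loci_total": len(reference.loci),
            "loci_retained": len(reference.retained),
            "contaminants_removed": len(removed),
        }
        lio.write_json_report(report, d / "assembly_report.json")
        manifest.record(
            "assemble",
            config.seeds["assemble"],
            {
                "identity": config.identity_threshold,
                "min_support": config.min_support,
                "min_share": config.min_share_fraction,
                "gc_max": config.gc_max,
            },
            [d / "reference.fasta", d / "assembly_report.json"],
        )
        art.update(reference=reference, stacks=stacks, assembly_report=report)

    # ---- genotype -------------------------------------------------------
    if on.get("genotype", True):
        d = _stage_dir(outdir, 3, "genotype", overwrite)
        sample = art["sample"]
        gcfg = config.genotyping
        gls, dropped = genotype_likelihoods(
            art["stacks"],
            art["reference"],
            sample.individuals,
            eps=gcfg.error_rate,
        )
        freqs = estimate_allele_frequencies(gls)
        calls = call_genotypes(gls, freqs, gcfg)
        # indel truth positions are declared on source loci; map them onto
        # reference loci by locus assignment of error-free representatives
        declared = _map_declared_indels(sample, art["reference"])
        filtered, freport = filter_sites(calls, declared, gcfg)
        thinned = thin_one_snp_per_locus(filtered, config.seeds["genotype"])
        site_index = {s: j for j, s in enumerate(gls.sites)}
        idx = [site_index[s] for s in thinned.sites]
        lio.write_vcf(
            thinned,
            d / "snps.vcf",
            depth=gls.depth[:, idx].astype(int),
        )
        lio.write_json_report(freport, d / "site_filter_report.json")
        outputs = [d / "snps.vcf", d / "site_filter_report.json"]
        if config.run_grid:
            cells, summary = run_filter_grid(gls, freqs, declared, gcfg)
            summary.to_csv(d / "filter_grid.tsv", sep="\t", index=False)
            outputs.append(d / "filter_grid.tsv")
            art["grid_summary"] = summary
            art["grid_cells"] = cells
        manifest.record(
            "genotype",
            config.seeds["genotype"],
            {
                "posterior_min": gcfg.posterior_min,
                "min_depth": gcfg.min_depth,
                "max_missing": gcfg.max_missing,
                "indel_window": gcfg.indel_window,
            },
            outputs,
        )
        art.update(gls=gls, freqs=freqs, calls=thinned, filter_report=freport)

    # ---- stats ----------------------------------------------------------
    if on.get("stats", True):
        d = _stage_dir(outdir, 4, "stats", overwrite)
        sample = art["sample"]
        calls = art["calls"]
        labels = {i: sample.populations[i] for i in sample.individuals}
        total_sites = sample.config.n_loci * sample.config.locus_length
        div = diversity(calls, labels, total_sites=total_sites)
        div_table = pd.DataFrame(
            [dataclasses.asdict(x) for x in div]
        )
        fst = pairwise_fst(
            calls, labels, n_perm=config.fst_permutations, seed=config.seeds["stats"]
        )
        am = amova(
            calls, labels, n_perm=config.amova_permutations, seed=config.seeds["stats"]
        )
        coords, pct = pca_covariance(calls)
        net = relative_migration_network(
            calls,
            labels,
            threshold=config.network_threshold,
            n_boot=config.network_bootstraps,
            seed=config.seeds["stats"],
        )
        div_table.to_csv(d / "diversity.tsv", sep="\t", index=False)
        lio.write_matrix_tsv(fst["fst_std"], d / "fst_std.tsv")
        lio.write_matrix_tsv(fst["gst"], d / "gst.tsv")
        lio.write_matrix_tsv(fst["p_value"], d / "fst_p.tsv")
        lio.write_json_report(
            {
                "components": am.components,
                "percents": am.percents,
                "phi": {k: (None if not np.isfinite(v) else v) for k, v in am.phi.items()},
                "p_values": am.p_values,
                "df": am.df,
                "warnings": am.warnings,
            },
            d / "amova.json",
        )
        pca_df = pd.DataFrame(
            coords[:, :4],
            columns=[f"PC{i + 1}" for i in range(min(4, coords.shape[1]))],
        )
        pca_df.insert(0, "individual", calls.individuals)
        pca_df.to_csv(d / "pca.tsv", sep="\t", index=False)
        lio.write_network(net, d / "migration.graphml", d / "migration_edges.tsv")
        manifest.record(
            "stats",
            config.seeds["stats"],
            {
                "fst_permutations": config.fst_permutations,
                "amova_permutations": config.amova_permutations,
                "network_threshold": config.network_threshold,
            },
            [
                d / "diversity.tsv",
                d / "fst_std.tsv",
                d / "gst.tsv",
                d / "fst_p.tsv",
                d / "amova.json",
                d / "pca.tsv",
                d / "migration_edges.tsv",
            ],
        )
        art.update(
            diversity=div_table, fst=fst, amova=am, pca=(coords, pct), network=net
        )

    # ---- demography -----------------------------------------------------
    if on.get("demography", True):
        d = _stage_dir(outdir, 5, "demography", overwrite)
        sample = art["sample"]
        labels = {i: sample.populations[i] for i in sample.individuals}
        pops = config.stairway_populations or tuple(
            sorted(set(sample.populations.values()))[:1]
        )
        outputs = []
        art["stairway"] = {}
        for pop in pops:
            sfs = folded_sfs(
                art["calls"],
                labels,
                pop,
                total_sites=sample.config.n_loci * sample.config.locus_length,
            )
            traj, model = fit_stairway(
                sfs,
                n_epochs=config.stairway_epochs,
                mu=sample.config.mutation_rate,
                generation_time=sample.config.generation_time,
                n_boot=config.stairway_bootstraps,
                seed=config.seeds["demography"],
            )
            sfs_df = pd.DataFrame(
                {"minor_count": np.arange(1, len(sfs.bins) + 1), "sites": sfs.bins}
            )
            sfs_df.to_csv(d / f"sfs_{pop}.tsv", sep="\t", index=False)
            trajectory_table(traj).to_csv(
                d / f"stairway_{pop}.tsv", sep="\t", index=False
            )
            outputs += [d / f"sfs_{pop}.tsv", d / f"stairway_{pop}.tsv"]
            art["stairway"][pop] = (traj, model)
        manifest.record(
            "demography",
            config.seeds["demography"],
            {
                "epochs": config.stairway_epochs,
                "bootstraps": config.stairway_bootstraps,
                "mu": sample.config.mutation_rate,
            },
            outputs,
        )

    # ---- seascape -------------------------------------------------------
    if on.get("seascape", True):
        d = _stage_dir(outdir, 6, "seascape", overwrite)
        metadata = art["metadata"].copy()
        codes = art["codes"]
        # genomic distances live on population names; relabel to lake codes
        fstm = art["fst"]["fst_std"].rename(index=codes, columns=codes)
        lin = linearize_fst(fstm.fillna(0.0))
        sub = metadata[metadata["code"].isin(lin.index)].reset_index(drop=True)
        geo = geographic_distance_matrix(sub)
        env = environment_distance_matrix(sub)
        con = connection_distance_matrix(sub)
        results = {}
        seed = config.seeds["seascape"]
        for name, mat in (("geographic", geo), ("environment", env), ("connection", con)):
            common = [c for c in lin.index if c in mat.index]
            res = mantel(
                lin.loc[common, common],
                mat.loc[common, common],
                n_perm=config.mantel_permutations,
                seed=seed,
            )
            results[name] = {"r": res.r, "p": res.p, "n_perm": res.n_perm}
        lio.write_matrix_tsv(lin, d / "genomic_linearized.tsv")
        lio.write_matrix_tsv(geo, d / "geographic_m.tsv")
        lio.write_matrix_tsv(env, d / "environment.tsv")
        lio.write_matrix_tsv(con, d / "connection_resistance.tsv")
        lio.write_json_report(results, d / "mantel.json")
        manifest.record(
            "seascape",
            seed,
            {"mantel_permutations": config.mantel_permutations},
            [
                d / "genomic_linearized.tsv",
                d / "geographic_m.tsv",
                d / "environment.tsv",
                d / "connection_resistance.tsv",
                d / "mantel.json",
            ],
        )
        art["mantel"] = results

    manifest.write(outdir / "manifest.json")
    art["manifest"] = manifest
    return art


def _map_declared_indels(sample, reference) -> dict:
    """Project truth indel positions from source loci onto reference loci.

    A reference locus inherits an indel position when its representative
    matches the source locus sequence (gapless, best identity).
    """
    from .rad_assembly import seq_to_u8

    declared: dict = {}
    if not sample.genome.truth_indels:
        return declared
    remnant = 6  # SphI remnant stripped during demultiplexing
    src = {
        lid: seq_to_u8(seq[remnant:])
        for lid, seq in sample.genome.loci.items()
        if lid in sample.genome.truth_indels
    }
    for locus in reference.retained:
        rep = seq_to_u8(locus.representative)
        for lid, arr in src.items():
            m = min(rep.size, arr.size)
            if m and (rep[:m] == arr[:m]).mean() >= 0.9:
                declared[locus.locus_id] = sample.genome.truth_indels[lid]
                break
    return declared
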