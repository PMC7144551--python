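"""End-to-end orchestration of the GBS pipeline on a synthetic cohort.

This module wires the per-stage modules together in the order a real GBS
study runs them: reference digestion, read demultiplexing and trimming,
chimera filtering, depth/presence QC, genotype-likelihood SNP calling,
diversity statistics, and distance-based structure (NJ + bootstrap, MDS).
It exists so the whole pipeline can be exercised on data with known truth
in one call; each stage remains independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chimera, digest, diststruct, genolik, locus_qc, popstats, readprep, simulate


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small two-population GBS experiment: 6 diploids
    per population plus two water negative controls, 500 restriction loci
    across 4 scaffolds, a deep clean population split, one collapsed
    paralog locus, a few percent chimeric reads, and sequencing depth and
    error typical of a GBS lane.
    """

    n_per_pop: int = 6
    n_controls: int = 2
    n_loci: int = 500
    n_scaffolds: int = 4
    theta: float = 3.0
    split_time: float = 2.0
    mean_depth: float = 8.0
    error_rate: float = 0.001
    chimera_rate: float = 0.02
    control_depth_factor: float = 0.02
    paralog_factor: float = 10.0
    n_paralog_loci: int = 1
    flank_bp: int = digest.DEFAULT_FLANK
    motif: str = digest.DEFAULT_MOTIF
    min_spacing: int = 300


@dataclass
class CohortData:
    genome: dict[str, str]
    locus_set: digest.LocusSet
    reads: simulate.ReadSimResult
    config: CohortConfig
    samples: list[str]
    controls: list[str]
    populations: dict[str, str]
    coalescent: simulate.CoalescentSim


def simulate_cohort(config: CohortConfig, seed: int) -> CohortData:
    """Generate reference, genotypes and reads for a two-population cohort."""
    rng_seeds = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]
    per_scaffold = -(-config.n_loci // config.n_scaffolds)
    scaffold_len = per_scaffold * config.min_spacing + 2 * simulate.READ_LENGTH
    genome, _ = simulate.simulate_reference(
        config.n_scaffolds,
        [scaffold_len] * config.n_scaffolds,
        config.n_loci,
        seed=seeds[0],
        motif=config.motif,
        min_spacing=config.min_spacing,
    )
    sites = digest.find_cut_sites(genome, config.motif)
    locus_set = digest.build_merged_loci(
        sites,
        {k: len(v) for k, v in genome.items()},
        flank_bp=config.flank_bp,
        motif=config.motif,
    )
    coalescent = simulate.simulate_two_population_genotypes(
        config.n_per_pop, len(locus_set), config.theta, config.split_time, seed=seeds[1]
    )
    pop_a = [f"popA_{i:02d}" for i in range(config.n_per_pop)]
    pop_b = [f"popB_{i:02d}" for i in range(config.n_per_pop)]
    controls = [f"control_{i}" for i in range(config.n_controls)]
    samples = pop_a + pop_b
    barcodes = simulate.default_barcodes(samples + controls, seed=seeds[2])
    paralogs = {i: config.paralog_factor for i in range(config.n_paralog_loci)}
    reads = simulate.simulate_gbs_reads(
        genome,
        locus_set,
        coalescent,
        barcodes,
        mean_depth=config.mean_depth,
        error_rate=config.error_rate,
        chimera_rate=config.chimera_rate,
        seed=seeds[3],
        control_samples=controls,
        control_depth_factor=config.control_depth_factor,
        paralog_loci=paralogs,
        motif=config.motif,
    )
    populations = {s: "A" for s in pop_a} | {s: "B" for s in pop_b}
    return CohortData(
        genome=genome,
        locus_set=locus_set,
        reads=reads,
        config=config,
        samples=samples,
        controls=controls,
        populations=populations,
        coalescent=coalescent,
    )


@dataclass
class CohortResults:
    demux_report: readprep.DemuxReport
    chimera_report: chimera.ChimeraReport
    excluded_paralogs: list[str]
    failed_samples: locus_qc.FailedSampleResult
    analysis_samples: list[str]
    gl_matrix: genolik.GLMatrix | None
    site_stats: pd.DataFrame | None
    kept_sites: np.ndarray | None
    attrition: dict[str, int]
    calls: genolik.GenotypeCalls | None
    heterozygosity: dict[str, float | None]
    diversity: list[popstats.DiversityEntry]
    tree: diststruct.TreeNode | None
    distances: diststruct.DistanceMatrix | None
    mds_coords: np.ndarray | None
    mds_eigvals: np.ndarray | None


def analyze_cohort(
    data: CohortData,
    workdir: str | Path,
    bootstrap_replicates: int = 100,
    seed: int = 0,
    max_gd: float = 800.0,
    snp_pval: float = 1e-6,
) -> CohortResults:
    """Run the full pipeline on a simulated cohort under ``workdir``."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config = data.config

    fastq = workdir / "reads.fastq"
    sam = workdir / "alignments.sam"
    data.reads.write_fastq(fastq)
    data.reads.write_sam(sam)

    table = readprep.BarcodeTable(
        barcodes=data.reads.truth.sample_barcodes,
        control_samples=set(data.controls),
    )
    demux_report = readprep.demultiplex(fastq, table, workdir / "demux")
    for sample in table.barcodes:
        readprep.trim_fastq(
            workdir / "demux" / f"{sample}.fastq",
            workdir / "demux" / f"{sample}.trimmed.fastq",
        )

    filtered_sam = workdir / "alignments.nochimera.sam"
    chimera_report = chimera.filter_chimeras(sam, filtered_sam, motif=config.motif)

    all_samples = data.samples + data.controls
    profile = locus_qc.compute_global_depth(
        filtered_sam, data.locus_set, sample_set=all_samples
    )
    kept_loci, excluded = locus_qc.paralog_filter(
        profile, data.locus_set, max_gd=max_gd
    )
    pmat = locus_qc.presence_matrix(
        profile.read_counts, min_reads=3, control_samples=data.controls
    )
    failed = locus_qc.flag_failed_samples(pmat)
    analysis_samples = [
        s for s in data.samples if s not in failed.clade
    ]

    empty = CohortResults(
        demux_report=demux_report,
        chimera_report=chimera_report,
        excluded_paralogs=excluded,
        failed_samples=failed,
        analysis_samples=analysis_samples,
        gl_matrix=None,
        site_stats=None,
        kept_sites=None,
        attrition={},
        calls=None,
        heterozygosity={},
        diversity=[],
        tree=None,
        distances=None,
        mds_coords=None,
        mds_eigvals=None,
    )
    if len(analysis_samples) < 3:
        return empty

    pileups = genolik.pileup_candidate_sites(
        filtered_sam, kept_loci, analysis_samples
    )
    if not pileups:
        return empty
    glm = genolik.gl_matrix_from_pileups(pileups, analysis_samples)

    f, loglik, _ = genolik.estimate_maf_em_batch(glm.gl, glm.missing)
    lrt, pval = genolik.snp_lrt_batch(glm.gl, glm.missing, f, loglik)
    site_stats = pd.DataFrame(
        {
            "scaffold": glm.sites["scaffold"],
            "pos": glm.sites["pos"],
            "f": f,
            "maf": np.minimum(f, 1 - f),
            "lrt": lrt,
            "pval": pval,
            "n_informative": (~glm.missing).sum(1),
            "total_depth": glm.depth.sum(1),
        }
    )
    kept_sites, attrition = genolik.site_filter_cascade(
        site_stats, len(analysis_samples), snp_pval=snp_pval
    )
    results = empty
    results.gl_matrix = glm
    results.site_stats = site_stats
    results.kept_sites = kept_sites
    results.attrition = attrition
    if kept_sites.sum() < 2:
        return results

    gl_kept = glm.gl[kept_sites]
    depth_kept = glm.depth[kept_sites]
    miss_kept = glm.missing[kept_sites]
    calls = genolik.call_genotypes(
        gl_kept, depth_kept, miss_kept, prior="uniform", samples=analysis_samples
    )
    results.calls = calls
    results.heterozygosity = {
        s: popstats.heterozygosity(calls.calls[:, i])
        for i, s in enumerate(analysis_samples)
    }

    # per-population SFS and diversity over the kept sites
    for pop in sorted(set(data.populations.values())):
        members = [
            i
            for i, s in enumerate(analysis_samples)
            if data.populations.get(s) == pop
        ]
        if len(members) < 2:
            continue
        saf = []
        for site in range(gl_kept.shape[0]):
            miss_row = miss_kept[site, members]
            if (~miss_row).sum() == len(members):
                saf.append(popstats.saf_per_site(gl_kept[site, members]))
        if not saf:
            continue
        sfs_counts, _ = popstats.estimate_sfs_em(np.array(saf))
        sfs = popstats.SFS(counts=sfs_counts, n_diploids=len(members))
        results.diversity.append(
            popstats.diversity_stats(sfs, population=pop)
        )

    posteriors = genolik.genotype_posteriors(gl_kept, prior="uniform")
    tree, dist = diststruct.bootstrap_support(
        posteriors,
        miss_kept,
        analysis_samples,
        n_replicates=bootstrap_replicates,
        seed=seed,
    )
    results.tree = tree
    results.distances = dist
    coords, eigvals = diststruct.classical_mds(dist, k=2)
    results.mds_coords = coords
    results.mds_eigvals = eigvals
    return results
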