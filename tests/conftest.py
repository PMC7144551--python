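import numpy as np
import pytest

from gbskit import digest, simulate


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small simulated GBS run shared by the I/O-heavy stage tests.

    Two scaffolds, 20 loci, 4 samples, 5% chimeras, on-disk FASTQ + SAM.
    """
    genome, truth = simulate.simulate_reference(2, [20000, 20000], 20, seed=11)
    sites = digest.find_cut_sites(genome)
    locus_set = digest.build_merged_loci(sites, {k: len(v) for k, v in genome.items()})
    coalescent = simulate.simulate_coalescent_genotypes(4, len(locus_set), 2.0, seed=12)
    samples = [f"s{i:02d}" for i in range(4)]
    barcodes = simulate.default_barcodes(samples, seed=13)
    reads = simulate.simulate_gbs_reads(
        genome,
        locus_set,
        coalescent,
        barcodes,
        mean_depth=6.0,
        error_rate=0.001,
        chimera_rate=0.05,
        seed=14,
    )
    d = tmp_path_factory.mktemp("small_sim")
    reads.write_fastq(d / "reads.fastq")
    reads.write_sam(d / "alignments.sam")
    return {
        "genome": genome,
        "locus_set": locus_set,
        "coalescent": coalescent,
        "barcodes": barcodes,
        "samples": samples,
        "reads": reads,
        "fastq": d / "reads.fastq",
        "sam": d / "alignments.sam",
        "dir": d,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
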