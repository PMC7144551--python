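import numpy as np
import pytest

from gbskit import chimera, digest, simulate


class TestSimulateReference:
    def test_no_planted_sites_digests_to_nothing(self):
        genome, truth = simulate.simulate_reference(1, [5000], 0, seed=0)
        assert digest.find_cut_sites(genome) == {"scaffold_1": []}
        assert truth.cut_positions == {"scaffold_1": []}

    def test_planted_sites_are_exhaustive(self):
        genome, truth = simulate.simulate_reference(1, [50000], 25, seed=3)
        found = digest.find_cut_sites(genome)["scaffold_1"]
        assert found == truth.cut_positions["scaffold_1"]
        assert len(found) == 25
        # brute-force substring confirmation
        seq = genome["scaffold_1"]
        brute = [i for i in range(len(seq) - 5) if seq[i : i + 6] == "ATGCAT"]
        assert brute == found

    def test_deterministic_for_fixed_seed(self, tmp_path):
        paths = []
        for name in ("a.fasta", "b.fasta"):
            genome, _ = simulate.simulate_reference(2, [8000, 8000], 10, seed=42)
            simulate.write_fasta(genome, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate.simulate_reference(1, [1000], 10, seed=0)


class TestCoalescent:
    def test_two_chromosome_expectation(self):
        # n_diploids=1: E[S] = theta * a1 with a1 = 1
        theta = 4.0
        sim = simulate.simulate_coalescent_genotypes(1, 3000, theta, seed=1)
        s = np.array([h.shape[1] for h in sim.haplotypes])
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - theta) < 3 * se

    def test_watterson_expectation_ten_chromosomes(self):
        theta = 5.0
        sim = simulate.simulate_coalescent_genotypes(5, 2000, theta, seed=2)
        a1 = sum(1.0 / i for i in range(1, 10))
        s = np.array([h.shape[1] for h in sim.haplotypes])
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - theta * a1) < 3 * se

    def test_diploid_pairing_is_consecutive(self):
        sim = simulate.simulate_coalescent_genotypes(3, 5, 3.0, seed=3)
        for hap, geno in zip(sim.haplotypes, sim.genotypes):
            np.testing.assert_array_equal(geno, hap[0::2] + hap[1::2])

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate.simulate_coalescent_genotypes(0, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_coalescent_genotypes(2, 10, 0.0, seed=0)

    def test_two_population_split_fixes_differences(self):
        # a deep split accumulates fixed differences between the demes
        sim = simulate.simulate_two_population_genotypes(4, 200, 2.0, 4.0, seed=4)
        n_fixed = 0
        for hap in sim.haplotypes:
            a, b = hap[:8], hap[8:]
            n_fixed += int(
                np.sum((a.mean(0) == 1) & (b.mean(0) == 0))
                + np.sum((a.mean(0) == 0) & (b.mean(0) == 1))
            )
        assert n_fixed > 50


class TestGbsReads:
    def test_chimera_rate_validation(self, small_sim):
        with pytest.raises(ValueError):
            simulate.simulate_gbs_reads(
                small_sim["genome"],
                small_sim["locus_set"],
                small_sim["coalescent"],
                small_sim["barcodes"],
                chimera_rate=1.5,
            )

    def test_zero_chimera_rate_plants_none(self, small_sim):
        reads = simulate.simulate_gbs_reads(
            small_sim["genome"],
            small_sim["locus_set"],
            small_sim["coalescent"],
            small_sim["barcodes"],
            mean_depth=3.0,
            chimera_rate=0.0,
            seed=5,
        )
        assert reads.truth.chimeric_read_ids == set()

    def test_planted_chimera_count_within_binomial_bounds(self, small_sim):
        from scipy.stats import binom

        reads = small_sim["reads"]
        n = len(reads.fastq)
        k = len(reads.truth.chimeric_read_ids)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= k <= hi

    def test_planted_chimeras_satisfy_both_conditions(self, small_sim):
        # >1 internal motif, and >= 2 noncontiguous aligned regions
        reads = small_sim["reads"]
        bc_len = len(next(iter(small_sim["barcodes"].values())))
        by_id = {rid: seq for rid, seq, _ in reads.fastq}
        for rid in reads.truth.chimeric_read_ids:
            assert chimera.count_internal_cut_sites(by_id[rid][bc_len:]) >= 2
        sam_blocks: dict[str, list] = {}
        for rec in reads.sam:
            sam_blocks.setdefault(rec["name"], []).append(rec)
        for rid in reads.truth.chimeric_read_ids:
            scaffolds_pos = {(r["scaffold"], r["pos"]) for r in sam_blocks[rid]}
            assert len(sam_blocks[rid]) == 3
            assert len(scaffolds_pos) == 3

    def test_every_read_attributed_to_one_sample(self, small_sim):
        reads = small_sim["reads"]
        assert set(reads.truth.read_samples) == {r[0] for r in reads.fastq}
        assert set(reads.truth.read_samples.values()) <= set(small_sim["samples"])

    def test_fastq_sam_deterministic(self, small_sim, tmp_path):
        args = (
            small_sim["genome"],
            small_sim["locus_set"],
            small_sim["coalescent"],
            small_sim["barcodes"],
        )
        for name in ("x", "y"):
            reads = simulate.simulate_gbs_reads(
                *args, mean_depth=4.0, chimera_rate=0.03, seed=77
            )
            reads.write_fastq(tmp_path / f"{name}.fastq")
            reads.write_sam(tmp_path / f"{name}.sam")
        assert (tmp_path / "x.fastq").read_bytes() == (tmp_path / "y.fastq").read_bytes()
        assert (tmp_path / "x.sam").read_bytes() == (tmp_path / "y.sam").read_bytes()

    def test_noiseless_high_depth_recovers_truth_genotypes(self, tmp_path):
        """With error 0 and deep coverage the full GL pipeline reproduces truth."""
        from gbskit import genolik

        genome, _ = simulate.simulate_reference(1, [20000], 20, seed=21)
        sites = digest.find_cut_sites(genome)
        locus_set = digest.build_merged_loci(sites, {k: len(v) for k, v in genome.items()})
        coalescent = simulate.simulate_coalescent_genotypes(4, len(locus_set), 2.0, seed=22)
        samples = [f"s{i}" for i in range(4)]
        barcodes = simulate.default_barcodes(samples, seed=23)
        reads = simulate.simulate_gbs_reads(
            genome, locus_set, coalescent, barcodes,
            mean_depth=30.0, error_rate=0.0, chimera_rate=0.0, seed=24,
        )
        sam = tmp_path / "deep.sam"
        reads.write_sam(sam)
        pileups = genolik.pileup_candidate_sites(sam, locus_set, samples)
        glm = genolik.gl_matrix_from_pileups(pileups, samples)
        calls = genolik.call_genotypes(glm.gl, glm.depth, glm.missing)
        truth = reads.truth
        truth_by_pos = {
            pos: truth.genotypes[:, i] for i, pos in enumerate(truth.site_positions)
        }
        checked = 0
        for i, row in glm.sites.iterrows():
            key = (row.scaffold, row.pos)
            if key not in truth_by_pos:
                continue
            called = calls.calls[i]
            ok = called != genolik.MISSING
            # polarity: the pipeline's minor allele is the simulated derived allele
            expected = truth_by_pos[key]
            if not np.array_equal(called[ok], expected[ok]):
                expected = 2 - expected  # major/minor swapped at f ~ 0.5
            np.testing.assert_array_equal(called[ok], expected[ok])
            checked += 1
        assert checked > 10

    def test_pileup_counts_noise_free_limit(self, rng):
        g = np.array([[0, 1, 2]])
        c = simulate.simulate_pileup_counts(g, 50.0, 0.0, rng)
        assert c["n_other"].sum() == 0
        assert c["n_minor"][0, 0] == 0  # hom-major sample: no minor reads
        assert c["n_major"][0, 2] == 0  # hom-minor sample: no major reads
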