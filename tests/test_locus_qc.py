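import itertools

import numpy as np
import pandas as pd
import pysam
import pytest

from gbskit import digest, locus_qc

HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "scaffold_1", "LN": 100000}]}
)


def write_sam(path, records):
    with pysam.AlignmentFile(str(path), "w", header=HEADER) as fh:
        for name, pos, length, mapq in records:
            a = pysam.AlignedSegment(HEADER)
            a.query_name = name
            a.flag = 0
            a.reference_name = "scaffold_1"
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{length}M"
            a.query_sequence = "A" * length
            fh.write(a)


@pytest.fixture
def one_locus():
    return digest.LocusSet([digest.Locus("scaffold_1", 100, 290, "locus_000000")])


class TestComputeGlobalDepth:
    def test_no_reads_gives_zero_profile(self, tmp_path, one_locus):
        sam = tmp_path / "empty.sam"
        write_sam(sam, [])
        profile = locus_qc.compute_global_depth(sam, one_locus, sample_set=["s1"])
        assert profile.per_locus_depth[0].sum() == 0

    def test_full_coverage_arithmetic(self, tmp_path, one_locus):
        # 3 reads fully covering the 190-bp locus from each of 2 samples -> depth 6
        recs = [
            (f"{s}:r{i}", 100, 190, 60) for s in ("s1", "s2") for i in range(3)
        ]
        sam = tmp_path / "full.sam"
        write_sam(sam, recs)
        profile = locus_qc.compute_global_depth(sam, one_locus, sample_set=["s1", "s2"])
        np.testing.assert_array_equal(profile.per_locus_depth[0], np.full(190, 6))
        assert profile.read_counts.loc["s1", "locus_000000"] == 3

    def test_low_mapq_reads_excluded(self, tmp_path, one_locus):
        sam = tmp_path / "mapq.sam"
        write_sam(sam, [("s1:r1", 100, 190, 10)])
        profile = locus_qc.compute_global_depth(sam, one_locus, sample_set=["s1"])
        assert profile.per_locus_depth[0].sum() == 0

    def test_matches_brute_force_interval_stabbing(self, tmp_path):
        rng = np.random.default_rng(4)
        loci = digest.build_merged_loci(
            {"scaffold_1": [500, 1500, 3000]}, {"scaffold_1": 100000}
        )
        recs = []
        for i in range(200):
            pos = int(rng.integers(300, 3300))
            recs.append((f"s{rng.integers(3)}:r{i}", pos, 95, 60))
        sam = tmp_path / "rand.sam"
        write_sam(sam, recs)
        profile = locus_qc.compute_global_depth(
            sam, loci, sample_set=["s0", "s1", "s2"]
        )
        for li, locus in enumerate(loci):
            brute = np.zeros(len(locus), dtype=int)
            for _, pos, length, _ in recs:
                for bp in range(max(pos, locus.start), min(pos + length, locus.end)):
                    brute[bp - locus.start] += 1
            np.testing.assert_array_equal(profile.per_locus_depth[li], brute)


class TestParalogFilter:
    def make_profile(self, depths):
        ids = [f"locus_{i:06d}" for i in range(len(depths))]
        return (
            locus_qc.DepthProfile(
                locus_ids=ids,
                per_locus_depth=[np.full(10, d) for d in depths],
                read_counts=pd.DataFrame(),
            ),
            digest.LocusSet(
                [digest.Locus("scaffold_1", i * 1000, i * 1000 + 10, lid) for i, lid in enumerate(ids)]
            ),
        )

    def test_toy_threshold(self):
        profile, loci = self.make_profile([10, 12, 9, 1000])
        kept, excluded = locus_qc.paralog_filter(profile, loci, max_gd=800)
        assert excluded == ["locus_000003"]
        assert len(kept) == 3

    def test_infinite_threshold_keeps_all(self):
        profile, loci = self.make_profile([10, 12, 9, 1000])
        kept, excluded = locus_qc.paralog_filter(profile, loci, max_gd=np.inf)
        assert excluded == [] and len(kept) == 4

    def test_partition_is_exact(self):
        profile, loci = self.make_profile([10, 900, 9, 1000, 40])
        kept, excluded = locus_qc.paralog_filter(profile, loci, max_gd=800)
        kept_ids = {l.locus_id for l in kept}
        assert kept_ids.isdisjoint(excluded)
        assert kept_ids | set(excluded) == {l.locus_id for l in loci}

    def test_poisson_quantile_mode_excludes_duplicated_locus(self):
        # single-copy loci near the mean survive; a doubled locus is excluded
        rng = np.random.default_rng(8)
        depths = list(rng.poisson(100, size=50)) + [200]
        profile, loci = self.make_profile(depths)
        kept, excluded = locus_qc.paralog_filter(
            profile, loci, poisson_quantile=1e-6
        )
        assert excluded == ["locus_000050"]


class TestPresenceMatrix:
    def test_threshold_is_three_reads(self):
        counts = pd.DataFrame(
            {"l1": [3, 2], "l2": [0, 7]}, index=["a", "b"]
        )
        pm = locus_qc.presence_matrix(counts)
        assert pm.matrix.loc["a", "l1"]
        assert not pm.matrix.loc["b", "l1"]

    def test_empty_sample_all_absent(self):
        counts = pd.DataFrame({"l1": [0, 5], "l2": [0, 5]}, index=["empty", "rich"])
        pm = locus_qc.presence_matrix(counts)
        assert not pm.matrix.loc["empty"].any()


class TestKmeans:
    def test_separable_blocks_recovered(self):
        X = np.vstack([np.tile([1.0, 1, 0, 0], (10, 1)), np.tile([0.0, 0, 1, 1], (8, 1))])
        labels, wcss = locus_qc.cluster_loci_kmeans(X, k=2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        assert wcss == pytest.approx(0.0)

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(1)
        X = rng.random((7, 3))
        _, wcss = locus_qc.cluster_loci_kmeans(X, k=7, seed=0)
        assert wcss == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            locus_qc.cluster_loci_kmeans(np.zeros((3, 2)), k=5)

    def test_small_instance_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 3))
        _, wcss = locus_qc.cluster_loci_kmeans(X, k=2, seed=0, n_init=20)
        best = np.inf
        for assignment in itertools.product([0, 1], repeat=10):
            a = np.array(assignment)
            if a.min() == a.max():
                continue
            sse = sum(
                ((X[a == c] - X[a == c].mean(0)) ** 2).sum() for c in (0, 1)
            )
            best = min(best, sse)
        assert wcss == pytest.approx(best, rel=1e-9)

    def test_matches_sklearn_objective(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(3)
        X = rng.random((40, 5))
        _, wcss = locus_qc.cluster_loci_kmeans(X, k=4, seed=0, n_init=10)
        sk = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        assert wcss == pytest.approx(sk.inertia_, rel=0.05)


class TestFlagFailedSamples:
    def test_near_empty_sample_flagged_with_controls(self):
        rng = np.random.default_rng(5)
        rich = rng.random((6, 80)) < 0.9
        data = {f"rich{i}": rich[i] for i in range(6)}
        data["failed"] = rng.random(80) < 0.03
        data["ctrl1"] = np.zeros(80, bool)
        data["ctrl2"] = np.zeros(80, bool)
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(data).T, control_samples={"ctrl1", "ctrl2"}
        )
        result = locus_qc.flag_failed_samples(pm)
        assert result.flagged == ["failed"]

    def test_rich_samples_leave_controls_alone(self):
        rng = np.random.default_rng(6)
        data = {f"rich{i}": rng.random(60) < 0.9 for i in range(6)}
        data["ctrl"] = np.zeros(60, bool)
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(data).T, control_samples={"ctrl"}
        )
        result = locus_qc.flag_failed_samples(pm)
        assert result.flagged == []
        assert result.clade == ["ctrl"]

    def test_identical_failed_duplicates_flagged_together(self):
        rng = np.random.default_rng(7)
        data = {f"rich{i}": rng.random(60) < 0.9 for i in range(5)}
        dup = rng.random(60) < 0.02
        data["dupA"] = dup
        data["dupB"] = dup.copy()
        data["ctrl"] = np.zeros(60, bool)
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(data).T, control_samples={"ctrl"}
        )
        result = locus_qc.flag_failed_samples(pm)
        assert set(result.flagged) == {"dupA", "dupB"}

    def test_no_control_rejected(self):
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(np.ones((3, 4), bool)), control_samples=set()
        )
        with pytest.raises(ValueError):
            locus_qc.flag_failed_samples(pm)

    def test_rich_sample_never_flagged_sanity_bound(self):
        # a sample whose presence fraction beats every control's by >= 0.5
        rng = np.random.default_rng(8)
        data = {f"rich{i}": rng.random(100) < 0.85 for i in range(8)}
        data["ctrl1"] = rng.random(100) < 0.02
        data["ctrl2"] = np.zeros(100, bool)
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(data).T, control_samples={"ctrl1", "ctrl2"}
        )
        result = locus_qc.flag_failed_samples(pm)
        fractions = pd.DataFrame(data).T.mean(1)
        ctrl_max = max(fractions["ctrl1"], fractions["ctrl2"])
        for sample in result.flagged:
            assert fractions[sample] - ctrl_max < 0.5

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        data = {f"s{i}": rng.random(40) < 0.8 for i in range(5)}
        data["ctrl"] = np.zeros(40, bool)
        pm = locus_qc.PresenceMatrix(
            matrix=pd.DataFrame(data).T, control_samples={"ctrl"}
        )
        result = locus_qc.flag_failed_samples(pm)
        tree = dendropy.Tree.get(data=result.newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(data.keys())
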