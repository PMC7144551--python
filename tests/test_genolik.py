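import numpy as np
import pandas as pd
import pytest

from gbskit import genolik, simulate


class TestGenotypeLikelihood:
    def test_single_major_read_q20(self):
        # direct evaluation of the independent-error model at e = 0.01
        gl, depth = genolik.genotype_likelihood(["A"], [20], "A", "C")
        raw = np.exp(gl) * 0.99  # un-normalize via the hom-major likelihood
        np.testing.assert_allclose(raw, [0.99, 0.99 / 2 + 0.01 / 6, 0.01 / 3], rtol=1e-9)
        assert depth == 1

    def test_zero_depth_is_missing(self):
        gl, depth = genolik.genotype_likelihood([], [], "A", "C")
        np.testing.assert_array_equal(gl, [0.0, 0.0, 0.0])
        assert depth == 0

    def test_likelihood_ratio_grows_geometrically(self):
        # n identical major reads: hom-major / het ratio = (0.99 / 0.4966667)^n
        for n in (1, 3, 7):
            gl, _ = genolik.genotype_likelihood(["A"] * n, [20] * n, "A", "C")
            ratio = np.exp(gl[0] - gl[1])
            assert ratio == pytest.approx((0.99 / 0.4966667) ** n, rel=1e-4)

    def test_quality_and_mapq_filters(self):
        gl, depth = genolik.genotype_likelihood(
            ["A", "A", "A"], [10, 30, 30], "A", "C", mapqs=[60, 10, 60]
        )
        assert depth == 1  # q10 and mapq10 reads dropped

    def test_counts_path_matches_per_read_path(self, rng):
        e = 0.01
        for _ in range(20):
            n_major, n_minor, n_other = rng.integers(0, 8, size=3)
            bases = ["A"] * n_major + ["C"] * n_minor + ["G"] * n_other
            quals = [20] * len(bases)
            gl_reads, _ = genolik.genotype_likelihood(bases, quals, "A", "C")
            gl_counts = genolik.gl_from_counts(n_major, n_minor, n_other, e)
            np.testing.assert_allclose(gl_reads, gl_counts, atol=1e-10)

    def test_major_minor_tie_breaks_alphabetically(self):
        assert genolik.choose_major_minor([5, 5, 0, 0]) == (0, 1)  # A then C
        assert genolik.choose_major_minor([0, 3, 3, 7]) == (3, 1)  # T major, C minor


class TestMafEm:
    def certain(self, genotypes):
        """Near-certain GLs for given genotypes."""
        gl = np.full((len(genotypes), 3), -60.0)
        for i, g in enumerate(genotypes):
            gl[i, g] = 0.0
        return gl

    def test_all_hom_major_gives_zero(self):
        r = genolik.estimate_maf_em(self.certain([0] * 10))
        assert r.f == pytest.approx(0.0, abs=1e-4)

    def test_symmetric_panel_gives_half(self):
        r = genolik.estimate_maf_em(self.certain([0, 2] * 5))
        assert r.f == pytest.approx(0.5, abs=1e-6)

    def test_loglik_monotone_and_matches_grid_oracle(self, rng):
        """EM frequency matches a 1e-4-step grid search of the HWE likelihood."""
        S, N = 30, 20
        f_true = rng.uniform(0.05, 0.5, size=S)
        g = rng.binomial(2, f_true[:, None], size=(S, N))
        c = simulate.simulate_pileup_counts(g, 8.0, 0.01, rng)
        gl = genolik.gl_from_counts(c["n_major"], c["n_minor"], c["n_other"], 0.01)
        missing = c["depth"] == 0
        f_hat, ll, _ = genolik.estimate_maf_em_batch(gl, missing)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for s in range(S):
            lls = genolik.hwe_loglik(
                np.broadcast_to(gl[s], (len(grid),) + gl[s].shape),
                np.broadcast_to(missing[s], (len(grid), N)),
                grid,
            )
            f_grid = grid[np.argmax(lls)]
            assert abs(f_hat[s] - f_grid) < 1e-3

    def test_all_missing_site_rejected(self):
        gl = np.zeros((1, 4, 3))
        with pytest.raises(ValueError):
            genolik.estimate_maf_em_batch(gl, np.ones((1, 4), bool))

    def test_permutation_invariance(self, rng):
        g = rng.binomial(2, 0.3, size=(1, 15))
        c = simulate.simulate_pileup_counts(g, 10.0, 0.01, rng)
        gl = genolik.gl_from_counts(c["n_major"], c["n_minor"], c["n_other"], 0.01)
        miss = c["depth"] == 0
        perm = rng.permutation(15)
        f1, ll1, _ = genolik.estimate_maf_em_batch(gl, miss)
        f2, ll2, _ = genolik.estimate_maf_em_batch(gl[:, perm], miss[:, perm])
        assert f1[0] == pytest.approx(f2[0], abs=1e-9)
        lrt1, _ = genolik.snp_lrt_batch(gl, miss, f1, ll1)
        lrt2, _ = genolik.snp_lrt_batch(gl[:, perm], miss[:, perm], f2, ll2)
        assert lrt1[0] == pytest.approx(lrt2[0], abs=1e-8)


class TestSnpLrt:
    def test_null_frequency_gives_zero_lrt(self):
        gl = np.full((10, 3), -40.0)
        gl[:, 0] = 0.0
        r = genolik.estimate_maf_em(gl)
        stats = genolik.snp_lrt(gl, r)
        assert stats.lrt == pytest.approx(0.0, abs=1e-6)
        assert stats.pval == pytest.approx(1.0, abs=1e-6)

    def test_polymorphic_site_is_significant(self):
        gl = np.full((20, 3), -40.0)
        gl[:10, 0] = 0.0
        gl[10:, 1] = 0.0
        gl -= gl.max(1, keepdims=True)
        r = genolik.estimate_maf_em(gl)
        stats = genolik.snp_lrt(gl, r)
        assert stats.pval < 1e-6


class TestCallGenotypes:
    def test_certain_calls_with_sufficient_depth(self):
        gl = np.array([[[0.0, -50.0, -50.0]]])
        calls = genolik.call_genotypes(gl, depth=np.array([[3]]))
        assert calls.calls[0, 0] == 0

    def test_flat_posterior_stays_missing(self):
        gl = np.zeros((1, 1, 3))
        calls = genolik.call_genotypes(gl, depth=np.array([[10]]))
        assert calls.calls[0, 0] == genolik.MISSING

    def test_low_depth_stays_missing(self):
        gl = np.array([[[-50.0, 0.0, -50.0]]])
        calls = genolik.call_genotypes(gl, depth=np.array([[2]]))
        assert calls.calls[0, 0] == genolik.MISSING

    def test_posteriors_sum_to_one(self, rng):
        gl = np.log(rng.random((5, 4, 3)))
        gl -= gl.max(-1, keepdims=True)
        post = genolik.genotype_posteriors(gl)
        np.testing.assert_allclose(post.sum(-1), 1.0, atol=1e-12)

    def test_hwe_prior_shifts_calls(self):
        gl = np.log(np.array([[[0.40, 0.35, 0.25]]]))
        uniform = genolik.genotype_posteriors(gl, prior="uniform")
        hwe = genolik.genotype_posteriors(gl, prior="hwe", f=np.array([0.01]))
        assert hwe[0, 0, 0] > uniform[0, 0, 0]


class TestSiteFilterCascade:
    def make_stats(self, **overrides):
        base = dict(
            n_informative=[20] * 4,
            total_depth=[400] * 4,
            maf=[0.3] * 4,
            pval=[1e-12] * 4,
        )
        base.update(overrides)
        return pd.DataFrame(base)

    def test_all_passing_panel(self):
        keep, attrition = genolik.site_filter_cascade(self.make_stats(), 20)
        assert keep.all()
        assert all(v == 0 for v in attrition.values())

    def test_each_rule_fires_and_cascade_order_charges_first(self):
        stats = self.make_stats(
            n_informative=[18, 20, 20, 20],
            total_depth=[400, 6000, 400, 400],
            maf=[0.3, 0.3, 0.004, 0.3],
            pval=[1e-12, 1e-12, 1e-12, 1e-3],
        )
        keep, attrition = genolik.site_filter_cascade(stats, 20)
        assert not keep.any()
        assert attrition == {"min_ind": 1, "max_depth": 1, "min_maf": 1, "snp_pval": 1}
        # a site violating several rules is charged to the first in cascade order
        stats2 = self.make_stats(n_informative=[10, 20, 20, 20], maf=[0.001, 0.3, 0.3, 0.3])
        _, attr2 = genolik.site_filter_cascade(stats2, 20)
        assert attr2["min_ind"] == 1 and attr2["min_maf"] == 0

    def test_boundary_min_ind(self):
        # ceil(0.95 * 20) = 19: a 94%-informative site fails, 95% passes
        stats = self.make_stats(n_informative=[19, 18, 20, 20])
        keep, attrition = genolik.site_filter_cascade(stats, 20)
        assert keep.tolist() == [True, False, True, True]
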