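"""Round-1 HMM: conditioning selection, window imputation, ligation, confidence."""

import numpy as np
import pytest

from lcimpute import phase1, seqsim
from lcimpute.hmm import diploid_forward_backward, genotype_given_pair, switch_probs
from lcimpute.phase1 import HMMParams
from lcimpute.types import (GenotypeLikelihoods, HaplotypePanel, RegionSpec,
                            SiteReadCounts)

from _oracles import enumerate_diploid_posteriors, genotype_dist_by_flips


def flat_gl(n, s):
    return GenotypeLikelihoods(gl=np.ones((n, s, 3)))


def test_params_window_must_exceed_buffers():
    with pytest.raises(ValueError):
        HMMParams(window_bp=100, buffer_bp=60)


class TestConditioningSelection:
    def make_panel(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(6, 8)).astype(np.int8)
        alleles[0] = [0, 1, 0, 1, 0, 1, 0, 1]
        return HaplotypePanel(chrom="1", positions=np.arange(1, 9) * 100,
                              alleles=alleles)

    def test_perfect_match_ranked_first(self):
        panel = self.make_panel()
        # reads exactly homozygous for haplotype 0's alleles at every site
        g = (2 * panel.alleles[0]).astype(np.int8)[None, :]
        ref = np.where(g == 0, 5, 0)
        alt = np.where(g == 2, 5, 0)
        counts = SiteReadCounts(ref_count=ref, alt_count=alt,
                                nominal_depth=5.0, error_rate=0.0)
        gl = seqsim.genotype_likelihoods(counts)
        chosen = phase1.select_conditioning_haps(panel, gl, 0, 3)
        assert 0 in chosen

    def test_k_equals_h_returns_all(self):
        panel = self.make_panel()
        chosen = phase1.select_conditioning_haps(panel, flat_gl(1, 8), 0, 6)
        assert chosen.tolist() == list(range(6))

    def test_ranking_matches_brute_force_scores(self):
        panel = self.make_panel()
        rng = np.random.default_rng(2)
        raw = rng.random((1, 8, 3))
        gl = GenotypeLikelihoods(gl=raw / raw.max(axis=2, keepdims=True))
        chosen = phase1.select_conditioning_haps(panel, gl, 0, 3)
        # brute force: score by explicit loops over informative sites
        scores = []
        for h in range(6):
            s = 0.0
            for t in range(8):
                trip = gl.gl[0, t]
                if not (np.isclose(trip[0], trip[1]) and np.isclose(trip[1], trip[2])):
                    s += trip[2] if panel.alleles[h, t] == 1 else trip[0]
            scores.append(s)
        expected = sorted(sorted(range(6), key=lambda h: (-scores[h], h))[:3])
        assert chosen.tolist() == expected

    def test_no_coverage_falls_back_to_first_k(self):
        panel = self.make_panel()
        chosen = phase1.select_conditioning_haps(panel, flat_gl(1, 8), 0, 4)
        assert chosen.tolist() == [0, 1, 2, 3]


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("k,s,seed", [(2, 4, 0), (2, 6, 1), (3, 4, 2),
                                          (4, 3, 3), (3, 3, 4)])
    def test_state_posteriors_match_path_enumeration(self, k, s, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 2, size=(k, s)).astype(np.int8)
        raw = rng.random((s, 3)) + 0.05
        gl = raw / raw.max(axis=1, keepdims=True)
        positions = np.sort(rng.choice(10_000, size=s, replace=False)) + 1
        lam = 0.01
        rho = switch_probs(positions, 1000.0, 1e-6, k)

        pg_c = genotype_given_pair(lam)
        w = gl @ pg_c.T
        post, _ = diploid_forward_backward(alleles, w, rho)

        oracle_post, _ = enumerate_diploid_posteriors(alleles, gl, rho, lam)
        assert np.allclose(post, oracle_post, atol=1e-9)

    def test_genotype_posterior_matches_path_enumeration(self):
        """3-site, 4-haplotype window: gp equals the exhaustive path sum."""
        rng = np.random.default_rng(7)
        alleles = rng.integers(0, 2, size=(4, 3)).astype(np.int8)
        while np.any(alleles.min(axis=0) == alleles.max(axis=0)):
            alleles = rng.integers(0, 2, size=(4, 3)).astype(np.int8)
        positions = np.array([100, 700, 2000])
        panel = HaplotypePanel(chrom="1", positions=positions, alleles=alleles)
        raw = rng.random((1, 3, 3)) + 0.05
        gl = GenotypeLikelihoods(gl=raw / raw.max(axis=2, keepdims=True))
        params = HMMParams(n_states=4, ne=1000.0, recomb_rate=1e-6,
                           miscopy_rate=0.01)
        win = phase1.impute_window(panel, gl, params,
                                   RegionSpec("1", 1, 3000))
        rho = switch_probs(positions, params.ne, params.recomb_rate, 4)
        _, oracle_gp = enumerate_diploid_posteriors(alleles, gl.gl[0], rho,
                                                    params.miscopy_rate)
        assert np.allclose(win.gp[0], oracle_gp, atol=1e-9)


class TestImputeWindowEdgeCases:
    def test_identical_ref_haplotypes_force_prior(self):
        panel = HaplotypePanel(chrom="1", positions=np.array([10, 20, 30]),
                               alleles=np.zeros((4, 3), dtype=np.int8))
        params = HMMParams(n_states=4, miscopy_rate=0.0)
        win = phase1.impute_window(panel, flat_gl(2, 3), params,
                                   RegionSpec("1", 1, 100))
        assert np.allclose(win.gp, np.tile([1.0, 0.0, 0.0], (2, 3, 1)))

    def test_single_site_two_haplotypes_hardy_weinberg(self):
        panel = HaplotypePanel(chrom="1", positions=np.array([10]),
                               alleles=np.array([[0], [1]], dtype=np.int8))
        params = HMMParams(n_states=2, miscopy_rate=0.0)
        win = phase1.impute_window(panel, flat_gl(1, 1), params,
                                   RegionSpec("1", 1, 100))
        assert np.allclose(win.gp[0, 0], [0.25, 0.5, 0.25])

    def test_empty_region_returns_empty(self, small_panel):
        params = HMMParams()
        win = phase1.impute_window(small_panel, flat_gl(1, small_panel.n_sites),
                                   params, RegionSpec("1", 10**8, 10**8 + 10))
        assert win.site_idx.size == 0


class TestLigate:
    def run_window(self, panel, gl, params, region):
        return phase1.impute_window(panel, gl, params, region)

    def test_single_window_identity(self, small_panel):
        params = HMMParams(n_states=8)
        gl = flat_gl(2, small_panel.n_sites)
        region = RegionSpec("1", int(small_panel.positions[0]),
                            int(small_panel.positions[-1]))
        win = self.run_window(small_panel, gl, params, region)
        post = phase1.ligate([win], ["a", "b"], small_panel.n_sites)
        assert np.allclose(post.gp, win.gp)

    def test_core_region_wins(self, small_panel):
        """A site in the left window's buffer and the right window's core
        must take the right window's posterior."""
        params = HMMParams(n_states=8, window_bp=250_000, buffer_bp=50_000)
        rng = np.random.default_rng(3)
        raw = rng.random((1, small_panel.n_sites, 3)) + 0.05
        gl = GenotypeLikelihoods(gl=raw / raw.max(axis=2, keepdims=True))
        region = RegionSpec("1", int(small_panel.positions[0]),
                            int(small_panel.positions[-1]))
        wins = [self.run_window(small_panel, gl, params, w)
                for w in phase1.chunk_region(region, params)]
        post = phase1.ligate(wins, ["a"], small_panel.n_sites)
        left, right = wins[0], wins[1]
        shared = np.intersect1d(left.site_idx, right.site_idx)
        assert shared.size > 0
        for sidx in shared:
            pos = small_panel.positions[sidx]
            margin_l = min(pos - left.region.start, left.region.end - pos)
            margin_r = min(pos - right.region.start, right.region.end - pos)
            src, j = ((left, np.searchsorted(left.site_idx, sidx))
                      if margin_l > margin_r
                      else (right, np.searchsorted(right.site_idx, sidx)))
            assert np.allclose(post.gp[0, sidx], src.gp[0, j])

    def test_gap_is_hard_error(self, small_panel):
        params = HMMParams(n_states=8)
        gl = flat_gl(1, small_panel.n_sites)
        win = self.run_window(small_panel, gl, params,
                              RegionSpec("1", int(small_panel.positions[0]),
                                         int(small_panel.positions[100])))
        with pytest.raises(ValueError, match="gap"):
            phase1.ligate([win], ["a"], small_panel.n_sites)


class TestSelectConfident:
    def test_tau_bounds(self, small_panel, small_counts):
        gl = seqsim.genotype_likelihoods(small_counts)
        post = phase1.impute_round1(small_panel, gl, small_counts, HMMParams())
        with pytest.raises(ValueError):
            phase1.select_confident(post, small_counts, tau=0.4)

    def test_uncovered_site_never_typed(self, small_panel, small_truth):
        counts = seqsim.simulate_reads(small_truth, depth=0.05, seed=21)
        gl = seqsim.genotype_likelihoods(counts)
        post = phase1.impute_round1(small_panel, gl, counts, HMMParams(),
                                    sample_ids=small_truth.sample_ids)
        uncovered = counts.total.sum(axis=0) == 0
        assert uncovered.any()
        assert not post.confident[:, uncovered].any()

    def test_confident_sites_are_more_accurate(self, small_panel, small_truth,
                                               small_counts):
        gl = seqsim.genotype_likelihoods(small_counts)
        post = phase1.impute_round1(small_panel, gl, small_counts, HMMParams(),
                                    sample_ids=small_truth.sample_ids)
        correct = post.gt == small_truth.genotypes
        conf, nonconf = post.confident, ~post.confident
        assert conf.any() and nonconf.any()
        assert correct[conf].mean() >= correct[nonconf].mean()


def test_high_depth_calls_converge_to_truth(small_panel, small_truth):
    """With error-free reads at 30x, every hard call matches the truth."""
    counts = seqsim.simulate_reads(small_truth, depth=30.0, error_rate=0.0, seed=30)
    gl = seqsim.genotype_likelihoods(counts)
    post = phase1.impute_round1(small_panel, gl, counts, HMMParams(),
                                sample_ids=small_truth.sample_ids)
    assert np.array_equal(post.gt, small_truth.genotypes)


def test_round1_deterministic(small_panel, small_counts):
    gl = seqsim.genotype_likelihoods(small_counts)
    a = phase1.impute_round1(small_panel, gl, small_counts, HMMParams())
    b = phase1.impute_round1(small_panel, gl, small_counts, HMMParams())
    assert np.array_equal(a.gp, b.gp)
    assert np.array_equal(a.confident, b.confident)
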