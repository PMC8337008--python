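import numpy as np
import pytest

from oracles import (
    direct_mle,
    enum_log_likelihood,
    enum_posterior_transitions,
    enum_signature_distribution,
)
from spliceusage import (
    ChainParameters,
    SignatureCounts,
    SimulationConfig,
    check_identifiability,
    em_fit,
    estimates_table,
    signature_log_likelihood,
    signature_probabilities,
    simulate_reads,
)
from spliceusage.gene_model import GeneSegmentation
from spliceusage.inference import expected_stats


def expected_count_data(theta, seg, L, N=10_000.0):
    """Noise-free data: expected signature counts N * P(g)."""
    dist = enum_signature_distribution(theta, seg, L)
    return SignatureCounts(seg.gene_id, {s: N * p for s, p in dist.items()}, L)


class TestSignatureLikelihood:
    def test_probabilities_sum_to_one_and_match_enumeration(self, cassette_seg):
        L = 50
        for seed in range(4):
            theta = ChainParameters.random(cassette_seg, seed)
            dist = enum_signature_distribution(theta, cassette_seg, L)
            counts = SignatureCounts("cassette", {s: 1.0 for s in dist}, L)
            probs = signature_probabilities(counts, theta, cassette_seg)
            assert probs.sum() == pytest.approx(1.0, abs=1e-10)
            for (sig, _), p in zip(counts.sorted_items(), probs):
                assert p == pytest.approx(dist[sig], rel=1e-10, abs=1e-12)

    def test_single_segment_gene_likelihood_is_flat_zero(self):
        """With one segment there is one possible signature; its probability
        is 1 whatever pi, so the log-likelihood is 0 (pi unidentifiable)."""
        seg = GeneSegmentation.from_lengths([400], [], gene_id="g")
        counts = SignatureCounts("g", {(1,): 50}, 100)
        for pi in (0.1, 0.5, 0.9):
            theta = ChainParameters(pi, [], [])
            assert signature_log_likelihood(counts, theta, seg) == pytest.approx(0.0)

    def test_matches_enumeration_log_likelihood(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=5000, read_length=50, seed=2)
        )
        for seed in range(3):
            theta = ChainParameters.random(cassette_seg, seed)
            got = signature_log_likelihood(counts, theta, cassette_seg)
            want = enum_log_likelihood(counts, theta, cassette_seg)
            assert got == pytest.approx(want, rel=1e-10)

    def test_truth_beats_perturbation_at_large_N(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=50_000, read_length=50, seed=3)
        )
        ll_star = signature_log_likelihood(counts, theta_star, cassette_seg)
        perturbed = ChainParameters(0.75, [0.45, 0.75], [0.7, 0.65])
        assert ll_star > signature_log_likelihood(counts, perturbed, cassette_seg)


class TestEStep:
    def test_posterior_transitions_match_enumeration(self, cassette_seg):
        """Expected transition counts from the forward-backward E-step agree
        with the posterior computed by enumerating consistent paths."""
        L = 50
        theta = ChainParameters.random(cassette_seg, 11)
        dist = enum_signature_distribution(theta, cassette_seg, L)
        sigs = sorted(dist)
        a_p = np.zeros(cassette_seg.M_s)
        b_p = np.zeros(cassette_seg.M_s)
        a_q = np.zeros(cassette_seg.M_e)
        b_q = np.zeros(cassette_seg.M_e)
        c1 = 0.0
        counts = SignatureCounts("cassette", {s: 100.0 * dist[s] for s in sigs}, L)
        for sig, c in counts.sorted_items():
            post = enum_posterior_transitions(theta, cassette_seg, sig)
            for i, b in enumerate(cassette_seg.boundaries):
                m = b.param_index - 1
                if b.kind == "start_site":
                    a_p[m] += c * post[i, 0, 1]
                    b_p[m] += c * post[i, 0, 0]
                else:
                    a_q[m] += c * post[i, 1, 0]
                    b_q[m] += c * post[i, 1, 1]
            c1 += c * (post[0, 1, 0] + post[0, 1, 1])
        stats = expected_stats(counts, theta, cassette_seg)
        np.testing.assert_allclose(stats.a_p, a_p, atol=1e-9)
        np.testing.assert_allclose(stats.b_p, b_p, atol=1e-9)
        np.testing.assert_allclose(stats.a_q, a_q, atol=1e-9)
        np.testing.assert_allclose(stats.b_q, b_q, atol=1e-9)
        assert stats.c1 == pytest.approx(c1, abs=1e-9)


class TestEmFit:
    def test_monotone_loglik_and_recovery(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=20_000, read_length=50, seed=5)
        )
        fit = em_fit(counts, cassette_seg, tol=1e-9)
        assert fit.converged
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        assert np.abs(fit.theta.to_vector() - theta_star.to_vector()).max() < 0.05

    def test_finds_enumeration_mle_on_noise_free_data(self, cassette_seg):
        """On expected-count data the EM optimum matches direct numerical
        maximization of the enumeration likelihood."""
        theta_star = ChainParameters(0.8, [0.55, 0.85], [0.7, 0.65])
        counts = expected_count_data(theta_star, cassette_seg, L=50)
        fit = em_fit(counts, cassette_seg, tol=1e-13, max_iter=5000)
        vec, ll = direct_mle(
            counts, cassette_seg,
            starts=[np.full(5, 0.5), fit.theta.to_vector(), theta_star.to_vector()],
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        np.testing.assert_allclose(fit.theta.to_vector(), vec, atol=1e-4)

    def test_permutation_invariance(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=2000, read_length=50, seed=6)
        )
        shuffled = SignatureCounts(
            counts.gene_id,
            dict(reversed(list(counts.entries.items()))),
            counts.read_length,
        )
        a = em_fit(counts, cassette_seg, tol=1e-9)
        b = em_fit(shuffled, cassette_seg, tol=1e-9)
        np.testing.assert_array_equal(a.theta.to_vector(), b.theta.to_vector())

    def test_single_segment_gene_flags_pi_unidentifiable(self):
        seg = GeneSegmentation.from_lengths([400], [], gene_id="g")
        counts = SignatureCounts("g", {(1,): 50}, 100)
        fit = em_fit(counts, seg)
        assert fit.identifiable["pi"] is False
        assert np.all(np.diff(fit.loglik_trace) == 0.0)

    def test_pure_inclusion_pushes_cassette_usage_to_boundary(self, cassette_seg):
        """Counts containing only full-inclusion signatures drive the
        cassette acceptor usage to the parameter-space boundary."""
        # sole transcript: exon - cassette - exon with introns spliced out
        theta_all_in = ChainParameters(1.0, [1.0, 1.0], [1.0, 1.0])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_all_in, n_reads=5000, read_length=60, seed=9)
        )
        fit = em_fit(counts, cassette_seg, tol=1e-10)
        table = estimates_table(fit, cassette_seg, counts)
        cassette_acceptor = table[table["parameter"] == "p1"].iloc[0]
        assert cassette_acceptor["estimate"] == pytest.approx(1.0, abs=1e-6)

    def test_rejects_empty_counts(self, cassette_seg):
        with pytest.raises(ValueError, match="no signature counts"):
            em_fit(SignatureCounts("cassette", {}, 50), cassette_seg)

    def test_drops_structurally_impossible_signature(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=1000, read_length=50, seed=7)
        )
        # (2, 4) splices out of X3 at the cassette acceptor, i.e. an exon
        # ending at a start site: impossible under the chain
        bad = dict(counts.entries)
        bad[(2, 4)] = 4.0
        with pytest.warns(UserWarning, match="inconsistent"):
            fit = em_fit(
                SignatureCounts("cassette", bad, 50), cassette_seg, tol=1e-9
            )
        assert fit.dropped_signatures == [(2, 4)]


class TestIdentifiability:
    def test_uncovered_boundary_is_flagged(self, cassette_seg):
        # reads only on segments 4/5: nothing supports boundaries 1-2
        counts = SignatureCounts("cassette", {(4, 5): 30, (5,): 10}, 50)
        flags = check_identifiability(counts, cassette_seg)
        assert not flags["pi"]
        assert flags["q"].tolist() == [False, True]  # e1 at boundary 1, e2 at 3
        assert flags["p"].tolist() == [False, True]  # s1 at boundary 2, s2 at 4

    def test_full_coverage_all_identifiable(self, cassette_seg):
        theta_star = ChainParameters(0.9, [0.6, 0.9], [0.85, 0.8])
        counts, _ = simulate_reads(
            SimulationConfig(cassette_seg, theta_star, n_reads=5000, read_length=50, seed=8)
        )
        flags = check_identifiability(counts, cassette_seg)
        assert flags["pi"]
        assert all(flags["p"]) and all(flags["q"])

    def test_pi_responds_to_segment1_coverage(self, cassette_seg):
        """Reads covering segment 1 in some signatures make the likelihood
        vary in pi (finite-difference check)."""
        counts = SignatureCounts("cassette", {(1,): 40, (1, 2): 5, (3,): 20}, 50)
        base = ChainParameters(0.5, [0.5, 0.5], [0.5, 0.5])
        up = ChainParameters(0.6, [0.5, 0.5], [0.5, 0.5])
        assert check_identifiability(counts, cassette_seg)["pi"]
        assert signature_log_likelihood(counts, base, cassette_seg) != pytest.approx(
            signature_log_likelihood(counts, up, cassette_seg), abs=1e-9
        )
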