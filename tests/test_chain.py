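import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import enum_effective_length, enum_marginal_usage, enum_marginals
from spliceusage import (
    ChainParameters,
    TranscriptPath,
    enumerate_paths,
    expected_effective_length,
    marginal_site_usage,
    path_probability,
    random_segmentation,
    terminal_end_usage,
    transcribed_marginals,
)
from spliceusage.gene_model import END_SITE, START_SITE, GeneSegmentation


class TestPathProbability:
    def test_worked_example_transcripts(self, example_seg, example_theta):
        """The three example transcripts' chain probabilities equal the
        hand-derived per-boundary factor products."""
        pi, p, q = example_theta.pi, example_theta.p, example_theta.q
        cases = {
            (1, 1, 0, 1, 0, 0, 1, 1): pi * q[0] * p[1] * q[1] * (1 - p[2]) * p[3] * (1 - q[2]),
            (0, 1, 0, 0, 0, 1, 1, 1): (1 - pi) * p[0] * q[0] * (1 - p[1]) * p[2] * (1 - q[2]),
            (1, 1, 0, 0, 0, 0, 1, 0): pi * q[0] * (1 - p[1]) * (1 - p[2]) * p[3] * q[2],
        }
        for Z, expected in cases.items():
            assert path_probability(Z, example_theta, example_seg) == pytest.approx(
                expected, abs=1e-15
            )

    def test_forced_transitions_single_path(self, example_seg):
        theta = ChainParameters(1.0, np.ones(4), np.zeros(3))
        assert path_probability(np.ones(8), theta, example_seg) == 1.0
        assert path_probability((1, 1, 1, 1, 1, 1, 1, 0), theta, example_seg) == 0.0

    def test_read_through_at_start_site_is_forced(self, example_seg, example_theta):
        """A 1->0 transition at a start site is impossible (an exon cannot
        end at an acceptor)."""
        Z = (1, 0, 0, 0, 0, 0, 1, 1)  # boundary 1 is start site s1
        assert path_probability(Z, example_theta, example_seg) == 0.0

    def test_dimension_mismatch_rejected(self, example_seg, example_theta):
        with pytest.raises(ValueError, match="length"):
            path_probability((1, 0), example_theta, example_seg)


class TestEnumeratePaths:
    def test_single_segment_gene(self):
        seg = GeneSegmentation.from_lengths([300], [], gene_id="g")
        theta = ChainParameters(0.3, [], [])
        Z, w = enumerate_paths(theta, seg)
        assert Z.tolist() == [[0], [1]]
        assert np.allclose(w, [0.7, 0.3])

    @given(seed=st.integers(0, 10_000))
    def test_normalization(self, seed):
        """Path probabilities sum to one for any segmentation and Theta."""
        rng = np.random.default_rng(seed)
        seg = random_segmentation(rng, M_s=int(rng.integers(0, 5)), M_e=int(rng.integers(0, 5)))
        theta = ChainParameters.random(seg, rng, low=0.0, high=1.0)
        _, w = enumerate_paths(theta, seg)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_path_probability(self, example_seg, example_theta):
        Z, w = enumerate_paths(example_theta, example_seg)
        for row, prob in zip(Z[::17], w[::17]):
            assert prob == pytest.approx(
                path_probability(row, example_theta, example_seg), abs=1e-14
            )

    def test_refuses_large_M(self):
        seg = GeneSegmentation.from_lengths(
            np.full(22, 50), [START_SITE, END_SITE] * 10 + [START_SITE], gene_id="g"
        )
        with pytest.raises(ValueError, match="enumeration"):
            enumerate_paths(ChainParameters.uniform(seg), seg)


class TestMarginals:
    def test_matches_enumeration(self, example_seg):
        for seed in range(5):
            theta = ChainParameters.random(example_seg, seed)
            got = transcribed_marginals(theta, example_seg)
            np.testing.assert_allclose(got, enum_marginals(theta, example_seg), atol=1e-12)

    def test_degenerate_all_included(self, example_seg):
        theta = ChainParameters(1.0, np.ones(4), np.zeros(3))
        assert np.allclose(transcribed_marginals(theta, example_seg), 1.0)

    def test_single_segment_marginal_is_pi(self):
        seg = GeneSegmentation.from_lengths([100], [], gene_id="g")
        theta = ChainParameters(0.42, [], [])
        assert transcribed_marginals(theta, seg) == pytest.approx([0.42])


class TestEffectiveLength:
    def test_single_path_closed_form(self):
        seg = GeneSegmentation.from_lengths([200, 300], [END_SITE], gene_id="g")
        theta = ChainParameters(1.0, [], [0.0])
        assert expected_effective_length(theta, seg, 100) == pytest.approx(401.0)

    def test_matches_enumeration(self, example_seg):
        for seed in range(5):
            theta = ChainParameters.random(example_seg, seed)
            for L in (1, 50, 100, 350):
                got = expected_effective_length(theta, example_seg, L)
                want = enum_effective_length(theta, example_seg, L)
                assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_short_transcripts_emit_nothing(self):
        seg = GeneSegmentation.from_lengths([30, 40], [END_SITE], gene_id="g")
        theta = ChainParameters(1.0, [], [1.0])  # only path: segment 1 alone
        assert expected_effective_length(theta, seg, 100) == 0.0

    def test_linearity_shortcut_when_all_paths_long(self, example_seg):
        """When every positive-probability path has tl >= L, the expected
        effective length reduces to sum_i len_i P(Z_i=1) - (L-1) P(any)."""
        theta = ChainParameters(1.0, np.full(4, 0.5), np.full(3, 0.5))  # Z1=1 always
        L = 100  # shortest transcript is segment 1 alone? no: q forces nothing
        marg = transcribed_marginals(theta, example_seg)
        shortcut = float(example_seg.segment_lengths @ marg) - (L - 1)
        got = expected_effective_length(theta, example_seg, L)
        assert got == pytest.approx(shortcut, rel=1e-12)


class TestSiteUsage:
    def test_marginal_usage_matches_enumeration(self, example_seg):
        for seed in range(5):
            theta = ChainParameters.random(example_seg, seed)
            got = marginal_site_usage(theta, example_seg)["marginal_usage"].to_numpy()
            np.testing.assert_allclose(
                got, enum_marginal_usage(theta, example_seg), atol=1e-12
            )

    def test_start_site_marginal_equals_conditional_when_always_considered(self):
        # pi=0: no transcript reads through the first boundary
        seg = GeneSegmentation.from_lengths([100, 100, 100], [START_SITE, END_SITE], "g")
        theta = ChainParameters(0.0, [0.37], [0.8])
        table = marginal_site_usage(theta, seg)
        assert table.loc[0, "marginal_usage"] == pytest.approx(0.37)

    def test_monotone_in_conditional_usage(self, example_seg):
        rng = np.random.default_rng(5)
        base = ChainParameters.random(example_seg, rng)
        for m in range(example_seg.M_s):
            values = []
            for x in np.linspace(0.05, 0.95, 7):
                p = base.p.copy()
                p[m] = x
                theta = ChainParameters(base.pi, p, base.q)
                table = marginal_site_usage(theta, example_seg)
                row = table[(table["kind"] == START_SITE) & (table["param_index"] == m + 1)]
                values.append(float(row["marginal_usage"].iloc[0]))
            assert np.all(np.diff(values) >= -1e-12)

    def test_terminal_end_site_usage_is_one(self, example_seg):
        """The gene TES is always used by transcripts that reach it."""
        for seed in range(50):
            theta = ChainParameters.random(example_seg, seed, low=0.01, high=0.99)
            assert terminal_end_usage(theta, example_seg) == 1.0


class TestTranscriptPath:
    def test_effective_length_rule(self, example_seg):
        path = TranscriptPath.from_states((1, 1, 0, 1, 0, 0, 1, 1), example_seg)
        tl = int(example_seg.segment_lengths[[0, 1, 3, 6, 7]].sum())
        assert path.transcribed_length == tl
        assert path.effective_length(100) == tl - 99
        assert path.effective_length(tl + 1) == 0
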