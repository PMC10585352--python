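"""CRF dynamic programs checked against explicit path enumeration."""

import numpy as np
import pytest

from peptidecrf.crf import (
    CrfParameters,
    expand_emissions,
    forward_log_partition,
    nll_loss,
    nll_loss_and_gradients,
    posterior_marginals,
    viterbi_decode,
)
from peptidecrf.state_space import build_state_space

from conftest import (
    enumerate_valid_paths,
    oracle_best,
    oracle_class_marginals,
    oracle_log_partition,
    oracle_path_score,
)


def random_instance(space, T, rng, scale=1.0):
    e = rng.normal(scale=scale, size=(T, space.n_classes))
    params = CrfParameters.zeros(space)
    params.transition_weights[space.allowed_transition] = rng.normal(
        scale=0.5, size=int(space.allowed_transition.sum())
    )
    return e, params


class TestExpandEmissions:
    def test_tying_definition(self, paper_space):
        e = np.array([[1.0, 2.0, 3.0]])
        tiled = expand_emissions(e, paper_space)
        assert tiled.shape == (1, 101)
        assert np.sum(tiled == 1.0) == 1
        assert np.sum(tiled == 2.0) == 50
        assert np.sum(tiled == 3.0) == 50

    def test_zero_emissions_and_column_dependence(self, paper_space):
        assert not expand_emissions(np.zeros((4, 3)), paper_space).any()
        a = expand_emissions(np.zeros((1, 3)), paper_space)
        b = np.zeros((1, 3))
        b[0, 1] = 7.0
        diff = expand_emissions(b, paper_space) - a
        assert np.sum(diff != 0) == 50

    def test_shape_mismatch(self, paper_space):
        with pytest.raises(ValueError):
            expand_emissions(np.zeros((4, 2)), paper_space)


class TestOracleEquivalence:
    """Agreement with full path enumeration on small instances."""

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("config", [(2, 3, 1), (2, 4, 2), (1, 2, 2), (3, 4, 1)])
    def test_log_partition_viterbi_marginals(self, seed, config):
        min_len, max_len, n_classes = config
        space = build_state_space(min_len, max_len,
                                  ["Peptide", "Propeptide"][:n_classes])
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 7))
        e, params = random_instance(space, T, rng)
        W = params.transition_weights

        assert forward_log_partition(e, params) == pytest.approx(
            oracle_log_partition(e, W, space), abs=1e-8
        )
        best_score, best_paths = oracle_best(e, W, space)
        decoding = viterbi_decode(e, params)
        assert decoding.score == pytest.approx(best_score, abs=1e-8)
        assert tuple(decoding.state_path) in best_paths
        marg = posterior_marginals(e, params).class_posteriors
        np.testing.assert_allclose(
            marg, oracle_class_marginals(e, W, space), atol=1e-8
        )

    def test_zero_scores_count_paths(self, tiny_space):
        for T in (1, 3, 5, 6):
            e = np.zeros((T, tiny_space.n_classes))
            params = CrfParameters.zeros(tiny_space)
            n_paths = len(enumerate_valid_paths(tiny_space, T))
            assert forward_log_partition(e, params) == pytest.approx(
                np.log(n_paths), abs=1e-10
            )

    def test_single_position_with_min_len_above_one(self, tiny_space):
        # T=1: only the background state is final-allowed when min_len > 1
        e = np.array([[0.7, 2.5]])
        params = CrfParameters.zeros(tiny_space)
        assert forward_log_partition(e, params) == pytest.approx(0.7)

    def test_nll_equals_minus_log_path_probability(self, two_class_tiny_space):
        space = two_class_tiny_space
        rng = np.random.default_rng(7)
        for _ in range(10):
            T = int(rng.integers(2, 7))
            e, params = random_instance(space, T, rng)
            paths = enumerate_valid_paths(space, T)
            scores = np.array([
                oracle_path_score(e, params.transition_weights, space, p)
                for p in paths
            ])
            probs = np.exp(scores - scores.max())
            probs /= probs.sum()
            y = paths[int(rng.integers(len(paths)))]
            loss = nll_loss(e, params, np.array(y))
            assert loss >= -1e-12
            assert loss == pytest.approx(-np.log(probs[paths.index(y)]), abs=1e-8)

    def test_path_probabilities_sum_to_one(self, tiny_space):
        rng = np.random.default_rng(3)
        e, params = random_instance(tiny_space, 5, rng)
        total = sum(
            np.exp(-nll_loss(e, params, np.array(p)))
            for p in enumerate_valid_paths(tiny_space, 5)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_path_rejected(self, tiny_space):
        e = np.zeros((3, 2))
        params = CrfParameters.zeros(tiny_space)
        first = tiny_space.state_index("Peptide", 1)
        with pytest.raises(ValueError):
            nll_loss(e, params, np.array([first, 0, 0]))  # exit below min_len


class TestViterbiProperties:
    def test_short_sequence_decodes_all_background(self, paper_space):
        rng = np.random.default_rng(0)
        params = CrfParameters.zeros(paper_space)
        for T in (1, 2, 3, 4):
            e = rng.normal(scale=10.0, size=(T, 3))
            decoding = viterbi_decode(e, params)
            assert (decoding.state_path == 0).all()
            assert decoding.spans == []

    def test_forced_span_location(self):
        # strongly peptide-favoring emissions at positions 10..16 of T=30
        space = build_state_space(5, 50, ["Peptide", "Propeptide"])
        e = np.zeros((30, 3))
        e[:, 0] = 2.0
        e[10:17, 0] = -5.0
        e[10:17, 1] = 5.0
        decoding = viterbi_decode(e, CrfParameters.zeros(space))
        assert decoding.spans == [(10, 17, "Peptide")]

    def test_decoded_spans_respect_length_bounds(self, paper_space):
        rng = np.random.default_rng(42)
        params = CrfParameters.zeros(paper_space)
        for _ in range(200):
            T = int(rng.integers(1, 70))
            e = rng.normal(size=(T, 3))
            decoding = viterbi_decode(e, params)
            for start, end, _ in decoding.spans:
                assert paper_space.min_len <= end - start <= paper_space.max_len
            # no cross-class adjacency along the merged labels
            cls = decoding.class_labels
            for t in range(T - 1):
                if cls[t] > 0 and cls[t + 1] > 0:
                    assert cls[t] == cls[t + 1]

    def test_viterbi_score_bounded_by_log_partition(self, two_class_tiny_space):
        rng = np.random.default_rng(11)
        for _ in range(20):
            e, params = random_instance(two_class_tiny_space, int(rng.integers(1, 8)), rng)
            v = viterbi_decode(e, params).score
            assert v <= forward_log_partition(e, params) + 1e-10

    def test_tie_breaking_is_deterministic(self, two_class_tiny_space):
        e = np.zeros((6, 3))
        params = CrfParameters.zeros(two_class_tiny_space)
        a = viterbi_decode(e, params).state_path
        b = viterbi_decode(e, params).state_path
        assert (a == b).all()
        assert (a == 0).all()  # all scores tie; lowest state index wins


class TestMarginals:
    def test_rows_on_simplex(self, paper_space):
        rng = np.random.default_rng(5)
        params = CrfParameters.zeros(paper_space)
        for _ in range(10):
            e = rng.normal(scale=3.0, size=(int(rng.integers(1, 40)), 3))
            post = posterior_marginals(e, params).class_posteriors
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)
            assert (post >= -1e-12).all() and (post <= 1 + 1e-12).all()

    def test_no_span_probability_below_min_len(self, paper_space):
        e = np.random.default_rng(1).normal(size=(3, 3))
        post = posterior_marginals(e, CrfParameters.zeros(paper_space)).class_posteriors
        np.testing.assert_allclose(post[:, 1:], 0.0, atol=1e-12)


class TestGradients:
    def _fd_check(self, space, T, seed):
        rng = np.random.default_rng(seed)
        e = rng.normal(size=(T, space.n_classes))
        params = CrfParameters.zeros(space)
        params.transition_weights[space.allowed_transition] = rng.normal(
            scale=0.3, size=int(space.allowed_transition.sum())
        )
        paths = enumerate_valid_paths(space, T)
        y = np.array(paths[int(rng.integers(len(paths)))])
        loss, d_e, d_trans = nll_loss_and_gradients(e, params, y)
        eps = 1e-6
        for t in range(T):
            for k in range(space.n_classes):
                e2 = e.copy(); e2[t, k] += eps
                e3 = e.copy(); e3[t, k] -= eps
                fd = (nll_loss(e2, params, y) - nll_loss(e3, params, y)) / (2 * eps)
                assert d_e[t, k] == pytest.approx(fd, abs=2e-5)
        idx = np.argwhere(space.allowed_transition)
        for i, j in idx[:: max(1, len(idx) // 10)]:
            p2 = CrfParameters(params.transition_weights.copy(), space)
            p2.transition_weights[i, j] += eps
            p3 = CrfParameters(params.transition_weights.copy(), space)
            p3.transition_weights[i, j] -= eps
            fd = (nll_loss(e, p2, y) - nll_loss(e, p3, y)) / (2 * eps)
            denom = max(abs(fd), abs(d_trans[i, j]), 1e-3)
            assert abs(d_trans[i, j] - fd) / denom < 1e-4

    def test_finite_difference_agreement(self, tiny_space, two_class_tiny_space):
        self._fd_check(tiny_space, 5, 0)
        self._fd_check(two_class_tiny_space, 6, 1)

    def test_sharpening_emissions_never_hurts_viterbi_path(self, two_class_tiny_space):
        rng = np.random.default_rng(9)
        params = CrfParameters.zeros(two_class_tiny_space)
        for _ in range(20):
            e = rng.normal(size=(int(rng.integers(2, 8)), 3))
            y = viterbi_decode(e, params).state_path
            assert nll_loss(2 * e, params, y) <= nll_loss(e, params, y) + 1e-9
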