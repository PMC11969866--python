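import itertools

import numpy as np
import pytest

import paraner.autodiff as ad
from paraner.autodiff import Tensor
from paraner.fusion_decoder import (
    AttentionParams,
    CRFParams,
    GateParams,
    attention_fuse,
    crf_decode,
    crf_nll,
    crf_nll_t,
    crf_score,
    gate_fuse,
)


def make_attn_params(rng, d, dh, dv):
    def t(shape):
        return Tensor(rng.standard_normal(shape) * 0.3)

    return AttentionParams(P_e=t((d, dv)), b_e=t((dv,)),
                           P_q=t((d + dh, dv)), b_q=t((dv,)),
                           P_h=t((dh, dv)), b_h=t((dv,)))


class TestAttentionFuse:
    def test_rows_sum_to_one(self, rng):
        p = make_attn_params(rng, 4, 6, 5)
        for _ in range(100):
            out = attention_fuse(rng.standard_normal((3, 4)),
                                 rng.standard_normal((3, 6)), p)
            np.testing.assert_allclose(out.attention.sum(axis=1),
                                       np.ones(3), atol=1e-12)

    def test_single_token_convex_combination(self, rng):
        p = make_attn_params(rng, 4, 6, 5)
        E, H = rng.standard_normal((1, 4)), rng.standard_normal((1, 6))
        out = attention_fuse(E, H, p)
        assert out.attention.shape == (1, 2)
        ve = E @ p.P_e.data + p.b_e.data
        vh = H @ p.P_h.data + p.b_h.data
        expect = out.attention[0, 0] * ve[0] + out.attention[0, 1] * vh[0]
        np.testing.assert_allclose(out.matrix[0], expect, atol=1e-12)

    def test_low_temperature_converges_to_argmax_row(self, rng):
        p = make_attn_params(rng, 4, 6, 5)
        E, H = rng.standard_normal((4, 4)), rng.standard_normal((4, 6))
        sharp = attention_fuse(E, H, p, temperature=1e-3)
        V = np.vstack([E @ p.P_e.data + p.b_e.data,
                       H @ p.P_h.data + p.b_h.data])
        soft = attention_fuse(E, H, p)
        for t in range(4):
            best = int(soft.attention[t].argmax())
            np.testing.assert_allclose(sharp.matrix[t], V[best], atol=1e-4)

    def test_misaligned_streams_rejected(self, rng):
        p = make_attn_params(rng, 4, 6, 5)
        with pytest.raises(ValueError, match="aligned"):
            attention_fuse(rng.standard_normal((3, 4)),
                           rng.standard_normal((2, 6)), p)

    def test_ablated_attention_is_elementwise_sum(self, rng):
        p = make_attn_params(rng, 4, 6, 5)
        E, H = rng.standard_normal((3, 4)), rng.standard_normal((3, 6))
        out = attention_fuse(E, H, p, use_attention=False)
        expect = (E @ p.P_e.data + p.b_e.data) + (H @ p.P_h.data + p.b_h.data)
        np.testing.assert_allclose(out.matrix, expect, atol=1e-12)


class TestGateFuse:
    def zero_params(self, d):
        z = lambda shape: Tensor(np.zeros(shape))
        return GateParams(W_o=z((d, d)), b_o=z((d,)),
                          W_d=z((d, d)), b_d=z((d,)))

    def test_zero_parameters_average(self, rng):
        O, D = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        h = gate_fuse(O, D, self.zero_params(4)).matrix
        np.testing.assert_allclose(h, (O + D) / 2, atol=1e-12)

    def test_saturated_gate_selects_o(self, rng):
        p = self.zero_params(4)
        p.b_o.data[:] = 50.0
        O, D = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        np.testing.assert_allclose(gate_fuse(O, D, p).matrix, O, atol=1e-6)

    def test_equal_inputs_pass_through(self, rng):
        p = GateParams(*(Tensor(rng.standard_normal(s)) for s in
                         [(4, 4), (4,), (4, 4), (4,)]))
        O = rng.standard_normal((3, 4))
        np.testing.assert_allclose(gate_fuse(O, O.copy(), p).matrix, O,
                                   atol=1e-12)

    def test_output_boxed_by_inputs(self, rng):
        p = GateParams(*(Tensor(rng.standard_normal(s)) for s in
                         [(4, 4), (4,), (4, 4), (4,)]))
        O, D = rng.standard_normal((5, 4)), rng.standard_normal((5, 4))
        h = gate_fuse(O, D, p).matrix
        assert np.all(h >= np.minimum(O, D) - 1e-12)
        assert np.all(h <= np.maximum(O, D) + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gate_fuse(rng.standard_normal((3, 4)),
                      rng.standard_normal((3, 5)), self.zero_params(4))

    def test_ablated_gate_is_sum(self, rng):
        O, D = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        h = gate_fuse(O, D, self.zero_params(4), use_gate=False).matrix
        np.testing.assert_allclose(h, O + D, atol=1e-12)


def random_crf(rng, L):
    return CRFParams(transitions=Tensor(rng.standard_normal((L, L))),
                     start=Tensor(rng.standard_normal(L)),
                     end=Tensor(rng.standard_normal(L)))


def brute_scores(emissions, crf):
    n, L = emissions.shape
    out = {}
    for path in itertools.product(range(L), repeat=n):
        out[path] = crf_score(emissions, crf.transitions.data,
                              crf.start.data, crf.end.data, list(path))
    return out


class TestCRF:
    def test_score_single_token(self, rng):
        crf = random_crf(rng, 3)
        em = rng.standard_normal((1, 3))
        for y in range(3):
            expect = crf.start.data[y] + em[0, y] + crf.end.data[y]
            assert crf_score(em, crf.transitions.data, crf.start.data,
                             crf.end.data, [y]) == pytest.approx(expect)

    def test_zero_parameters_zero_score(self):
        em = np.zeros((4, 3))
        zero = np.zeros((3, 3))
        for path in ([0, 1, 2, 0], [2, 2, 2, 2]):
            assert crf_score(em, zero, np.zeros(3), np.zeros(3), path) == 0.0

    def test_score_matches_handloop_on_all_paths(self, rng):
        crf = random_crf(rng, 3)
        em = rng.standard_normal((3, 3))
        for path, score in brute_scores(em, crf).items():
            hand = (crf.start.data[path[0]] + crf.end.data[path[-1]]
                    + sum(em[t, y] for t, y in enumerate(path))
                    + sum(crf.transitions.data[a, b]
                          for a, b in zip(path, path[1:])))
            assert score == pytest.approx(hand)

    def test_out_of_range_label_rejected(self, rng):
        crf = random_crf(rng, 3)
        with pytest.raises(IndexError):
            crf_score(np.zeros((2, 3)), crf.transitions.data,
                      crf.start.data, crf.end.data, [0, 3])

    def test_nll_partition_matches_explicit_sum(self, rng):
        crf = random_crf(rng, 3)
        em = rng.standard_normal((4, 3))
        scores = brute_scores(em, crf)
        log_z = np.logaddexp.reduce(np.array(list(scores.values())))
        gold = [1, 0, 2, 1]
        expect = log_z - scores[tuple(gold)]
        assert crf_nll(em, crf, gold) == pytest.approx(expect, abs=1e-6)

    def test_nll_single_label_degenerate(self, rng):
        crf = random_crf(rng, 1)
        em = rng.standard_normal((5, 1))
        assert crf_nll(em, crf, [0] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_nll_nonnegative(self, rng):
        for _ in range(50):
            L = int(rng.integers(2, 5))
            n = int(rng.integers(1, 6))
            crf = random_crf(rng, L)
            em = rng.standard_normal((n, L))
            gold = list(rng.integers(0, L, size=n))
            assert crf_nll(em, crf, gold) >= -1e-12

    def test_viterbi_matches_exhaustive_max(self, rng):
        """Primary oracle: 200 random small instances."""
        for _ in range(200):
            L = int(rng.integers(1, 5))
            n = int(rng.integers(1, 7))
            crf = random_crf(rng, L)
            em = rng.standard_normal((n, L))
            best = max(brute_scores(em, crf).values())
            path = crf_decode(em, crf.transitions.data, crf.start.data,
                              crf.end.data)
            got = crf_score(em, crf.transitions.data, crf.start.data,
                            crf.end.data, path)
            assert got == pytest.approx(best, abs=1e-6)

    def test_viterbi_zero_transitions_is_per_position_argmax(self, rng):
        em = rng.standard_normal((6, 4))
        zero = np.zeros((4, 4))
        path = crf_decode(em, zero, np.zeros(4), np.zeros(4))
        assert path == list(em.argmax(axis=1))

    def test_viterbi_ties_break_low_index(self):
        em = np.zeros((3, 3))
        path = crf_decode(em, np.zeros((3, 3)), np.zeros(3), np.zeros(3))
        assert path == [0, 0, 0]

    def test_empty_sequence_rejected(self, rng):
        crf = random_crf(rng, 2)
        with pytest.raises(ValueError):
            crf_decode(np.zeros((0, 2)), crf.transitions.data,
                       crf.start.data, crf.end.data)

    def test_nll_gradient_matches_finite_differences(self, rng):
        crf = random_crf(rng, 3)
        em = rng.standard_normal((3, 3))
        gold = [0, 2, 1]
        x = Tensor(em.copy(), requires_grad=True)
        crf_nll_t(x, crf, gold).backward()
        fd = np.zeros_like(em)
        eps = 1e-5
        for i in range(3):
            for j in range(3):
                hi, lo = em.copy(), em.copy()
                hi[i, j] += eps
                lo[i, j] -= eps
                fd[i, j] = (crf_nll(hi, crf, gold)
                            - crf_nll(lo, crf, gold)) / (2 * eps)
        np.testing.assert_allclose(x.grad, fd, atol=1e-4)
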