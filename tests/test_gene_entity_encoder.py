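"""Relation attention, score normalisation and the four aggregators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slkg.attention import (AttentionParams, EnhanceParams,
                            aggregate_neighbors, enhance_entity,
                            normalize_scores, relation_attention_score,
                            top_k_mask)


def mlp_params(s, rng, zero=False):
    if zero:
        z = lambda *shape: np.zeros(shape)
        return AttentionParams(z(2 * s, s), z(s), z(s, s), z(s), z(s, 1),
                               z(1))
    return AttentionParams(rng.normal(size=(2 * s, s)), rng.normal(size=s),
                           rng.normal(size=(s, s)), rng.normal(size=s),
                           rng.normal(size=(s, 1)), rng.normal(size=1))


def naive_attention(x, r, p):
    z0 = np.maximum(np.concatenate([x, r]) @ p.W1 + p.b1, 0)
    z1 = np.maximum(z0 @ p.W2 + p.b2, 0)
    return 1.0 / (1.0 + np.exp(-(z1 @ p.W3 + p.b3)[0]))


class TestRelationAttention:
    def test_zero_network_scores_half(self, rng):
        p = mlp_params(4, rng, zero=True)
        out = relation_attention_score(rng.normal(size=4),
                                       rng.normal(size=4), p)
        assert out == pytest.approx(0.5)

    def test_score_in_open_unit_interval(self, rng):
        p = mlp_params(4, rng)
        for _ in range(20):
            s = relation_attention_score(rng.normal(size=4) * 10,
                                         rng.normal(size=4) * 10, p)
            assert 0.0 < s < 1.0

    def test_matches_layerwise_oracle(self, rng):
        p = mlp_params(4, rng)
        x, r = rng.normal(size=4), rng.normal(size=4)
        assert relation_attention_score(x, r, p) == pytest.approx(
            naive_attention(x, r, p), abs=1e-6)

    def test_gene_specific(self, rng):
        p = mlp_params(4, rng)
        r = rng.normal(size=4)
        s1 = relation_attention_score(rng.normal(size=4), r, p)
        s2 = relation_attention_score(rng.normal(size=4), r, p)
        assert s1 != s2


class TestNormalizeScores:
    def test_equal_scores_uniform(self):
        assert np.allclose(normalize_scores(np.zeros(3)), 1 / 3)

    def test_singleton(self):
        assert np.allclose(normalize_scores(np.array([3.7])), [1.0])

    def test_ln2_example(self):
        out = normalize_scores(np.array([np.log(2.0), 0.0]))
        assert np.allclose(out, [2 / 3, 1 / 3])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([0.0, np.nan]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores(np.array([]))


class TestAggregateNeighbors:
    def test_uniform_weights_identical_vectors(self, rng):
        v = rng.normal(size=4)
        out = aggregate_neighbors(np.full(5, 0.2), np.tile(v, (5, 1)))
        assert np.allclose(out, v)

    def test_vertex_weight(self, rng):
        nbrs = rng.normal(size=(4, 3))
        out = aggregate_neighbors(np.array([0, 1.0, 0, 0]), nbrs)
        assert np.allclose(out, nbrs[1])

    def test_matches_loop_oracle(self, rng):
        w = normalize_scores(rng.normal(size=8))
        nbrs = rng.normal(size=(8, 4))
        ref = sum(wi * ni for wi, ni in zip(w, nbrs))
        assert np.allclose(aggregate_neighbors(w, nbrs), ref, atol=1e-6)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate_neighbors(np.full(3, 1 / 3), rng.normal(size=(4, 2)))


def enh_params(s, mode, rng, k_top=None):
    din = s if mode in ("sum", "pool") else 2 * s
    return EnhanceParams(rng.normal(size=(din, s)), rng.normal(size=s),
                         mode=mode, k_top=k_top)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestEnhanceEntity:
    def test_sum_mode_zero_inputs(self):
        p = EnhanceParams(np.eye(4), np.zeros(4), mode="sum")
        assert np.allclose(enhance_entity(np.zeros(4), np.zeros(4), p), 0.5)

    def test_pool_idempotent_on_equal_args(self, rng):
        e = rng.normal(size=4)
        p = enh_params(4, "pool", rng)
        ref = sigmoid(e @ p.W_e + p.b_e)
        assert np.allclose(enhance_entity(e, e, p), ref)

    @pytest.mark.parametrize("mode", ["sum", "concat", "pool", "top_k"])
    def test_matches_loop_oracle(self, mode, rng):
        s = 4
        p = enh_params(s, mode, rng, k_top=2)
        e, m = rng.normal(size=s), rng.normal(size=s)
        if mode == "sum":
            x = e + m
        elif mode == "pool":
            x = np.maximum(e, m)
        else:
            x = np.concatenate([e, m])
        ref = sigmoid(np.array([x @ p.W_e[:, j] + p.b_e[j]
                                for j in range(s)]))
        if mode == "top_k":
            order = np.argsort(-ref, kind="stable")
            mask = np.zeros(s)
            mask[order[:2]] = 1
            ref = ref * mask
        assert np.allclose(enhance_entity(e, m, p), ref, atol=1e-6)

    def test_top_k_forced_example(self):
        vals = np.array([0.9, 0.1, 0.5, 0.3])
        assert np.allclose(vals * top_k_mask(vals, 2), [0.9, 0, 0.5, 0])

    def test_output_in_unit_interval(self, rng):
        for mode in ("sum", "concat", "pool"):
            p = enh_params(4, mode, rng)
            out = enhance_entity(rng.normal(size=4), rng.normal(size=4), p)
            assert np.all((out > 0) & (out < 1))

    def test_unknown_mode_rejected(self, rng):
        p = enh_params(4, "sum", rng)
        p.mode = "median"
        with pytest.raises(ValueError, match="aggregator"):
            enhance_entity(np.zeros(4), np.zeros(4), p)


class TestTopKMask:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                    max_size=12),
           st.integers(min_value=1, max_value=12))
    def test_matches_sort_oracle_with_index_tiebreak(self, vals, k):
        v = np.asarray(vals)
        k = min(k, len(v))
        mask = top_k_mask(v, k)
        # oracle: sort by (-value, index), keep first k
        order = sorted(range(len(v)), key=lambda i: (-v[i], i))
        expect = np.zeros(len(v))
        expect[order[:k]] = 1
        assert np.array_equal(mask, expect)
        assert mask.sum() == k
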