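"""Gene-oriented relation attention and entity enhancement.

When aggregating a KG neighborhood, each sampled neighbor is weighted by a
small MLP scoring the (conditioning gene, relation) pair, normalised by a
softmax over the neighborhood. The enhancement layer then folds a gene
embedding into an entity embedding through one of four interchangeable
aggregators: sum, concat, pool (elementwise max) and top-k (coordinate
selection of the k largest activations).

All operations accept leading batch axes and either ndarrays or autodiff
Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

AGGREGATORS = ("sum", "concat", "pool", "top_k")


@dataclass
class AttentionParams:
    """Two-hidden-layer scoring MLP: (2S,) -> H1 -> H2 -> scalar in (0,1)."""

    W1: object  # (2S, H1)
    b1: object  # (H1,)
    W2: object  # (H1, H2)
    b2: object  # (H2,)
    W3: object  # (H2, 1)
    b3: object  # (1,)


@dataclass
class EnhanceParams:
    """Aggregator weights; W_e is (S, S) for sum/pool, (2S, S) for
    concat/top_k."""

    W_e: object
    b_e: object  # (S,)
    mode: str = "sum"
    k_top: int | None = None


def _shape(x):
    return x.data.shape if ad.is_tensor(x) else np.asarray(x).shape


def _expand_last(x):
    return ad.reshape(x, tuple(_shape(x)) + (1,))


def broadcast_rows(vec, k: int):
    """Broadcast (..., S) to (..., k, S)."""
    shape = _shape(vec)
    expanded = ad.reshape(vec, tuple(shape[:-1]) + (1, shape[-1]))
    return ad.mul(expanded, np.ones((k, 1)))


def relation_attention_score(gene_embed, relation_embed,
                             params: AttentionParams):
    """sigmoid(W3 . ReLU(W2 . ReLU(W1 [x || r] + b1) + b2) + b3) in (0, 1).

    gene_embed / relation_embed: (..., S); returns (...,).
    """
    x = ad.concat([gene_embed, relation_embed], axis=-1)
    z0 = ad.relu(ad.add(ad.matmul(x, params.W1), params.b1))
    z1 = ad.relu(ad.add(ad.matmul(z0, params.W2), params.b2))
    out = ad.sigmoid(ad.add(ad.matmul(z1, params.W3), params.b3))
    return ad.reshape(out, tuple(_shape(out))[:-1])


def normalize_scores(scores, axis=-1):
    """Max-shifted softmax over a nonempty, finite score collection."""
    vals = scores.data if ad.is_tensor(scores) else np.asarray(scores, float)
    if vals.size == 0:
        raise ValueError("cannot normalise an empty score list")
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores contain NaN or infinity")
    if ad.is_tensor(scores):
        return ad.softmax(scores, axis=axis)
    return ad.softmax(vals, axis=axis)


def aggregate_neighbors(weights, neighbor_embeds, check: bool = True):
    """Convex combination sum_i w_i e_i; weights (..., K), embeds (..., K, S)."""
    w_shape, e_shape = _shape(weights), _shape(neighbor_embeds)
    if tuple(w_shape) != tuple(e_shape[:-1]):
        raise ValueError(
            f"weights {tuple(w_shape)} do not match embeddings "
            f"{tuple(e_shape)}")
    if check:
        vals = weights.data if ad.is_tensor(weights) else np.asarray(weights)
        if not np.allclose(vals.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("attention weights must sum to 1")
    return ad.sum_(ad.mul(_expand_last(weights), neighbor_embeds), axis=-2)


def top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """0/1 mask keeping the k largest entries along the last axis, positions
    preserved; ties broken in favour of the lower index (stable sort)."""
    order = np.argsort(-values, axis=-1, kind="stable")
    mask = np.zeros_like(values)
    np.put_along_axis(mask, order[..., :k], 1.0, axis=-1)
    return mask


def enhance_entity(entity_embed, gene_embed, params: EnhanceParams):
    """Gene-conditioned entity transformation, one of four aggregators.

    sum:    sigmoid(W_e (e + m) + b_e)
    concat: sigmoid(W_e [e || m] + b_e)
    pool:   sigmoid(W_e max(e, m) + b_e)         (elementwise max)
    top_k:  the concat output with all but the k_top largest coordinates
            zeroed (positions preserved)
    """
    mode = params.mode
    if mode == "sum":
        x = ad.add(entity_embed, gene_embed)
    elif mode == "pool":
        x = ad.maximum(entity_embed, gene_embed)
    elif mode in ("concat", "top_k"):
        x = ad.concat([entity_embed, gene_embed], axis=-1)
    else:
        raise ValueError(f"unknown aggregator mode {mode!r}; "
                         f"expected one of {AGGREGATORS}")
    y = ad.sigmoid(ad.add(ad.matmul(x, params.W_e), params.b_e))
    if mode != "top_k":
        return y
    s = _shape(y)[-1]
    k = params.k_top if params.k_top is not None else s
    if not (1 <= k <= s):
        raise ValueError(f"k_top must be in [1, {s}], got {k}")
    vals = y.data if ad.is_tensor(y) else y
    return ad.mul(y, top_k_mask(vals, k))
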