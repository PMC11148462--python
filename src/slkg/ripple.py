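"""Ripple-propagation gene encoder.

A gene's embedding is assembled from its ripple sets: a hop-0 response that
attends over the seed heads (its known SL partners), hop-p responses that
weight each sampled triple's tail by the compatibility of the conditioning
gene with the triple's head under its relation matrix, and an affine fusion
of all hop responses into a single vector.

All operations accept arbitrary leading batch axes and work on either plain
ndarrays or autodiff Tensors (see :mod:`slkg._autodiff`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad


@dataclass
class RippleParams:
    """Parameters of the ripple encoder.

    w_a scores seed heads against the conditioning gene as one linear
    functional on the concatenation [head || cond] (length 2S). w_o / b_o
    map the concatenated (l_p + 1) hop responses affinely back to S.
    """

    w_a: object  # (2S,)
    w_o: object  # ((l_p + 1) * S, S)
    b_o: object  # (S,)


def _expand_last(x):
    """Append a trailing singleton axis (works for Tensor and ndarray)."""
    shape = x.shape if not ad.is_tensor(x) else x.data.shape
    return ad.reshape(x, tuple(shape) + (1,))


def _cond_rows(cond, k: int):
    """Broadcast a (..., S) conditioning vector to (..., k, S)."""
    shape = cond.shape if not ad.is_tensor(cond) else cond.data.shape
    s = shape[-1]
    expanded = ad.reshape(cond, tuple(shape[:-1]) + (1, s))
    return ad.mul(expanded, np.ones((k, 1)))


def hop0_response(seed_head_embeds, candidate_embed, params: RippleParams,
                  return_weights: bool = False):
    """Attention-weighted sum of seed-head embeddings.

    seed_head_embeds: (..., K, S); candidate_embed: (..., S).
    Scores are w_a . [h_i || n], softmax-normalised over the K heads.
    """
    shape = (seed_head_embeds.shape if not ad.is_tensor(seed_head_embeds)
             else seed_head_embeds.data.shape)
    k, s = shape[-2], shape[-1]
    if k == 0:
        raise ValueError("hop0_response requires at least one seed head")
    wa_h = ad.take(params.w_a, np.arange(s))
    wa_n = ad.take(params.w_a, np.arange(s, 2 * s))
    scores = ad.add(ad.matmul(seed_head_embeds, wa_h),          # (..., K)
                    _expand_last(ad.matmul(candidate_embed, wa_n)))
    a = ad.softmax(scores, axis=-1)
    out = ad.sum_(ad.mul(_expand_last(a), seed_head_embeds), axis=-2)
    return (out, a) if return_weights else out


def hop_response(head_embeds, relation_mats, tail_embeds, candidate_embed,
                 return_weights: bool = False):
    """Weighted-tail response of one ripple hop.

    head_embeds / tail_embeds: (..., K, S); relation_mats: (..., K, S, S)
    for full relation matrices or (..., K, S) for the diagonal variant;
    candidate_embed: (..., S). Weights are softmax_i(n^T R_i h_i).
    """
    hshape = (head_embeds.shape if not ad.is_tensor(head_embeds)
              else head_embeds.data.shape)
    s = hshape[-1]
    rshape = (relation_mats.shape if not ad.is_tensor(relation_mats)
              else relation_mats.data.shape)
    if len(rshape) == len(hshape) + 1:  # full S x S matrices
        rh = ad.reshape(
            ad.matmul(relation_mats,
                      ad.reshape(head_embeds, tuple(hshape) + (1,))),
            tuple(hshape))
    else:  # diagonal relation matrices stored as vectors
        rh = ad.mul(relation_mats, head_embeds)
    cond = ad.reshape(candidate_embed,
                      tuple(hshape[:-2]) + (1, s))
    scores = ad.sum_(ad.mul(cond, rh), axis=-1)  # (..., K)
    k = ad.softmax(scores, axis=-1)
    out = ad.sum_(ad.mul(_expand_last(k), tail_embeds), axis=-2)
    return (out, k) if return_weights else out


def fuse_responses(responses: list, params: RippleParams):
    """Affine fusion of hop responses: concat(o^0..o^{l_p}) @ w_o + b_o."""
    x = ad.concat(list(responses), axis=-1)
    xshape = x.shape if not ad.is_tensor(x) else x.data.shape
    wshape = (params.w_o.shape if not ad.is_tensor(params.w_o)
              else params.w_o.data.shape)
    if xshape[-1] != wshape[0]:
        raise ValueError(
            f"fusion input width {xshape[-1]} does not match w_o rows "
            f"{wshape[0]}")
    return ad.add(ad.matmul(x, params.w_o), params.b_o)
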