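"""Discrepancy contrastive layer and final attention aggregator.

The contrastive stage refines an entity embedding by mixing neighborhood
information along two axes: *depth* (repeated aggregation of the embedding
with its neighborhood summary) and *width* (a learned linear mix of the
depth-wise embeddings that seeds the next width layer). The representations
collected across width layers are then fused by an attention aggregator
into the final gene embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .attention import EnhanceParams, enhance_entity, _shape, _expand_last


@dataclass
class ContrastParams:
    """depth >= 1 aggregation steps per width layer; width >= 1 layers.

    ``mix`` holds one (depth*S, S) mixing matrix per width layer;
    ``depth_agg`` is the aggregator used for the depth step (top_k by
    default, matching the strongest model variant).
    """

    mix: list  # width matrices, each (depth * S, S)
    depth_agg: EnhanceParams
    depth: int = 2
    width: int = 3


@dataclass
class FusionParams:
    w6: object        # (S,)
    W6: object        # (S, S)
    W7: object        # (S, S)
    b4: object        # (S,)
    W_pool: object    # (S, S)
    b_pool: object    # (S,)
    condition_on_pool: bool = False


def depth_mix(entity_embed, neighborhood_embed, params: EnhanceParams):
    """One depth step: aggregate the current embedding with its neighborhood
    summary using the configured aggregator (shared with the enhancement
    layer)."""
    return enhance_entity(entity_embed, neighborhood_embed, params)


def width_mix(depth_embeds: list, M_w):
    """Linear width mix: concat(e^1 .. e^d) @ M_w, no bias."""
    x = ad.concat(list(depth_embeds), axis=-1)
    xw = _shape(x)[-1]
    mw = _shape(M_w)[0]
    if xw != mw:
        raise ValueError(f"width_mix input width {xw} != M_w rows {mw}")
    return ad.matmul(x, M_w)


def attention_fuse(rep_set: list, params: FusionParams,
                   uniform: bool = False, return_weights: bool = False):
    """Fuse a representation set into one embedding.

    Per-element scores alpha_i = w6 . tanh(W6 rep_i) are softmax-normalised
    and the convex combination is passed through sigmoid(W7 . + b4). A
    max-pooled summary of the set optionally conditions the scores
    (``condition_on_pool``). ``uniform=True`` replaces the softmax with
    uniform weights (the no-attention-fusion ablation).
    """
    if not rep_set:
        raise ValueError("rep_set must be nonempty")
    st = ad.stack(list(rep_set), axis=-2)  # (..., L, S)
    sshape = _shape(st)
    n_rep = sshape[-2]
    alpha_t = None
    if uniform:
        fused = ad.mean_(st, axis=-2)
    else:
        scored = st
        if params.condition_on_pool:
            pooled = ad.sigmoid(ad.add(
                ad.matmul(ad.amax(st, axis=-2), params.W_pool),
                params.b_pool))
            pooled_rows = ad.mul(
                ad.reshape(pooled, tuple(sshape[:-2]) + (1, sshape[-1])),
                np.ones((n_rep, 1)))
            scored = ad.add(st, pooled_rows)
        alpha = ad.matmul(ad.tanh(ad.matmul(scored, params.W6)), params.w6)
        alpha_t = ad.softmax(alpha, axis=-1)  # (..., L)
        fused = ad.sum_(ad.mul(_expand_last(alpha_t), st), axis=-2)
    out = ad.sigmoid(ad.add(ad.matmul(fused, params.W7), params.b4))
    return (out, alpha_t) if return_weights else out


def contrast_stack(entity_embed, neighborhood_embed, params: ContrastParams):
    """Run the full discrepancy-contrastive stage.

    Returns the representation set: the input embedding followed by one
    output per width layer. Within a width layer, depth embeddings are
    generated by repeated ``depth_mix`` against the neighborhood summary,
    then combined by that layer's width matrix to seed the next layer.
    """
    reps = [entity_embed]
    x = entity_embed
    for w in range(params.width):
        depth_embeds = [x]
        for _ in range(params.depth - 1):
            depth_embeds.append(
                depth_mix(depth_embeds[-1], neighborhood_embed,
                          params.depth_agg))
        x = width_mix(depth_embeds, params.mix[w])
        reps.append(x)
    return reps
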