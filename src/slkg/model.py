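"""Pair-scoring model: configuration, parameters, loss and training loop.

The model scores an unordered gene pair (m, n) by encoding each gene through
two coupled views and taking a symmetrised inner product:

* a *ripple view*: attention-weighted propagation over the gene's ripple
  sets, conditioned on the partner gene's embedding-table row;
* an *entity view*: the gene's table embedding enhanced by its own ripple
  view, refined by the discrepancy-contrastive stage against an
  attention-aggregated KG neighborhood summary, and fused by the attention
  aggregator.

The predicted probability is sigmoid(0.5 * (rip_m . ent_n + rip_n . ent_m)),
which is invariant to pair orientation. The training objective is
cross-entropy over observed positives plus per-gene uniformly resampled
negatives, an L2 penalty on all weights, and a label-smoothness penalty that
asks the gene-conditioned attention weights to propagate held-out SL labels
correctly over the local KG neighborhood.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import _autodiff as ad
from .attention import (AttentionParams, EnhanceParams, aggregate_neighbors,
                        broadcast_rows, enhance_entity, normalize_scores,
                        relation_attention_score)
from .contrast import ContrastParams, FusionParams, attention_fuse, contrast_stack
from .kg import KnowledgeGraph, SLPairSet, DataSplit
from .metrics import Metrics, compute_metrics
from .neighborhood import build_seed_index, ripple_sets, sample_neighbors, SeedSet
from .ripple import RippleParams, fuse_responses, hop0_response, hop_response

logger = logging.getLogger(__name__)

VARIANTS = (None, "full", "no_ripple", "no_enhance", "no_attention_fuse",
            "drop_relation_types")


@dataclass
class ModelConfig:
    """Hyperparameters. Defaults follow the reference configuration for the
    full-scale KG (dim 128, batch 512, lr 6e-5, Adam, two ripple hops,
    contrast depth 2 / width 3, L2 and label-smoothness weights 1e-8,
    8 sampled neighbors and ripple-set size 8, early stopping patience 5)."""

    dim: int = 128
    batch_size: int = 512
    learning_rate: float = 6e-5
    p_hop: int = 2
    depth: int = 2
    width: int = 3
    l2_weight: float = 1e-8
    ls_weight: float = 1e-8
    optimizer: str = "adam"
    n_samples: int = 8
    ripple_set_size: int = 8
    aggregator: str = "top_k"
    k_top: int | None = None          # defaults to dim // 2
    epochs: int = 20
    early_stop_patience: int = 5
    seed: int = 0
    # architecture switches
    embedding_init: str = "spectral"  # "spectral" (KG-adjacency) or "random"
    relation_matrix: str = "full"     # "full" S x S, or "diag"
    attn_condition: str = "m"         # "m" | "n" | "m_and_n"
    hidden1: int | None = None        # attention MLP sizes, default dim
    hidden2: int | None = None
    fuse_condition_on_pool: bool = False
    # data handling
    inverse_edges: bool = True
    mask_test_edges: bool = True
    resample_per_epoch: bool = True
    orient_augment: bool = False      # immaterial: the score is symmetric
    seed_include_self: bool = False   # add the gene itself to its seed set
    eval_samples: int = 4             # table draws averaged at inference
    ls_max_genes: int = 4
    ls_max_partners: int = 16
    drop_relations: tuple = ()

    def __post_init__(self):
        for name in ("dim", "batch_size", "p_hop", "depth", "width",
                     "n_samples", "ripple_set_size", "epochs",
                     "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.aggregator not in ("sum", "concat", "pool", "top_k"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")

    @property
    def k_top_eff(self) -> int:
        return self.k_top if self.k_top is not None else max(1, self.dim // 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop_relations"] = list(d["drop_relations"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "drop_relations" in d:
            d["drop_relations"] = tuple(d["drop_relations"])
        return cls(**d)


def predict_pair(m_embed, n_embed):
    """sigmoid(m . n) — the inner-product pair score."""
    return ad.sigmoid(ad.sum_(ad.mul(m_embed, n_embed), axis=-1))


# ---------------------------------------------------------------------------
# Parameters


def spectral_embedding_init(kg: KnowledgeGraph, dim: int,
                            rng: np.random.Generator,
                            row_norm: float = 1.0) -> np.ndarray:
    """Structure-aware entity embedding initialisation.

    Rows are the top-``dim`` eigenvectors of the symmetrised (untyped) KG
    adjacency, scaled by |eigenvalue|, so that inner products between entity
    rows approximate the spectral truncation of the two-step path count —
    the shared-neighbor structure. Rows are rescaled to an RMS norm of
    ``row_norm`` and isolated entities fall back to random rows.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spl

    n = kg.n_entities
    h, t = kg.triples[:, 0], kg.triples[:, 2]
    ones = np.ones(len(h))
    a = sp.coo_matrix((ones, (h, t)), shape=(n, n))
    a = ((a + a.T) > 0).astype(np.float64).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    k = min(dim, n - 2)
    v0 = rng.normal(size=n)  # deterministic start vector
    vals, vecs = spl.eigsh(a, k=k, v0=v0)
    emb = vecs * np.abs(vals)
    if k < dim:
        emb = np.hstack([emb, np.zeros((n, dim - k))])
    norms = np.linalg.norm(emb, axis=1)
    live = norms > 1e-8
    scale = row_norm / max(np.sqrt(np.mean(norms[live] ** 2)), 1e-12)
    emb = emb * scale
    fallback = rng.normal(0.0, row_norm / np.sqrt(dim), size=(n, dim))
    emb[~live] = fallback[~live]
    return emb


def _eye_blocks(n_blocks: int, s: int, rng: np.random.Generator,
                noise: float = 0.05) -> np.ndarray:
    """(n_blocks * s, s) vertical stack of identity blocks / n_blocks plus
    small noise — an identity-biased linear map for concatenated inputs."""
    m = np.vstack([np.eye(s)] * n_blocks) / n_blocks
    return m + rng.normal(0.0, noise / np.sqrt(s), size=m.shape)


def init_params(kg: KnowledgeGraph, config: ModelConfig,
                rng: np.random.Generator) -> dict:
    """Initial trainable tensors for every model stage.

    The entity table optionally starts from the spectral KG embedding, and
    the mixing / readout maps are identity-biased so the embedding-space
    geometry is visible in the score from the first step (attention MLPs
    stay near-uniform at initialisation); training then refines all of them.
    """
    s = config.dim
    h1 = config.hidden1 or s
    h2 = config.hidden2 or s
    enh_blocks = 1 if config.aggregator in ("sum", "pool") else 2
    emb_scale = 1.0 / np.sqrt(s)  # per-row scale for embedding tables
    if config.embedding_init == "spectral":
        ent0 = ad.parameter(spectral_embedding_init(kg, s, rng))
    else:
        ent0 = ad.parameter((kg.n_entities, s), rng, scale=emb_scale)
    p = {
        "ent_emb": ent0,
        "rel_emb": ad.parameter((kg.n_relations, s), rng, scale=emb_scale),
        "w_a": ad.parameter((2 * s,), rng),
        "w_o": ad.parameter(_eye_blocks(config.p_hop + 1, s, rng)),
        "b_o": ad.parameter(np.zeros(s)),
        "attn_W1": ad.parameter((2 * s, h1), rng),
        "attn_b1": ad.parameter(np.zeros(h1)),
        "attn_W2": ad.parameter((h1, h2), rng),
        "attn_b2": ad.parameter(np.zeros(h2)),
        "attn_W3": ad.parameter((h2, 1), rng),
        "attn_b3": ad.parameter(np.zeros(1)),
        "enh_W": ad.parameter(_eye_blocks(enh_blocks, s, rng)),
        "enh_b": ad.parameter(np.zeros(s)),
        "dep_W": ad.parameter(_eye_blocks(2, s, rng)),  # depth agg: top_k
        "dep_b": ad.parameter(np.zeros(s)),
        "fus_w6": ad.parameter((s,), rng),
        "fus_W6": ad.parameter((s, s), rng),
        "fus_W7": ad.parameter(_eye_blocks(1, s, rng)),
        "fus_b4": ad.parameter(np.zeros(s)),
        "fus_Wp": ad.parameter(_eye_blocks(1, s, rng)),
        "fus_bp": ad.parameter(np.zeros(s)),
    }
    # linear weights of the three scoring perspectives (table, ripple
    # view, entity view); the table perspective opens dominant, the
    # encoder views fade in as training shapes them
    p["view_gates"] = ad.parameter(np.array([1.0, 0.1, 0.1]))
    if config.relation_matrix == "diag":
        p["rel_mat"] = ad.parameter(
            np.ones((kg.n_relations, s))
            + rng.normal(0, 0.05, (kg.n_relations, s)))
    else:
        eye = np.broadcast_to(np.eye(s), (kg.n_relations, s, s)).copy()
        p["rel_mat"] = ad.parameter(
            eye + rng.normal(0, 0.05 / np.sqrt(s),
                             (kg.n_relations, s, s)))
    return p


def _views(params: dict, config: ModelConfig):
    """Wrap the flat parameter dict into the per-stage parameter objects."""
    rp = RippleParams(w_a=params["w_a"], w_o=params["w_o"], b_o=params["b_o"])
    ap = AttentionParams(params["attn_W1"], params["attn_b1"],
                         params["attn_W2"], params["attn_b2"],
                         params["attn_W3"], params["attn_b3"])
    ep = EnhanceParams(params["enh_W"], params["enh_b"],
                       mode=config.aggregator, k_top=config.k_top_eff)
    dp = EnhanceParams(params["dep_W"], params["dep_b"],
                       mode="top_k", k_top=config.k_top_eff)
    cp = ContrastParams(
        mix=[params[f"mix_{i}"] for i in range(config.width)],
        depth_agg=dp, depth=config.depth, width=config.width)
    fp = FusionParams(params["fus_w6"], params["fus_W6"], params["fus_W7"],
                      params["fus_b4"], params["fus_Wp"], params["fus_bp"],
                      condition_on_pool=config.fuse_condition_on_pool)
    return rp, ap, ep, cp, fp


def add_mix_params(params: dict, config: ModelConfig,
                   rng: np.random.Generator) -> None:
    s = config.dim
    for i in range(config.width):
        params[f"mix_{i}"] = ad.parameter((config.depth * s, s), rng)


# ---------------------------------------------------------------------------
# Per-epoch sample tables


@dataclass
class SampleTables:
    """Dense per-gene ripple/neighbor samples for one epoch."""

    row: dict[int, int]
    rip_heads: np.ndarray  # (G, l_p, size)
    rip_rels: np.ndarray
    rip_tails: np.ndarray
    nbr_rels: np.ndarray   # (G, k)
    nbr_ents: np.ndarray

    def rows(self, gene_ids: np.ndarray) -> np.ndarray:
        return np.fromiter((self.row[int(g)] for g in gene_ids),
                           dtype=np.int64, count=len(gene_ids))


def build_tables(kg: KnowledgeGraph, seeds: dict[int, np.ndarray],
                 gene_ids: np.ndarray, config: ModelConfig,
                 seed: int) -> SampleTables:
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    g = len(gene_ids)
    lp, sz, k = config.p_hop, config.ripple_set_size, config.n_samples
    heads = np.empty((g, lp, sz), dtype=np.int64)
    rels = np.empty((g, lp, sz), dtype=np.int64)
    tails = np.empty((g, lp, sz), dtype=np.int64)
    nr = np.empty((g, k), dtype=np.int64)
    ne = np.empty((g, k), dtype=np.int64)
    row = {}
    for i, gid in enumerate(sorted(int(x) for x in gene_ids)):
        row[gid] = i
        rs = ripple_sets(kg, SeedSet(gid, seeds[gid]), lp, sz, rng)
        for p in range(lp):
            heads[i, p] = rs.hops[p][:, 0]
            rels[i, p] = rs.hops[p][:, 1]
            tails[i, p] = rs.hops[p][:, 2]
        ns = sample_neighbors(kg, gid, k, rng)
        nr[i] = ns.neighbors[:, 0]
        ne[i] = ns.neighbors[:, 1]
    return SampleTables(row, heads, rels, tails, nr, ne)


# ---------------------------------------------------------------------------
# Forward pass


def encode_genes(params: dict, gene_ids: np.ndarray, other_ids: np.ndarray,
                 tables: SampleTables, config: ModelConfig,
                 variant: str | None = None):
    """Encode genes (conditioned on their pair partners) into the ripple view
    and the entity view. Returns (rip, ent_view), each (len(gene_ids), S)."""
    ent = params["ent_emb"]
    rp, ap, ep, cp, fp = _views(params, config)
    gi = tables.rows(gene_ids)
    cond = ad.take(ent, other_ids)
    self_emb = ad.take(ent, gene_ids)

    if variant == "no_ripple":
        rip = self_emb
    else:
        responses = [hop0_response(ad.take(ent, tables.rip_heads[gi, 0]),
                                   cond, rp)]
        for p in range(config.p_hop):
            h = ad.take(ent, tables.rip_heads[gi, p])
            r = ad.take(params["rel_mat"], tables.rip_rels[gi, p])
            t = ad.take(ent, tables.rip_tails[gi, p])
            responses.append(hop_response(h, r, t, cond))
        rip = fuse_responses(responses, rp)

    if config.attn_condition == "n":
        attn_cond = self_emb
    elif config.attn_condition == "m_and_n":
        attn_cond = ad.mul(ad.add(cond, self_emb), 0.5)
    else:
        attn_cond = cond
    rel_e = ad.take(params["rel_emb"], tables.nbr_rels[gi])
    pi = relation_attention_score(
        broadcast_rows(attn_cond, config.n_samples), rel_e, ap)
    pi_t = normalize_scores(pi)
    nbr = ad.take(ent, tables.nbr_ents[gi])
    nbr_sum = aggregate_neighbors(pi_t, nbr, check=False)

    # the enhanced entity is the relation-attention-aggregated central
    # entity, folded with the gene's ripple-view embedding
    e0 = nbr_sum if variant == "no_enhance" else enhance_entity(nbr_sum, rip, ep)
    reps = contrast_stack(e0, nbr_sum, cp)
    reps[0] = self_emb  # the representation set opens with the input embedding
    ent_view = attention_fuse(reps, fp,
                              uniform=(variant == "no_attention_fuse"))
    return rip, ent_view


def pair_logits(params: dict, pairs: np.ndarray, tables: SampleTables,
                config: ModelConfig, variant: str | None = None):
    """Multi-perspective logits for (n, 2) gene-id pairs.

    Each gene is described by three perspectives — its entity-table row, its
    ripple-view embedding and its entity-view embedding — and the pair logit
    is the gate-weighted sum of the per-perspective inner products. The
    score is therefore invariant to pair orientation, and zeroing the gate
    weights forces every prediction to exactly 1/2.
    """
    b = len(pairs)
    genes = np.concatenate([pairs[:, 0], pairs[:, 1]])
    others = np.concatenate([pairs[:, 1], pairs[:, 0]])
    rip, entv = encode_genes(params, genes, others, tables, config, variant)
    lo, hi = np.arange(b), np.arange(b, 2 * b)
    tab_m = ad.take(params["ent_emb"], pairs[:, 0])
    tab_n = ad.take(params["ent_emb"], pairs[:, 1])
    gates = params["view_gates"]
    g0 = ad.take(gates, np.array([0]))
    g1 = ad.take(gates, np.array([1]))
    g2 = ad.take(gates, np.array([2]))
    z = ad.mul(g0, ad.sum_(ad.mul(tab_m, tab_n), axis=-1))
    z = ad.add(z, ad.mul(g1, ad.sum_(
        ad.mul(ad.take(rip, lo), ad.take(rip, hi)), axis=-1)))
    z = ad.add(z, ad.mul(g2, ad.sum_(
        ad.mul(ad.take(entv, lo), ad.take(entv, hi)), axis=-1)))
    return z


def score_pairs(params: dict, pairs: np.ndarray, tables: SampleTables,
                config: ModelConfig, variant: str | None = None) -> np.ndarray:
    """Probability scores on the fast (ndarray) path."""
    flat = {k: (v.data if ad.is_tensor(v) else v) for k, v in params.items()}
    return ad.sigmoid(pair_logits(flat, np.asarray(pairs), tables, config,
                                  variant))


# ---------------------------------------------------------------------------
# Label smoothness


def propagate_labels_loo(weights, labeled_idx, labels, n_iters: int):
    """Leave-one-out clamped label propagation.

    ``weights`` is an (n, n) nonnegative edge-weight matrix (Tensor or
    ndarray); rows are normalised internally. For each labeled node j, all
    *other* labeled nodes are clamped to their labels, everything else starts
    at 0.5, and labels diffuse for ``n_iters`` rounds; the estimate read off
    at j is returned. Output shape: (len(labeled_idx),).
    """
    labeled_idx = np.asarray(labeled_idx, dtype=np.int64)
    labels = np.asarray(labels, dtype=float)
    n = (weights.data if ad.is_tensor(weights) else weights).shape[0]
    nl = len(labeled_idx)
    rowsum = ad.sum_(weights, axis=-1, keepdims=True)
    p = ad.div(weights, ad.add(rowsum, 1e-12))
    mask = np.zeros((n, nl))
    clamp = np.zeros((n, nl))
    for col in range(nl):
        for jj, y in zip(labeled_idx, labels):
            if jj != labeled_idx[col]:
                mask[jj, col] = 1.0
                clamp[jj, col] = y
    state = mask * clamp + 0.5 * (1.0 - mask)
    for _ in range(n_iters):
        state = ad.add(mask * clamp,
                       ad.mul(1.0 - mask, ad.matmul(p, state)))
    flat = labeled_idx * nl + np.arange(nl)
    return ad.take_flat(state, flat)


def label_smoothness(weights, labeled_idx, labels, n_iters: int):
    """Sum of binary cross-entropies between each held-out label and its
    leave-one-out propagation estimate; 0 when fewer than 2 labels exist."""
    labeled_idx = np.asarray(labeled_idx, dtype=np.int64)
    labels = np.asarray(labels, dtype=float)
    if len(labeled_idx) < 2:
        return 0.0 if not ad.is_tensor(weights) else ad.constant(0.0)
    lhat = ad.clip(propagate_labels_loo(weights, labeled_idx, labels,
                                        n_iters), 1e-6, 1.0 - 1e-6)
    ce = ad.neg(ad.add(ad.mul(labels, ad.log(lhat)),
                       ad.mul(1.0 - labels, ad.log(ad.sub(1.0, lhat)))))
    return ad.sum_(ce)


def _batch_label_smoothness(params: dict, kg: KnowledgeGraph,
                            partner_index: dict[int, list],
                            batch_genes: np.ndarray, config: ModelConfig,
                            rng: np.random.Generator):
    """Label-smoothness penalty over a few genes from the current batch.

    For each chosen gene m with >= 2 labeled train partners, a local graph is
    formed from the partners plus their sampled KG neighbors; edge weights
    come from the attention MLP conditioned on m's embedding, and the
    leave-one-out propagation of m's known labels is scored against them.
    """
    eligible = [g for g in np.unique(batch_genes)
                if len(partner_index.get(int(g), ())) >= 2]
    if not eligible:
        return ad.constant(0.0)
    chosen = rng.choice(np.asarray(eligible),
                        size=min(config.ls_max_genes, len(eligible)),
                        replace=False)
    total = ad.constant(0.0)
    for m in chosen:
        partners = partner_index[int(m)]
        if len(partners) > config.ls_max_partners:
            idx = rng.choice(len(partners), size=config.ls_max_partners,
                             replace=False)
            partners = [partners[i] for i in sorted(idx)]
        nodes = [p for p, _ in partners]
        for p, _ in partners:
            nb = kg.neighbors(p)
            if len(nb):
                take = rng.integers(0, len(nb), size=min(config.n_samples,
                                                         len(nb)))
                nodes.extend(int(t) for t in nb[take, 1])
        node_ids = list(dict.fromkeys(nodes))  # order-stable dedup
        pos_of = {nid: i for i, nid in enumerate(node_ids)}
        n = len(node_ids)
        src, dst, rel = [], [], []
        for nid in node_ids:
            for r, t in kg.neighbors(nid):
                if int(t) in pos_of:
                    src.append(pos_of[nid])
                    dst.append(pos_of[int(t)])
                    rel.append(int(r))
        if not src:
            continue
        cond = ad.take(params["ent_emb"], np.array([int(m)]))
        cond_rows = ad.mul(cond, np.ones((len(src), 1)))
        rel_e = ad.take(params["rel_emb"], np.asarray(rel))
        _, apv, *_ = _views(params, config)
        w = relation_attention_score(cond_rows, rel_e, apv)
        wmat = ad.put(w, np.asarray(src) * n + np.asarray(dst), (n, n))
        lab_idx = [pos_of[p] for p, _ in partners]
        lab = [y for _, y in partners]
        total = ad.add(total, label_smoothness(wmat, lab_idx, lab,
                                               config.p_hop))
    return total


# ---------------------------------------------------------------------------
# Loss


def sample_loss_negatives(pos_pairs: np.ndarray, gene_universe: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """One uniformly drawn negative partner per positive pair (so each gene m
    receives as many sampled negatives as it has positives in the batch)."""
    m = pos_pairs[:, 0]
    n_genes = len(gene_universe)
    partner = gene_universe[rng.integers(0, n_genes, size=len(pos_pairs))]
    clash = partner == m
    while np.any(clash):
        partner[clash] = gene_universe[
            rng.integers(0, n_genes, size=int(clash.sum()))]
        clash = partner == m
    return np.column_stack([m, partner])


def total_loss(params: dict, pos_pairs: np.ndarray, neg_pairs: np.ndarray,
               tables: SampleTables, config: ModelConfig,
               kg: KnowledgeGraph | None = None,
               partner_index: dict | None = None,
               rng: np.random.Generator | None = None,
               variant: str | None = None):
    """Cross-entropy (summed over positives and sampled negatives) plus
    gamma * ||Theta||^2 plus lambda * label-smoothness.

    Returns (total Tensor, components dict of floats).
    """
    pairs = np.vstack([pos_pairs, neg_pairs])
    y = np.concatenate([np.ones(len(pos_pairs)), np.zeros(len(neg_pairs))])
    if config.orient_augment:
        pairs = np.vstack([pairs, pairs[:, ::-1]])
        y = np.concatenate([y, y])
    z = pair_logits(params, pairs, tables, config, variant)
    # stable BCE from logits: softplus(z) - y z
    ce = ad.sum_(ad.sub(ad.softplus(z), ad.mul(y, z)))
    total = ce
    comps = {"ce": float(ce.data if ad.is_tensor(ce) else ce),
             "n_pairs": len(pairs)}
    if config.l2_weight:
        l2 = None
        for v in params.values():
            sq = ad.sum_(ad.mul(v, v))
            l2 = sq if l2 is None else ad.add(l2, sq)
        comps["l2"] = float(l2.data if ad.is_tensor(l2) else l2)
        total = ad.add(total, ad.mul(l2, config.l2_weight))
    else:
        comps["l2"] = 0.0
    if config.ls_weight and kg is not None and partner_index is not None:
        ls = _batch_label_smoothness(params, kg, partner_index,
                                     pairs[:len(pos_pairs), 0], config,
                                     rng or np.random.default_rng(0))
        comps["ls"] = float(ls.data if ad.is_tensor(ls) else ls)
        total = ad.add(total, ad.mul(ls, config.ls_weight))
    else:
        comps["ls"] = 0.0
    tval = float(total.data if ad.is_tensor(total) else total)
    if not np.isfinite(tval):
        raise FloatingPointError(f"non-finite loss: {comps}")
    comps["total"] = tval
    return total, comps


class Adam:
    """Standard Adam over a dict of Tensors."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Model / Results


def _partner_index(train: SLPairSet,
                   cap: int | None = None) -> dict[int, list]:
    """gene -> [(partner, label), ...] over *all* labeled train pairs."""
    out: dict[int, list] = {}
    for a, b, yy in train.pairs:
        out.setdefault(int(a), []).append((int(b), int(yy)))
        out.setdefault(int(b), []).append((int(a), int(yy)))
    return out


class SLInteractionModel:
    """Knowledge-graph attention model for synthetic-lethality prediction.

    Parameters
    ----------
    split : DataSplit
        Labeled pair partition; training uses ``split.train``, early
        stopping monitors ``split.valid``.
    kg : KnowledgeGraph
        The heterogeneous knowledge graph. Inverse edges are added and
        evaluation-pair gene-gene edges masked according to the config.
    config : ModelConfig, optional
    variant : str, optional
        One of the ablation variants: "no_ripple", "no_enhance",
        "no_attention_fuse", "drop_relation_types" (which removes
        ``config.drop_relations`` from the KG), or None for the full model.
    """

    def __init__(self, split: DataSplit, kg: KnowledgeGraph,
                 config: ModelConfig | None = None,
                 variant: str | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.config = config or ModelConfig()
        self.variant = None if variant == "full" else variant
        self.split = split
        kg_used = kg
        if self.variant == "drop_relation_types" and self.config.drop_relations:
            kg_used = kg_used.drop_relations(list(self.config.drop_relations))
        if self.config.inverse_edges:
            kg_used = kg_used.with_inverse_edges()
        if self.config.mask_test_edges:
            held = split.valid.pair_keys() | split.test.pair_keys()
            kg_used = kg_used.drop_triples_between(held)
        self.kg = kg_used
        self.gene_universe = split.train.gene_universe
        self.seeds = build_seed_index(split.train, self.gene_universe,
                                      include_self=self.config.seed_include_self)
        self.partner_index = _partner_index(split.train)

    @classmethod
    def from_tables(cls, triples_path, pairs_path,
                    config: ModelConfig | None = None, seed: int = 0,
                    ratios=(0.7, 0.1, 0.2), **kwargs):
        """Build a model straight from triples/pairs TSV files using a
        random split and balanced negative sampling."""
        from .kg import load_triples, load_sl_pairs, sample_negatives, split_random
        kg = load_triples(triples_path)
        pos = load_sl_pairs(pairs_path, kg)
        if np.all(pos.pairs[:, 2] == 1):
            neg = sample_negatives(pos, seed)
            pos = SLPairSet(np.vstack([pos.pairs, neg.pairs]),
                            pos.gene_universe, pos.n_dropped)
        split = split_random(pos, ratios, seed)
        return cls(split, kg, config, **kwargs)

    # -- training ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "SLInteractionResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
        params = init_params(self.kg, cfg, rng)
        add_mix_params(params, cfg, rng)
        opt = Adam(params, cfg.learning_rate)
        # training sees every labeled pair (positives and dataset-level
        # negatives); each batch additionally draws one uniform negative per
        # positive, so each gene m receives N^m resampled negatives
        train_pairs = self.split.train.pairs
        if len(self.split.train.positives) == 0:
            raise ValueError("training split has no positive pairs")
        log: list[dict] = []
        best = {"auc": -np.inf, "epoch": -1, "params": None}
        stale = 0
        tables = None
        for epoch in range(cfg.epochs):
            if tables is None or cfg.resample_per_epoch:
                tables = build_tables(self.kg, self.seeds, self.gene_universe,
                                      cfg, seed * 1009 + epoch)
            order = rng.permutation(len(train_pairs))
            epoch_comps = []
            for lo in range(0, len(order), cfg.batch_size):
                batch = train_pairs[order[lo:lo + cfg.batch_size]]
                pos = batch[batch[:, 2] == 1, :2]
                neg_fixed = batch[batch[:, 2] == 0, :2]
                neg_sampled = (sample_loss_negatives(pos, self.gene_universe,
                                                     rng)
                               if len(pos) else np.empty((0, 2), np.int64))
                negs = np.vstack([neg_fixed, neg_sampled])
                if len(pos) == 0 or len(negs) == 0:
                    continue
                opt.zero_grad()
                loss, comps = total_loss(
                    params, pos, negs, tables, cfg, kg=self.kg,
                    partner_index=self.partner_index, rng=rng,
                    variant=self.variant)
                if cfg.learning_rate > 0:
                    loss.backward()
                    opt.step()
                epoch_comps.append(comps)
            val = self._evaluate_with(params, self.split.valid,
                                      seed * 1009 + 500_000 + epoch)
            rec = {"epoch": epoch,
                   "loss": float(np.sum([c["total"] for c in epoch_comps])),
                   "ce": float(np.sum([c["ce"] for c in epoch_comps])),
                   "l2": float(np.mean([c["l2"] for c in epoch_comps])),
                   "ls": float(np.sum([c["ls"] for c in epoch_comps])),
                   "val_auc": val.auc_roc, "val_aupr": val.aupr}
            log.append(rec)
            logger.info("epoch %d loss %.4f val AUC %.4f", epoch,
                        rec["loss"], rec["val_auc"])
            if val.auc_roc > best["auc"]:
                best = {"auc": val.auc_roc, "epoch": epoch,
                        "params": {k: v.data.copy() for k, v in params.items()}}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        final = best["params"] if best["params"] is not None else \
            {k: v.data.copy() for k, v in params.items()}
        return SLInteractionResults(self, final, log, best["epoch"], seed)

    def _evaluate_with(self, params: dict, pairs: SLPairSet,
                       seed: int) -> Metrics:
        """Score with predictions averaged over ``eval_samples`` independent
        ripple/neighbor table draws (sampling-variance reduction)."""
        arr = pairs.pairs[:, :2]
        acc = np.zeros(len(arr))
        for i in range(self.config.eval_samples):
            tables = build_tables(self.kg, self.seeds, self.gene_universe,
                                  self.config, seed + 7919 * i)
            acc += score_pairs(params, arr, tables, self.config, self.variant)
        return compute_metrics(pairs.pairs[:, 2],
                               acc / self.config.eval_samples)


class SLInteractionResults:
    """Fitted model: best-validation parameters, training log, scoring."""

    def __init__(self, model: SLInteractionModel, params: dict[str, np.ndarray],
                 training_log: list[dict], best_epoch: int, seed: int):
        self.model = model
        self.config = model.config
        self.params = params
        self.training_log = training_log
        self.best_epoch = best_epoch
        self.seed = seed
        self._eval_tables: list[SampleTables] | None = None

    def _tables_for(self, gene_ids: np.ndarray) -> list[SampleTables]:
        """Deterministic evaluation-time samples covering the given genes;
        one table set per averaged draw."""
        need = set(int(g) for g in gene_ids)
        if (self._eval_tables is None
                or not need.issubset(self._eval_tables[0].row.keys())):
            universe = set(int(g) for g in self.model.gene_universe) | need
            seeds = dict(self.model.seeds)
            for g in universe:
                seeds.setdefault(g, np.array([g], dtype=np.int64))
            self._eval_tables = [
                build_tables(self.model.kg, seeds,
                             np.array(sorted(universe)), self.config,
                             self.seed * 1009 + 999_983 + 7919 * i)
                for i in range(self.config.eval_samples)]
        return self._eval_tables

    def predict(self, pairs) -> np.ndarray:
        """Probability scores for (n, 2) gene-id pairs or an SLPairSet.

        Scores are averaged over ``config.eval_samples`` independent
        ripple/neighbor sample draws (deterministic given the fit seed)."""
        arr = pairs.pairs[:, :2] if isinstance(pairs, SLPairSet) else \
            np.asarray(pairs, dtype=np.int64)
        table_draws = self._tables_for(arr.ravel())
        out = np.zeros(len(arr))
        for tables in table_draws:
            for lo in range(0, len(arr), self.config.batch_size):
                chunk = arr[lo:lo + self.config.batch_size]
                out[lo:lo + len(chunk)] += score_pairs(
                    self.params, chunk, tables, self.config,
                    self.model.variant)
        return out / len(table_draws)

    def evaluate(self, pairs: SLPairSet) -> Metrics:
        scores = self.predict(pairs)
        return compute_metrics(pairs.pairs[:, 2], scores)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "SL interaction model — fit summary",
            "=" * 44,
            f"{'entities':<24}{self.model.kg.n_entities:>20}",
            f"{'relations':<24}{self.model.kg.n_relations:>20}",
            f"{'KG triples':<24}{self.model.kg.n_triples:>20}",
            f"{'train pairs':<24}{len(self.model.split.train):>20}",
            f"{'embedding dim':<24}{cfg.dim:>20}",
            f"{'ripple hops':<24}{cfg.p_hop:>20}",
            f"{'contrast depth/width':<24}"
            f"{f'{cfg.depth}/{cfg.width}':>20}",
            f"{'aggregator':<24}{cfg.aggregator:>20}",
            f"{'variant':<24}{str(self.model.variant or 'full'):>20}",
            f"{'epochs run':<24}{len(self.training_log):>20}",
            f"{'best epoch':<24}{self.best_epoch:>20}",
        ]
        if self.training_log:
            last = self.training_log[-1]
            best = max(r["val_auc"] for r in self.training_log)
            lines += [
                f"{'final train loss':<24}{last['loss']:>20.4f}",
                f"{'best valid AUC':<24}{best:>20.4f}",
            ]
        lines.append("=" * 44)
        return "\n".join(lines)

    def save(self, path) -> None:
        """Portable named-array checkpoint (.npz)."""
        meta = json.dumps({"config": self.config.to_dict(),
                           "variant": self.model.variant,
                           "best_epoch": self.best_epoch,
                           "seed": self.seed,
                           "training_log": self.training_log})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path, split: DataSplit, kg: KnowledgeGraph
             ) -> "SLInteractionResults":
        with np.load(path) as zf:
            meta = json.loads(bytes(zf["__meta__"]).decode())
            params = {k: zf[k] for k in zf.files if k != "__meta__"}
        cfg = ModelConfig.from_dict(meta["config"])
        model = SLInteractionModel(split, kg, cfg, meta["variant"])
        res = cls(model, params, meta["training_log"], meta["best_epoch"],
                  meta["seed"])
        return res
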