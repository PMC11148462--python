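"""Hierarchy propagation over the knowledge graph.

For a gene, the hop-0 "seed set" is its known SL partners in the training
data (falling back to the gene itself when it has none — the cold-start
case). Hop-p extended entity sets follow head-to-tail edges recursively, and
per-hop fixed-size "ripple sets" of triples are sampled with replacement from
each frontier. Entities also get fixed-size uniformly sampled neighbor lists
so that batches have constant shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg import KnowledgeGraph, SLPairSet


@dataclass
class SeedSet:
    gene_id: int
    seeds: np.ndarray  # entity ids; never empty


@dataclass
class RippleSets:
    """Per-gene, per-hop fixed-size triple samples.

    ``hops[p]`` is a (size, 3) int array of (head, relation, tail) triples at
    hop p+1; heads at hop p are drawn from the frontier reached at hop p-1.
    """

    gene_id: int
    hops: list[np.ndarray]

    @property
    def l_p(self) -> int:
        return len(self.hops)

    @property
    def size(self) -> int:
        return len(self.hops[0])


@dataclass
class NeighborSample:
    entity_id: int
    neighbors: np.ndarray  # (k, 2) of (relation_id, neighbor_entity_id)


def seed_set(gene_id: int, train_positives: SLPairSet) -> SeedSet:
    """The gene's positive SL partners in training; itself if it has none."""
    p = train_positives.pairs
    pos = p[p[:, 2] == 1]
    partners = np.concatenate([pos[pos[:, 0] == gene_id, 1],
                               pos[pos[:, 1] == gene_id, 0]])
    partners = np.unique(partners)
    if len(partners) == 0:
        partners = np.array([gene_id], dtype=np.int64)
    return SeedSet(int(gene_id), partners.astype(np.int64))


def build_seed_index(train_positives: SLPairSet, gene_ids: np.ndarray,
                     include_self: bool = False) -> dict[int, np.ndarray]:
    """Vectorised seed sets for many genes at once.

    ``include_self`` adds the gene itself to its seed set, so the gene's own
    KG edges also feed hop-1 propagation (besides its partners').
    """
    pos = train_positives.positives
    partner_map: dict[int, list[int]] = {int(g): [] for g in gene_ids}
    for a, b, _ in pos:
        if int(a) in partner_map:
            partner_map[int(a)].append(int(b))
        if int(b) in partner_map:
            partner_map[int(b)].append(int(a))
    out = {}
    for g, ps in partner_map.items():
        if include_self:
            ps = ps + [g]
        arr = np.unique(np.asarray(ps, dtype=np.int64)) if ps else \
            np.array([g], dtype=np.int64)
        out[g] = arr
    return out


def extended_entity_sets(kg: KnowledgeGraph, seed: SeedSet,
                         l_p: int) -> list[np.ndarray]:
    """Hop frontiers: eps^p = tails of triples whose head lies in eps^{p-1},
    with eps^0 the seed set. Frontiers may repeat entities across hops."""
    if l_p < 1:
        raise ValueError("l_p must be >= 1")
    sets = []
    frontier = seed.seeds
    for _ in range(l_p):
        tails = [kg.neighbors(h)[:, 1] for h in frontier]
        frontier = (np.unique(np.concatenate(tails))
                    if tails and sum(len(t) for t in tails)
                    else np.empty(0, dtype=np.int64))
        sets.append(frontier)
    return sets


def _frontier_triples(kg: KnowledgeGraph, frontier: np.ndarray) -> np.ndarray:
    """(n, 3) candidate triples whose head is in the frontier."""
    chunks = []
    for h in frontier:
        nb = kg.neighbors(h)
        if len(nb):
            chunks.append(np.column_stack([
                np.full(len(nb), h, dtype=np.int64), nb[:, 0], nb[:, 1]]))
    if not chunks:
        return np.empty((0, 3), dtype=np.int64)
    return np.vstack(chunks)


def ripple_sets(kg: KnowledgeGraph, seed: SeedSet, l_p: int, size: int,
                rng: np.random.Generator) -> RippleSets:
    """Sample `size` triples per hop, with replacement, from each frontier's
    candidate triples. An empty frontier yields self-loop placeholder triples
    on the first seed (a learnable self-representation, keeping shapes fixed).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    self_rel = kg.self_relation
    hops = []
    frontier = seed.seeds
    for _ in range(l_p):
        cand = _frontier_triples(kg, frontier)
        if len(cand) == 0:
            anchor = int(seed.seeds[0])
            hop = np.tile([anchor, self_rel, anchor], (size, 1)).astype(np.int64)
            frontier = np.array([anchor], dtype=np.int64)
        else:
            idx = rng.integers(0, len(cand), size=size)
            hop = cand[idx]
            frontier = np.unique(cand[:, 2])
        hops.append(hop)
    return RippleSets(seed.gene_id, hops)


def sample_neighbors(kg: KnowledgeGraph, entity_id: int, k: int,
                     rng: np.random.Generator) -> NeighborSample:
    """Uniform with-replacement sample of k (relation, neighbor) entries from
    the entity's outgoing adjacency; isolated entities are padded with
    self-loop entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    nb = kg.neighbors(entity_id)
    if len(nb) == 0:
        out = np.tile([kg.self_relation, entity_id], (k, 1)).astype(np.int64)
    else:
        idx = rng.integers(0, len(nb), size=k)
        out = nb[idx]
    return NeighborSample(int(entity_id), out)


def sample_ripple_batch(kg: KnowledgeGraph, seeds: dict[int, np.ndarray],
                        gene_ids: np.ndarray, l_p: int, size: int,
                        rng: np.random.Generator) -> dict[int, RippleSets]:
    """Ripple sets for a collection of genes (one rng stream, order-stable)."""
    out = {}
    for g in gene_ids:
        out[int(g)] = ripple_sets(
            kg, SeedSet(int(g), seeds[int(g)]), l_p, size, rng)
    return out


def sample_neighbor_batch(kg: KnowledgeGraph, entity_ids: np.ndarray, k: int,
                          rng: np.random.Generator) -> dict[int, NeighborSample]:
    return {int(e): sample_neighbors(kg, int(e), k, rng) for e in entity_ids}
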