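"""Knowledge-graph and synthetic-lethality pair data model.

A heterogeneous knowledge graph (KG) is held as a typed triple store:
integer-coded ``(head, relation, tail)`` edges plus entity/relation
vocabularies, with a head-indexed adjacency for propagation. Labeled
synthetic-lethality (SL) gene pairs are unordered ``(gene_a, gene_b, label)``
records whose genes must be KG entities. The module also provides balanced
negative sampling, the two train/valid/test split regimes (random and
gene-holdout), and the symmetric 0/1 SL adjacency.

File formats are plain TSV: triples as ``head<TAB>relation<TAB>tail`` and
pairs as ``gene_a<TAB>gene_b<TAB>label`` with label in {0, 1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Name of the reserved self-loop relation appended to every vocabulary; used
#: to pad neighbor samples of isolated entities and empty ripple frontiers.
SELF_RELATION = "__self__"

#: Suffix marking auto-generated inverse relations.
INVERSE_SUFFIX = "__inv__"


class ParseError(ValueError):
    """Raised for malformed TSV input, carrying the offending line number."""


@dataclass
class KnowledgeGraph:
    """Typed multi-relational triple store with integer vocabularies."""

    entities: dict[str, int]
    relations: dict[str, int]
    triples: np.ndarray  # (n_triples, 3) int64 columns: head, relation, tail

    _by_head: dict[int, np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    @property
    def self_relation(self) -> int:
        return self.relations[SELF_RELATION]

    def entity_names(self) -> list[str]:
        names = [None] * len(self.entities)
        for name, i in self.entities.items():
            names[i] = name
        return names

    def relation_names(self) -> list[str]:
        names = [None] * len(self.relations)
        for name, i in self.relations.items():
            names[i] = name
        return names

    @property
    def by_head(self) -> dict[int, np.ndarray]:
        """head_id -> (deg, 2) array of (relation_id, tail_id), lazily built."""
        if self._by_head is None:
            idx = {}
            order = np.argsort(self.triples[:, 0], kind="stable")
            srt = self.triples[order]
            heads, starts = np.unique(srt[:, 0], return_index=True)
            bounds = np.append(starts, len(srt))
            for h, lo, hi in zip(heads, bounds[:-1], bounds[1:]):
                idx[int(h)] = srt[lo:hi, 1:3]
            self._by_head = idx
        return self._by_head

    def neighbors(self, entity_id: int) -> np.ndarray:
        """Outgoing (relation_id, tail_id) rows of an entity; may be empty."""
        return self.by_head.get(int(entity_id), np.empty((0, 2), dtype=np.int64))

    def with_inverse_edges(self) -> "KnowledgeGraph":
        """Add an inverse triple (t, r_inv, h) per edge with a distinct
        relation id, so that propagation can traverse edges both ways."""
        relations = dict(self.relations)
        inv_ids = np.empty(len(self.relations), dtype=np.int64)
        for name, rid in list(self.relations.items()):
            if name == SELF_RELATION:
                inv_ids[rid] = rid
                continue
            inv_name = name + INVERSE_SUFFIX
            relations[inv_name] = len(relations)
            inv_ids[rid] = relations[inv_name]
        inv = np.column_stack([
            self.triples[:, 2], inv_ids[self.triples[:, 1]], self.triples[:, 0]])
        return KnowledgeGraph(dict(self.entities), relations,
                              np.vstack([self.triples, inv]))

    def drop_relations(self, relation_names: list[str]) -> "KnowledgeGraph":
        """Remove all triples using the named relations (vocab unchanged)."""
        ids = {self.relations[n] for n in relation_names if n in self.relations}
        if not ids:
            return KnowledgeGraph(dict(self.entities), dict(self.relations),
                                  self.triples.copy())
        keep = ~np.isin(self.triples[:, 1], list(ids))
        return KnowledgeGraph(dict(self.entities), dict(self.relations),
                              self.triples[keep])

    def drop_triples_between(self, pairs: set[tuple[int, int]]) -> "KnowledgeGraph":
        """Remove triples whose (head, tail) matches any given unordered pair;
        used to mask evaluation SL edges from propagation."""
        if not pairs:
            return self
        canon = {(min(a, b), max(a, b)) for a, b in pairs}
        h = np.minimum(self.triples[:, 0], self.triples[:, 2])
        t = np.maximum(self.triples[:, 0], self.triples[:, 2])
        key = h.astype(np.int64) * (self.n_entities + 1) + t
        bad = np.fromiter(
            (a * (self.n_entities + 1) + b for a, b in canon),
            dtype=np.int64, count=len(canon))
        keep = ~np.isin(key, bad)
        return KnowledgeGraph(dict(self.entities), dict(self.relations),
                              self.triples[keep])


@dataclass
class SLPairSet:
    """Unordered labeled gene pairs over KG gene entities."""

    pairs: np.ndarray  # (n, 3) int64 columns: gene_a, gene_b, label
    gene_universe: np.ndarray  # sorted ids of genes eligible for pairing
    n_dropped: int = 0  # pairs removed because a gene was absent from the KG

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def positives(self) -> np.ndarray:
        return self.pairs[self.pairs[:, 2] == 1]

    @property
    def negatives(self) -> np.ndarray:
        return self.pairs[self.pairs[:, 2] == 0]

    def genes(self) -> set[int]:
        if len(self.pairs) == 0:
            return set()
        return set(self.pairs[:, 0]) | set(self.pairs[:, 1])

    def pair_keys(self) -> set[tuple[int, int]]:
        return {(min(a, b), max(a, b)) for a, b, _ in self.pairs}

    def subset(self, index: np.ndarray) -> "SLPairSet":
        return SLPairSet(self.pairs[index], self.gene_universe, 0)


@dataclass
class DataSplit:
    """Disjoint train/valid/test partition of an :class:`SLPairSet`."""

    train: SLPairSet
    valid: SLPairSet
    test: SLPairSet
    mode: str  # "random" | "leave_out_genes"
    seed: int
    n_dropped: int = 0  # leave-out mode: pairs removed to keep genes disjoint


# ---------------------------------------------------------------------------
# I/O


def _read_tsv(path, n_cols: int) -> list[tuple]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"fields, got {len(fields)}")
            rows.append(tuple(fields))
    if not rows:
        raise ParseError(f"{path}: file contains no data lines")
    return rows


def load_triples(path, header: str = "auto") -> KnowledgeGraph:
    """Parse a triples TSV into a :class:`KnowledgeGraph`.

    Vocabularies are assigned in first-appearance order; a reserved
    self-loop relation is appended last. ``header`` is one of
    ``{"auto", "skip", "none"}`` — "auto" drops a first row that looks like a
    header (its fields never reappear as entities/relations elsewhere).
    """
    rows = _read_tsv(path, 3)
    if header == "skip" and rows:
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: no data lines after header")
    elif header == "auto" and len(rows) > 1:
        h, r, t = rows[0]
        ents = {a for row in rows[1:] for a in (row[0], row[2])}
        rels = {row[1] for row in rows[1:]}
        if h not in ents and t not in ents and r not in rels:
            rows = rows[1:]
    entities: dict[str, int] = {}
    relations: dict[str, int] = {}
    tri = np.empty((len(rows), 3), dtype=np.int64)
    for i, (h, r, t) in enumerate(rows):
        tri[i, 0] = entities.setdefault(h, len(entities))
        tri[i, 1] = relations.setdefault(r, len(relations))
        tri[i, 2] = entities.setdefault(t, len(entities))
    relations.setdefault(SELF_RELATION, len(relations))
    return KnowledgeGraph(entities, relations, tri)


def write_triples(kg: KnowledgeGraph, path) -> None:
    ents = kg.entity_names()
    rels = kg.relation_names()
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in kg.triples:
            fh.write(f"{ents[h]}\t{rels[r]}\t{ents[t]}\n")


def write_vocabularies(kg: KnowledgeGraph, entities_path, relations_path) -> None:
    pd.DataFrame({"id": range(kg.n_entities), "name": kg.entity_names()}
                 ).to_csv(entities_path, sep="\t", index=False)
    pd.DataFrame({"id": range(kg.n_relations), "name": kg.relation_names()}
                 ).to_csv(relations_path, sep="\t", index=False)


def load_sl_pairs(path, kg: KnowledgeGraph,
                  gene_universe: np.ndarray | None = None) -> SLPairSet:
    """Parse an SL pair TSV, mapping gene names through the KG vocabulary.

    Unordered duplicates with equal labels collapse to one record;
    conflicting labels raise. Pairs naming a gene absent from the KG are
    dropped and counted in ``n_dropped``.
    """
    rows = _read_tsv(path, 3)
    # tolerate a header row (third field non-numeric, e.g. "label")
    if rows and not rows[0][2].lstrip("-").isdigit():
        rows = rows[1:]
    seen: dict[tuple[int, int], int] = {}
    n_dropped = 0
    for lineno, (a, b, lab) in enumerate(rows, start=1):
        if lab not in ("0", "1"):
            raise ParseError(f"{path}: line {lineno}: label must be 0 or 1, "
                             f"got {lab!r}")
        if a not in kg.entities or b not in kg.entities:
            n_dropped += 1
            continue
        ia, ib = kg.entities[a], kg.entities[b]
        if ia == ib:
            raise ParseError(f"{path}: line {lineno}: self-pair {a!r}")
        key = (min(ia, ib), max(ia, ib))
        y = int(lab)
        if key in seen and seen[key] != y:
            raise ParseError(f"{path}: line {lineno}: conflicting labels for "
                             f"pair ({a}, {b})")
        seen[key] = y
    if n_dropped:
        logger.info("load_sl_pairs: dropped %d pairs with genes absent from "
                    "the KG", n_dropped)
    pairs = np.array([(a, b, y) for (a, b), y in seen.items()],
                     dtype=np.int64).reshape(-1, 3)
    if gene_universe is None:
        gene_universe = np.unique(pairs[:, :2]) if len(pairs) else np.empty(0, np.int64)
    return SLPairSet(pairs, np.asarray(gene_universe, dtype=np.int64), n_dropped)


def write_sl_pairs(pairs: SLPairSet, kg: KnowledgeGraph, path) -> None:
    ents = kg.entity_names()
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, y in pairs.pairs:
            fh.write(f"{ents[a]}\t{ents[b]}\t{y}\n")


# ---------------------------------------------------------------------------
# Sampling and splitting


def sample_negatives(positives: SLPairSet, seed: int) -> SLPairSet:
    """Draw ``|positives|`` unordered non-positive gene pairs, uniformly
    without replacement over the gene universe, labeled 0."""
    if len(positives) and not np.all(positives.pairs[:, 2] == 1):
        raise ValueError("sample_negatives expects an all-positive pair set")
    uni = positives.gene_universe
    n_genes = len(uni)
    if n_genes < 2:
        raise ValueError("gene universe too small for negative sampling")
    n_needed = len(positives)
    n_all = n_genes * (n_genes - 1) // 2
    pos_keys = positives.pair_keys()
    if n_all - len(pos_keys) < n_needed:
        raise ValueError(
            f"candidate space ({n_all - len(pos_keys)}) smaller than the "
            f"requested {n_needed} negatives")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    out = np.empty((n_needed, 3), dtype=np.int64)
    n = 0
    while n < n_needed:
        # oversample, reject positives and repeats
        m = max(64, 2 * (n_needed - n))
        ii = rng.integers(0, n_genes, size=m)
        jj = rng.integers(0, n_genes, size=m)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a, b = int(uni[min(i, j)]), int(uni[max(i, j)])
            key = (a, b)
            if key in pos_keys or key in chosen:
                continue
            chosen.add(key)
            out[n] = (a, b, 0)
            n += 1
            if n == n_needed:
                break
    return SLPairSet(out, uni, 0)


def split_random(pairs: SLPairSet, ratios=(0.7, 0.1, 0.2), seed: int = 0) -> DataSplit:
    """Deterministic shuffled partition; floor-based sizes with the remainder
    assigned to train. Valid and test must come out nonempty."""
    r = np.asarray(ratios, dtype=float)
    if np.any(r <= 0) or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs to split")
    n_valid = int(np.floor(r[1] * n))
    n_test = int(np.floor(r[2] * n))
    if n_valid == 0 or n_test == 0:
        raise ValueError("split would leave an empty valid or test set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = n - n_valid - n_test
    return DataSplit(
        train=pairs.subset(order[:n_train]),
        valid=pairs.subset(order[n_train:n_train + n_valid]),
        test=pairs.subset(order[n_train + n_valid:]),
        mode="random", seed=seed)


def split_leave_out_genes(pairs: SLPairSet, holdout_fraction: float,
                          seed: int = 0, train_valid_ratio: float = 7 / 8,
                          holdout_genes: np.ndarray | None = None) -> DataSplit:
    """Cold-gene holdout split: a random gene subset H is held out; test
    pairs are those with *both* genes in H, train/valid pairs those with
    both genes outside H, and pairs straddling the boundary are dropped
    (counted in ``n_dropped``). The train and test gene sets are therefore
    strictly disjoint.

    ``holdout_genes`` overrides the random choice of H (used by nested CV
    to supply precomputed disjoint gene folds).
    """
    rng = np.random.default_rng(seed)
    genes = np.unique(pairs.pairs[:, :2])
    if holdout_genes is None:
        if not (0.0 < holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        n_hold = int(np.ceil(holdout_fraction * len(genes)))
        holdout_genes = rng.choice(genes, size=n_hold, replace=False)
    hold = set(int(g) for g in holdout_genes)
    a_in = np.fromiter((a in hold for a in pairs.pairs[:, 0]), bool, len(pairs))
    b_in = np.fromiter((b in hold for b in pairs.pairs[:, 1]), bool, len(pairs))
    test = pairs.subset(np.flatnonzero(a_in & b_in))
    n_dropped = int((a_in ^ b_in).sum())
    rest_idx = np.flatnonzero(~a_in & ~b_in)
    if len(rest_idx) == 0:
        raise ValueError("no training pairs left after gene holdout")
    order = rng.permutation(len(rest_idx))
    n_train = int(round(train_valid_ratio * len(rest_idx)))
    n_train = min(max(n_train, 1), len(rest_idx) - 1)
    split = DataSplit(
        train=pairs.subset(rest_idx[order[:n_train]]),
        valid=pairs.subset(rest_idx[order[n_train:]]),
        test=test,
        mode="leave_out_genes", seed=seed, n_dropped=n_dropped)
    if len(split.test) == 0:
        raise ValueError("gene holdout produced an empty test set")
    return split


def build_adjacency(pairs: SLPairSet) -> dict[int, dict[int, int]]:
    """Symmetric 0/1 SL adjacency: A[m][n] = 1 iff (m, n) is a positive pair."""
    adj: dict[int, dict[int, int]] = {}
    for a, b, y in pairs.pairs:
        if y != 1:
            continue
        adj.setdefault(int(a), {})[int(b)] = 1
        adj.setdefault(int(b), {})[int(a)] = 1
    return adj
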