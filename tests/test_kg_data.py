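"""Data model, I/O, sampling and splitting contracts."""

import numpy as np
import pytest

from slkg.kg import (ParseError, SLPairSet, build_adjacency, load_sl_pairs,
                     load_triples, sample_negatives, split_leave_out_genes,
                     split_random, write_triples, SELF_RELATION)
from conftest import make_pairset


class TestLoadTriples:
    def test_vocab_counts_and_head_index(self, toy_kg):
        # 3 data triples, 4 distinct entities, 3 relations (+ self relation)
        assert toy_kg.n_triples == 3
        assert set(toy_kg.entities) == {"g1", "g2", "p1", "d1"}
        assert toy_kg.n_relations == 4  # 3 + reserved self relation
        assert SELF_RELATION in toy_kg.relations
        g1 = toy_kg.entities["g1"]
        assert len(toy_kg.neighbors(g1)) == 2

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tr\tb\nc\td\n")
        with pytest.raises(ParseError, match="line 2"):
            load_triples(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            load_triples(p)

    def test_round_trip_preserves_edge_multiset(self, tmp_path, small_dataset):
        kg, _ = small_dataset
        out = tmp_path / "rt.tsv"
        write_triples(kg, out)
        kg2 = load_triples(out, header="none")
        names1 = kg.entity_names()
        rels1 = kg.relation_names()
        edges1 = sorted((names1[h], rels1[r], names1[t])
                        for h, r, t in kg.triples)
        names2 = kg2.entity_names()
        rels2 = kg2.relation_names()
        edges2 = sorted((names2[h], rels2[r], names2[t])
                        for h, r, t in kg2.triples)
        assert edges1 == edges2

    def test_header_auto_detected(self, tmp_path):
        p = tmp_path / "hdr.tsv"
        p.write_text("head\trelation\ttail\na\tr\tb\n")
        kg = load_triples(p)
        assert kg.n_triples == 1
        assert "head" not in kg.entities

    def test_inverse_edges_double_triples(self, toy_kg):
        kg2 = toy_kg.with_inverse_edges()
        assert kg2.n_triples == 2 * toy_kg.n_triples
        # g2 now has an outgoing inverse edge back to g1
        assert len(kg2.neighbors(toy_kg.entities["g2"])) == 1


class TestLoadSLPairs:
    def test_unordered_duplicates_collapse(self, toy_kg, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("g1\tg2\t1\ng2\tg1\t1\n")
        ps = load_sl_pairs(p, toy_kg)
        assert len(ps) == 1

    def test_missing_gene_dropped_and_counted(self, toy_kg, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("g1\tgX\t1\n")
        ps = load_sl_pairs(p, toy_kg)
        assert len(ps) == 0 and ps.n_dropped == 1

    def test_conflicting_labels_rejected(self, toy_kg, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("g1\tg2\t1\ng1\tg2\t0\n")
        with pytest.raises(ParseError, match="conflict"):
            load_sl_pairs(p, toy_kg)

    def test_bad_label_rejected(self, toy_kg, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("g1\tg2\t2\n")
        with pytest.raises(ParseError, match="label"):
            load_sl_pairs(p, toy_kg)


class TestNegativeSampling:
    def test_exact_balance_and_no_collision(self):
        rng = np.random.default_rng(3)
        genes = np.arange(30)
        rows = []
        seen = set()
        while len(rows) < 40:
            a, b = rng.choice(genes, 2, replace=False)
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                rows.append((key[0], key[1], 1))
        pos = make_pairset(rows, n_genes=30)
        neg = sample_negatives(pos, seed=5)
        assert len(neg) == len(pos)
        assert np.all(neg.pairs[:, 2] == 0)
        assert not (neg.pair_keys() & pos.pair_keys())
        assert len(neg.pair_keys()) == len(neg)  # no repeats

    def test_deterministic_and_seed_sensitive(self):
        rows = [(i, i + 1, 1) for i in range(0, 40, 2)]
        pos = make_pairset(rows, n_genes=100)
        a = sample_negatives(pos, seed=1)
        b = sample_negatives(pos, seed=1)
        c = sample_negatives(pos, seed=2)
        assert np.array_equal(a.pairs, b.pairs)
        assert a.pair_keys() != c.pair_keys()

    def test_single_positive_three_gene_universe(self):
        pos = make_pairset([(0, 1, 1)], n_genes=3)
        neg = sample_negatives(pos, seed=0)
        assert len(neg) == 1
        assert tuple(sorted(neg.pairs[0, :2])) in {(0, 2), (1, 2)}

    def test_exhausted_candidate_space_rejected(self):
        pos = make_pairset([(0, 1, 1), (0, 2, 1), (1, 2, 1)], n_genes=3)
        with pytest.raises(ValueError, match="candidate space"):
            sample_negatives(pos, seed=0)


class TestSplits:
    def test_random_split_sizes_7_1_2(self):
        ps = make_pairset([(i, i + 10, 1) for i in range(10)], n_genes=30)
        sp = split_random(ps, (0.7, 0.1, 0.2), seed=0)
        assert (len(sp.train), len(sp.valid), len(sp.test)) == (7, 1, 2)

    def test_split_disjoint_and_deterministic(self):
        ps = make_pairset([(i, i + 50, i % 2) for i in range(100)],
                          n_genes=200)
        a = split_random(ps, (0.7, 0.1, 0.2), seed=9)
        b = split_random(ps, (0.7, 0.1, 0.2), seed=9)
        for part in ("train", "valid", "test"):
            assert np.array_equal(getattr(a, part).pairs,
                                  getattr(b, part).pairs)
        ka, kv, kt = (a.train.pair_keys(), a.valid.pair_keys(),
                      a.test.pair_keys())
        assert not (ka & kv) and not (ka & kt) and not (kv & kt)
        assert len(ka) + len(kv) + len(kt) == 100

    def test_degenerate_ratios_rejected(self):
        ps = make_pairset([(i, i + 10, 1) for i in range(10)], n_genes=30)
        with pytest.raises(ValueError):
            split_random(ps, (1.0, 0.0, 0.0), seed=0)
        with pytest.raises(ValueError):
            split_random(ps, (0.5, 0.2, 0.2), seed=0)  # does not sum to 1

    def test_leave_out_forced_example(self):
        ps = make_pairset([(0, 1, 1), (2, 3, 0)], n_genes=4)
        sp = split_leave_out_genes(ps, 0.5, seed=0,
                                   holdout_genes=np.array([0, 1]))
        assert sp.test.pair_keys() == {(0, 1)}
        assert (sp.train.pair_keys() | sp.valid.pair_keys()) == {(2, 3)}

    def test_leave_out_gene_disjointness(self, small_dataset):
        _, pairs = small_dataset
        sp = split_leave_out_genes(pairs, 0.3, seed=4)
        assert not (sp.train.genes() & sp.test.genes())
        assert not (sp.valid.genes() & sp.test.genes())

    def test_leave_out_fraction_bounds(self, small_dataset):
        _, pairs = small_dataset
        with pytest.raises(ValueError):
            split_leave_out_genes(pairs, 0.0, seed=0)
        with pytest.raises(ValueError):
            split_leave_out_genes(pairs, 1.0, seed=0)


class TestAdjacency:
    def test_symmetry_and_negative_exclusion(self):
        a = build_adjacency(make_pairset([(0, 1, 1), (2, 3, 0)]))
        assert a[0][1] == 1 and a[1][0] == 1
        assert 2 not in a and 3 not in a

    def test_cell_count_is_twice_positive_count(self, rng):
        rows = []
        seen = set()
        while len(rows) < 20:
            x, y = rng.choice(15, 2, replace=False)
            if (min(x, y), max(x, y)) in seen:
                continue
            seen.add((min(x, y), max(x, y)))
            rows.append((min(x, y), max(x, y), int(rng.random() < 0.5)))
        ps = make_pairset(rows, n_genes=15)
        adj = build_adjacency(ps)
        n_cells = sum(len(v) for v in adj.values())
        assert n_cells == 2 * len(ps.positives)
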