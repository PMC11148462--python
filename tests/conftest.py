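import numpy as np
import pytest

from slkg.kg import KnowledgeGraph, SLPairSet, load_triples
from slkg.synthetic import SynthConfig, generate_dataset


@pytest.fixture()
def chain_kg(tmp_path):
    """a -> b -> c chain with one relation."""
    p = tmp_path / "chain.tsv"
    p.write_text("a\tr\tb\nb\tr\tc\n")
    return load_triples(p)


@pytest.fixture()
def toy_kg(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text("g1\tinteracts\tg2\n"
                 "g1\tparticipates\tp1\n"
                 "d1\tassociates\tg1\n")
    return load_triples(p)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted KG + pairs used across unit tests (fast)."""
    cfg = SynthConfig(n_genes=40, n_other_entities=80, n_relations=6,
                      n_sl_pairs=200, edges_per_entity=6, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_pairset(rows, n_genes=10):
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
    return SLPairSet(arr, np.arange(n_genes, dtype=np.int64), 0)
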