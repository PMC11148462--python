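"""Scoring, loss, label smoothness, optimisation loop, metrics, CV."""

import numpy as np
import pytest

from slkg import _autodiff as ad
from slkg.cv import ablate, gene_folds, run_cv, single_split_metrics
from slkg.kg import SLPairSet, split_leave_out_genes, split_random
from slkg.metrics import compute_metrics
from slkg.model import (ModelConfig, SLInteractionModel, SLInteractionResults,
                        add_mix_params, build_tables, init_params,
                        label_smoothness, pair_logits, predict_pair,
                        propagate_labels_loo, score_pairs, total_loss)
from slkg.synthetic import SynthConfig, generate_dataset


def small_config(**kw):
    base = dict(dim=8, batch_size=32, learning_rate=1e-3, p_hop=2, depth=2,
                width=2, n_samples=4, ripple_set_size=4, epochs=3,
                eval_samples=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="module")
def tiny_world():
    cfg = SynthConfig(n_genes=30, n_other_entities=60, n_relations=6,
                      n_sl_pairs=160, edges_per_entity=6, seed=11)
    kg, pairs = generate_dataset(cfg)
    split = split_random(pairs, (0.7, 0.1, 0.2), 0)
    return kg, pairs, split


class TestPredictPair:
    def test_zero_vector_scores_half(self, rng):
        assert predict_pair(np.zeros(4), rng.normal(size=4)) == 0.5

    def test_forced_inner_product(self):
        out = predict_pair(np.array([1.0, 0.0]), np.array([2.0, 0.0]))
        assert out == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        m, n = rng.normal(size=4), rng.normal(size=4)
        assert predict_pair(m, n) == pytest.approx(predict_pair(n, m))


class TestLabelSmoothness:
    def test_constant_labels_fixed_point(self):
        # complete graph over 4 labeled nodes, all labels 1
        w = np.ones((4, 4)) - np.eye(4)
        r = label_smoothness(w, [0, 1, 2, 3], [1, 1, 1, 1], n_iters=2)
        assert float(r) == pytest.approx(0.0, abs=1e-4)

    def test_fewer_than_two_labels_contribute_zero(self):
        w = np.ones((3, 3))
        assert float(label_smoothness(w, [0], [1], 2)) == 0.0

    def test_toy_graph_matches_manual_power_iteration(self):
        # 4-node graph with hand-set weights; nodes 0,1,2 labeled
        w = np.array([[0.0, 2.0, 0.0, 1.0],
                      [2.0, 0.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0, 3.0],
                      [1.0, 0.0, 3.0, 0.0]])
        labeled = [0, 1, 2]
        labels = [1.0, 0.0, 1.0]
        n_iters = 2
        est = propagate_labels_loo(w, labeled, labels, n_iters)
        p = w / w.sum(1, keepdims=True)
        for col, j in enumerate(labeled):
            state = np.full(4, 0.5)
            for jj, y in zip(labeled, labels):
                if jj != j:
                    state[jj] = y
            for _ in range(n_iters):
                nxt = p @ state
                for jj, y in zip(labeled, labels):
                    if jj != j:
                        nxt[jj] = y
                state = nxt
            assert est[col] == pytest.approx(state[j], abs=1e-6)

    def test_differentiable_through_weights(self):
        w = ad.parameter(np.array([[0.0, 1.0, 0.5],
                                   [1.0, 0.0, 1.5],
                                   [0.5, 1.5, 0.0]]))
        r = label_smoothness(w, [0, 1], [1.0, 0.0], 2)
        r.backward()
        assert w.grad is not None and np.any(w.grad != 0)


class TestTotalLoss:
    def test_zero_gates_force_ln2_per_pair(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(l2_weight=0.0, ls_weight=0.0)
        model = SLInteractionModel(split, kg, cfg)
        rng = np.random.default_rng(0)
        params = init_params(model.kg, cfg, rng)
        add_mix_params(params, cfg, rng)
        params["view_gates"].data[:] = 0.0
        tables = build_tables(model.kg, model.seeds, model.gene_universe,
                              cfg, 3)
        pos = split.train.positives[:3, :2]
        neg = split.train.negatives[:3, :2]
        scores = score_pairs(params, np.vstack([pos, neg]), tables, cfg)
        assert np.allclose(scores, 0.5)
        loss, comps = total_loss(params, pos, neg, tables, cfg)
        assert comps["ce"] / comps["n_pairs"] == pytest.approx(np.log(2),
                                                               abs=1e-9)
        assert float(loss.data) == pytest.approx(6 * np.log(2), abs=1e-9)

    def test_l2_component_equals_parameter_square_sum(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(l2_weight=1.0, ls_weight=0.0)
        model = SLInteractionModel(split, kg, cfg)
        rng = np.random.default_rng(1)
        params = init_params(model.kg, cfg, rng)
        add_mix_params(params, cfg, rng)
        tables = build_tables(model.kg, model.seeds, model.gene_universe,
                              cfg, 3)
        pos = split.train.positives[:2, :2]
        neg = split.train.negatives[:2, :2]
        loss, comps = total_loss(params, pos, neg, tables, cfg)
        sq = sum(float(np.sum(v.data ** 2)) for v in params.values())
        assert float(loss.data) - comps["ce"] == pytest.approx(sq, rel=1e-6)
        assert comps["l2"] == pytest.approx(sq, rel=1e-10)

    def test_components_non_negative(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(l2_weight=1e-4, ls_weight=1e-4)
        model = SLInteractionModel(split, kg, cfg)
        rng = np.random.default_rng(2)
        params = init_params(model.kg, cfg, rng)
        add_mix_params(params, cfg, rng)
        tables = build_tables(model.kg, model.seeds, model.gene_universe,
                              cfg, 3)
        pos = split.train.positives[:8, :2]
        neg = split.train.negatives[:8, :2]
        _, comps = total_loss(params, pos, neg, tables, cfg, kg=model.kg,
                              partner_index=model.partner_index,
                              rng=np.random.default_rng(0))
        assert comps["ce"] >= 0 and comps["l2"] >= 0 and comps["ls"] >= 0


class TestFit:
    def test_loss_decreases_on_fixture(self, tiny_world):
        kg, pairs, split = tiny_world
        res = SLInteractionModel(split, kg, small_config(epochs=6)).fit(seed=42)
        assert res.training_log[-1]["loss"] < res.training_log[0]["loss"]

    def test_zero_learning_rate_keeps_parameters(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(learning_rate=0.0, epochs=2)
        model = SLInteractionModel(split, kg, cfg)
        res = model.fit(seed=1)
        rng = np.random.default_rng(np.random.SeedSequence([1, 1]))
        fresh = init_params(model.kg, cfg, rng)
        add_mix_params(fresh, cfg, rng)
        for k in fresh:
            assert np.array_equal(res.params[k], fresh[k].data)

    def test_identical_seed_bit_identical_logs(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(epochs=2)
        r1 = SLInteractionModel(split, kg, cfg).fit(seed=3)
        r2 = SLInteractionModel(split, kg, cfg).fit(seed=3)
        assert r1.training_log == r2.training_log

    def test_checkpoint_roundtrip_scores(self, tiny_world, tmp_path):
        kg, pairs, split = tiny_world
        cfg = small_config(epochs=2)
        res = SLInteractionModel(split, kg, cfg).fit(seed=5)
        path = tmp_path / "model.npz"
        res.save(path)
        res2 = SLInteractionResults.load(path, split, kg)
        a = res.predict(split.test)
        b = res2.predict(split.test)
        assert np.array_equal(a, b)

    def test_batch_scoring_equals_per_pair(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(epochs=1)
        model = SLInteractionModel(split, kg, cfg)
        rng = np.random.default_rng(0)
        params = init_params(model.kg, cfg, rng)
        add_mix_params(params, cfg, rng)
        tables = build_tables(model.kg, model.seeds, model.gene_universe,
                              cfg, 3)
        batch = split.test.pairs[:6, :2]
        all_scores = score_pairs(params, batch, tables, cfg)
        singles = [float(score_pairs(params, batch[i:i + 1], tables, cfg)[0])
                   for i in range(len(batch))]
        assert np.allclose(all_scores, singles, atol=1e-12)

    def test_summary_mentions_key_facts(self, tiny_world):
        kg, pairs, split = tiny_world
        res = SLInteractionModel(split, kg, small_config(epochs=2)).fit(seed=2)
        text = res.summary()
        assert "train pairs" in text and "best valid AUC" in text


class TestMetrics:
    def test_perfect_ranking(self):
        m = compute_metrics(np.array([1, 0, 1, 0]),
                            np.array([0.9, 0.1, 0.8, 0.2]))
        assert m.auc_roc == 1.0 and m.aupr == 1.0

    def test_constant_scores_tie_average(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        assert m.auc_roc == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        labels = np.array([1, 0, 1, 1, 0, 0])
        scores = np.array([0.7, 0.6, 0.9, 0.4, 0.4, 0.1])
        m = compute_metrics(labels, scores)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m.auc_roc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(4), np.linspace(0, 1, 4))


class TestCVAndAblation:
    def test_gene_folds_partition(self, tiny_world):
        _, pairs, _ = tiny_world
        folds = gene_folds(pairs, 5, seed=0)
        genes = np.unique(pairs.pairs[:, :2])
        assert sorted(np.concatenate(folds)) == sorted(genes)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (set(folds[i]) & set(folds[j]))

    def test_leave_out_cv_fold_disjointness_and_mean(self, tiny_world):
        kg, pairs, _ = tiny_world
        cfg = small_config(epochs=1)
        rep = run_cv(pairs, kg, cfg, mode="leave_out", folds=3, seed=1)
        aucs = [f["auc_roc"] for f in rep["folds"]]
        assert rep["auc_roc_mean"] == pytest.approx(np.mean(aucs))
        assert rep["aupr_std"] == pytest.approx(
            np.std([f["aupr"] for f in rep["folds"]]))

    def test_single_point_grid_degenerates(self, tiny_world):
        kg, pairs, _ = tiny_world
        cfg = small_config(epochs=1)
        a = run_cv(pairs, kg, cfg, mode="leave_out", folds=2,
                   grid={"learning_rate": [1e-3]}, seed=2)
        b = run_cv(pairs, kg, cfg, mode="leave_out", folds=2, seed=2)
        assert a["auc_roc_mean"] == pytest.approx(b["auc_roc_mean"])

    def test_drop_relation_types_empty_list_noop(self, tiny_world):
        kg, pairs, split = tiny_world
        cfg = small_config(epochs=1, drop_relations=())
        full = SLInteractionModel(split, kg, cfg)
        dropped = SLInteractionModel(split, kg, cfg, "drop_relation_types")
        assert np.array_equal(full.kg.triples, dropped.kg.triples)

    def test_ablation_variants_run(self, tiny_world):
        kg, pairs, _ = tiny_world
        cfg = small_config(epochs=1)
        for variant in ("no_enhance", "no_attention_fuse"):
            out = single_split_metrics(pairs, kg, cfg, mode="random",
                                       seed=0, variant=variant)
            assert 0.0 <= out["auc_roc"] <= 1.0

    def test_unknown_variant_rejected(self, tiny_world):
        kg, pairs, split = tiny_world
        with pytest.raises(ValueError):
            SLInteractionModel(split, kg, small_config(), "no_everything")
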