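# slkg — synthetic-lethality prediction from knowledge graphs

Synthetic lethality (SL) is a genetic interaction in which knocking out two
genes together kills a cell while either knockout alone is tolerated; SL
pairs of a mutated cancer gene are prized drug targets. Screening pairs in
the wet lab is slow, so computational ranking of candidate pairs matters.
`slkg` predicts SL gene pairs from a heterogeneous biomedical *knowledge
graph* (KG): typed entities (genes, pathways, diseases, compounds, ...)
connected by typed relations, stored as `(head, relation, tail)` triples,
together with a table of labelled gene pairs.

The package is aimed at method developers: it ships the full model, a
typed-KG data layer, two cross-validation protocols (random and cold-gene
holdout), an ablation harness, and a synthetic-data generator that plants a
recoverable KG-mediated SL signal so everything is testable without any
external download.

## Model

For a gene pair (m, n) the model builds three coupled views per gene and
scores the pair with a gated sum of inner products:

* **Ripple view.** The gene's training SL partners form its seed set
  ε⁰; hop frontiers ε^p = { t : (h,r,t) ∈ KG, h ∈ ε^{p-1} } are sampled
  into fixed-size per-hop *ripple sets*. The hop-0 response attends over
  seed heads, `a_i = softmax(w_a·[h_i ‖ n])`; hop-p responses weight
  sampled tails by `k_i = softmax(nᵀ R_i h_i)` with a trainable matrix
  `R_i ∈ R^{S×S}` per relation; responses are fused affinely,
  `m = W_o · concat(o⁰, …, o^p) + b_o`.
* **Entity view.** A fixed number of KG neighbors of the gene are scored by
  a small MLP on (conditioning gene, relation) embeddings, softmax
  normalised and aggregated (relation attention); the aggregated entity is
  *enhanced* with the ripple view through one of four aggregators
  (sum / concat / elementwise-max pool / top-k coordinate selection); a
  discrepancy-contrastive stage mixes the result with the neighborhood
  summary across `depth` aggregation steps and `width` linear mixing
  layers; an attention aggregator fuses the collected representations,
  `α̃ = softmax(w₆ᵀ tanh(W₆ ẽ))`, into the final entity-view embedding.
* **Score.** `ŷ_mn = σ( Σ_v g_v · (v_m · v_n) )` over the three
  perspectives v ∈ {table row, ripple view, entity view}, with learned
  gates g — invariant to pair orientation.

Training minimises cross-entropy over observed positives plus per-gene
uniformly resampled negatives, an L2 penalty `γ‖Θ‖²`, and a
label-smoothness penalty `λ R(A)` in which the gene-conditioned attention
weights must propagate each held-out SL label correctly over the local KG
(leave-one-out clamped label propagation). The entity-embedding table is
initialised from the spectral decomposition of the symmetrised KG adjacency
so that embedding inner products start out approximating shared-neighbor
structure; all mixing maps start identity-biased.

## Worked example

```python
import numpy as np
from slkg import (SynthConfig, generate_dataset, split_random,
                  ModelConfig, SLInteractionModel)

kg, pairs = generate_dataset(SynthConfig())          # planted fixture
split = split_random(pairs, (0.7, 0.1, 0.2), seed=1)
config = ModelConfig(dim=16, batch_size=128, learning_rate=3e-4,
                     p_hop=2, depth=2, width=2, epochs=20,
                     aggregator="top_k", eval_samples=8, seed=1)
results = SLInteractionModel(split, kg, config).fit()
print(results.summary())
m = results.evaluate(split.test)
print(f"test AUC-ROC {m.auc_roc:.4f}  AUPR {m.aupr:.4f}  (n={m.n_pairs})")
```

prints

```
SL interaction model — fit summary
============================================
entities                                1000
relations                                 17
KG triples                             23964
train pairs                             1400
embedding dim                             16
ripple hops                                2
contrast depth/width                     2/2
aggregator                             top_k
variant                                 full
epochs run                                12
best epoch                                 6
final train loss                   1582.6204
best valid AUC                        0.8620
============================================
test AUC-ROC 0.8568  AUPR 0.8253  (n=400)
```

The fixture plants P(SL) = expit(β·overlap + logit(c)) where `overlap` is
the pair's shared-typed-neighbor count in the KG, so an AUC far above 0.5
means the model recovered graph-mediated structure: 0.86 here against a
closed-form ceiling of about 0.91 (the AUC of the true planted
probabilities). `results.predict(pairs)` returns per-pair probabilities,
`results.save("model.npz")` a portable checkpoint.

A thin CLI mirrors the library: `slkg synth`, `prepare`, `train`,
`evaluate`, `predict`, `cv --mode random|leave_out`, and
`ablate --variant no_ripple|no_enhance|no_attention_fuse|drop_relation_types`.

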