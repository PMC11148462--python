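"""Canonical synthetic-recovery benchmark.

One place defines the study conditions shared by the test suite and the
reproduction script: the canonical planted-structure fixture (200 genes,
800 other entities, 8 relations, 2,000 balanced pairs, generator seed 42)
and the scaled-down model configuration used on it (dim 16, two ripple
hops, contrast depth 2 / width 2, ripple-set and neighbor-sample size 8,
at most 20 epochs, Adam at 3e-4 with batches of 128, predictions averaged
over 8 sample draws).
"""

from __future__ import annotations

import numpy as np

from .kg import SLPairSet, split_leave_out_genes, split_random
from .model import ModelConfig, SLInteractionModel
from .synthetic import SynthConfig, baseline_auc, generate_dataset

FIXTURE_SEED = 42
HOLDOUT_FRACTION = 0.3

SCALED = dict(dim=16, batch_size=128, learning_rate=3e-4, p_hop=2,
              depth=2, width=2, epochs=20, aggregator="top_k",
              eval_samples=8)


def fixture_dataset(seed: int = FIXTURE_SEED):
    """The canonical fixture KG + planted balanced SL pairs."""
    return generate_dataset(SynthConfig(seed=seed))


def scaled_config(seed: int) -> ModelConfig:
    return ModelConfig(seed=seed, **SCALED)


def fit_and_score(kg, pairs: SLPairSet, seed: int, mode: str = "random",
                  variant: str | None = None) -> float:
    """One train/evaluate cycle on the fixture; returns test AUC-ROC."""
    if mode == "random":
        split = split_random(pairs, (0.7, 0.1, 0.2), seed)
    else:
        split = split_leave_out_genes(pairs, HOLDOUT_FRACTION, seed=seed)
    res = SLInteractionModel(split, kg, scaled_config(seed), variant).fit()
    return res.evaluate(split.test).auc_roc


def permute_labels(pairs: SLPairSet, seed: int) -> SLPairSet:
    """Label-permuted control: same pairs, labels shuffled."""
    arr = pairs.pairs.copy()
    arr[:, 2] = np.random.default_rng(seed).permutation(arr[:, 2])
    return SLPairSet(arr, pairs.gene_universe, 0)


def recovery_benchmark(model_seeds=(1, 2, 3), fixture_seed: int = FIXTURE_SEED,
                       include_ablation: bool = True) -> dict:
    """Synthetic-recovery study: median test AUC over seeds for the full
    model under random splits, the label-permuted control, and (optionally)
    the gene-holdout comparison of the full model against the no-ripple
    ablation. Also reports the shared-neighbor baseline AUC."""
    kg, pairs = fixture_dataset(fixture_seed)
    out = {"baseline_shared_neighbor_auc": baseline_auc(kg, pairs),
           "n_pairs": len(pairs), "model_seeds": list(model_seeds)}
    rand, perm = [], []
    for s in model_seeds:
        rand.append(fit_and_score(kg, pairs, s, "random"))
        perm.append(fit_and_score(kg, permute_labels(pairs, s), s, "random"))
    out["random_cv_auc_median"] = float(np.median(rand))
    out["random_cv_auc_all"] = rand
    out["permuted_auc_median"] = float(np.median(perm))
    out["permuted_auc_all"] = perm
    if include_ablation:
        full, norip = [], []
        for s in model_seeds:
            full.append(fit_and_score(kg, pairs, s, "leave_out"))
            norip.append(fit_and_score(kg, pairs, s, "leave_out", "no_ripple"))
        out["holdout_full_auc_median"] = float(np.median(full))
        out["holdout_full_auc_all"] = full
        out["holdout_no_ripple_auc_median"] = float(np.median(norip))
        out["holdout_no_ripple_auc_all"] = norip
    return out
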