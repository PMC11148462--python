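"""Cross-validation harnesses and ablation runner.

Two evaluation regimes are provided. *Random CV* re-splits the labeled pairs
uniformly (7:1:2 by default) in each fold. *Gene-holdout nested CV*
partitions the genes into disjoint outer folds; test pairs of a fold touch
only held-out genes, so test genes never occur in training pairs — the
stringent setting for generalisation to novel genes. The inner loop selects
a configuration from a grid by validation AUC; the chosen model is then
scored once on the outer test fold.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .kg import (DataSplit, KnowledgeGraph, SLPairSet, split_leave_out_genes,
                 split_random)
from .model import ModelConfig, SLInteractionModel, SLInteractionResults

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = ("no_ripple", "no_enhance", "no_attention_fuse",
                     "drop_relation_types")


def gene_folds(pairs: SLPairSet, n_folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint gene groups of near-equal size for gene-holdout CV."""
    genes = np.unique(pairs.pairs[:, :2])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(genes)
    return [perm[i::n_folds] for i in range(n_folds)]


def _expand_grid(grid: dict[str, list]) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    combos = [{}]
    for k in keys:
        combos = [{**c, k: v} for c in combos for v in grid[k]]
    return combos


def _fit_eval(split: DataSplit, kg: KnowledgeGraph, config: ModelConfig,
              variant: str | None, seed: int):
    model = SLInteractionModel(split, kg, config, variant)
    res = model.fit(seed=seed)
    return res


def run_cv(pairs: SLPairSet, kg: KnowledgeGraph, config: ModelConfig,
           mode: str = "random", folds: int = 5,
           grid: dict[str, list] | None = None,
           variant: str | None = None, seed: int = 0) -> dict:
    """Cross-validated test metrics.

    ``grid`` maps ModelConfig field names to candidate value lists; with a
    single-point (or empty) grid the nested inner loop degenerates to plain
    CV. Folds whose test set contains one class are skipped with a warning.
    """
    if mode not in ("random", "leave_out"):
        raise ValueError(f"unknown CV mode {mode!r}")
    combos = _expand_grid(grid or {})
    if not combos:
        raise ValueError("empty hyperparameter grid")
    fold_records: list[dict] = []
    groups = gene_folds(pairs, folds, seed) if mode == "leave_out" else None
    for f in range(folds):
        fold_seed = seed * 131 + f
        if mode == "random":
            split = split_random(pairs, (0.7, 0.1, 0.2), fold_seed)
        else:
            split = split_leave_out_genes(pairs, 1.0 / folds,
                                          seed=fold_seed,
                                          holdout_genes=groups[f])
        if len(np.unique(split.test.pairs[:, 2])) < 2:
            logger.warning("fold %d skipped: single-class test set", f)
            continue
        best = None
        for combo in combos:
            cfg = replace(config, **combo) if combo else config
            res = _fit_eval(split, kg, cfg, variant, fold_seed)
            val_auc = max((r["val_auc"] for r in res.training_log),
                          default=-np.inf)
            if best is None or val_auc > best[0]:
                best = (val_auc, combo, res)
        _, combo, res = best
        m = res.evaluate(split.test)
        fold_records.append({
            "fold": f, "mode": mode, "config": combo,
            "auc_roc": m.auc_roc, "aupr": m.aupr,
            "n_test": m.n_pairs,
            "n_dropped": getattr(split, "n_dropped", 0)})
        logger.info("fold %d (%s): AUC %.4f AUPR %.4f", f, mode,
                    m.auc_roc, m.aupr)
    if not fold_records:
        raise ValueError("all folds were skipped")
    aucs = np.array([r["auc_roc"] for r in fold_records])
    auprs = np.array([r["aupr"] for r in fold_records])
    return {
        "mode": mode, "folds": fold_records,
        "auc_roc_mean": float(aucs.mean()), "auc_roc_std": float(aucs.std()),
        "aupr_mean": float(auprs.mean()), "aupr_std": float(auprs.std()),
        "variant": variant or "full",
    }


def ablate(variant: str, pairs: SLPairSet, kg: KnowledgeGraph,
           config: ModelConfig, mode: str = "leave_out", folds: int = 5,
           seed: int = 0) -> dict:
    """Train and cross-validate one ablation variant (or 'full')."""
    if variant not in ABLATION_VARIANTS + ("full",):
        raise ValueError(f"unknown ablation variant {variant!r}")
    v = None if variant == "full" else variant
    report = run_cv(pairs, kg, config, mode=mode, folds=folds,
                    variant=v, seed=seed)
    report["variant"] = variant
    return report


def single_split_metrics(pairs: SLPairSet, kg: KnowledgeGraph,
                         config: ModelConfig, mode: str = "random",
                         seed: int = 0, variant: str | None = None,
                         holdout_fraction: float = 0.2) -> dict:
    """Train once on one split and report test metrics (cheaper than CV;
    used for seed-replicate medians)."""
    if mode == "random":
        split = split_random(pairs, (0.7, 0.1, 0.2), seed)
    else:
        split = split_leave_out_genes(pairs, holdout_fraction, seed=seed)
    res = _fit_eval(split, kg, config, variant, seed)
    m = res.evaluate(split.test)
    return {"mode": mode, "seed": seed, "variant": variant or "full",
            "auc_roc": m.auc_roc, "aupr": m.aupr, "n_test": m.n_pairs,
            "results": res}
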