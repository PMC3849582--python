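"""Simulation studies quantifying the statistical behavior of the pipeline.

These routines generate data with the synthetic-data module, run the real
analysis code on it, and report operating characteristics: planted-block
recovery by the tree model, type-I error and power of the PAGE scores,
agreement of the normal-theory p-value with a gene-resampling null, and
group separation of the gene-set PCA. All randomness flows from the explicit
seed arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genesets import GeneSet, GeneSetCollection
from .page import empirical_p, run_gsa, z_ratio, zscore_normalize
from .pca import project_samples
from .phenomodel import TreeFitConfig, distance_matrix, fit_tree, tree_splits
from .simulate import (
    PlantedCollectionSpec,
    PlantedExpressionSpec,
    simulate_collection,
    simulate_expression,
)

__all__ = [
    "tree_block_recovery_rate",
    "gsa_null_type1_rate",
    "page_vs_resampling_gap",
    "gsa_power_curve",
    "gsa_planted_sensitivity",
    "pca_separation_rate",
]


def tree_block_recovery_rate(n_seeds: int = 20, seed: int = 0,
                             power: float = 2.0,
                             **spec_kwargs) -> float:
    """Fraction of seeds where the fitted tree bipartitions the two planted
    blocks exactly (an internal edge separates block 0 from block 1)."""
    hits = 0
    for k in range(n_seeds):
        spec = PlantedCollectionSpec(seed=seed + k, **spec_kwargs)
        coll, ledger = simulate_collection(spec)
        D = distance_matrix(coll)
        tree = fit_tree(D, TreeFitConfig(power=power))
        blocks: dict[int, set[str]] = {}
        for term, b in ledger["blocks"].items():
            blocks.setdefault(b, set()).add(term)
        splits = tree_splits(tree)
        hits += int(any(frozenset(side) in splits
                        for side in blocks.values()))
    return hits / n_seeds


def _random_collection(genes: list[str], n_sets: int,
                       size_range: tuple[int, int],
                       rng: np.random.Generator) -> GeneSetCollection:
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets.append(GeneSet(f"rand_{i:04d}", [genes[j] for j in members]))
    return GeneSetCollection("random", sets)


def gsa_null_type1_rate(n_seeds: int = 20, n_sets: int = 200,
                        n_genes: int = 2000,
                        size_range: tuple[int, int] = (10, 200),
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of random gene sets called significant (p < alpha) on iid
    normal change values — the realized type-I error of the reported p."""
    genes = [f"g{i}.1" for i in range(n_genes)]
    hits = total = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        scores = pd.Series(rng.normal(size=n_genes), index=genes)
        coll = _random_collection(genes, n_sets, size_range, rng)
        table = run_gsa(coll, scores, min_genes=3, max_genes=None)
        hits += int((table["p"] < alpha).sum())
        total += len(table)
    return hits / total


def page_vs_resampling_gap(n_instances: int = 20, n_a: int = 200,
                           n_i: int = 20, draws: int = 100_000,
                           seed: int = 0) -> float:
    """Max |normal-theory p of Z − resampling p| over random null instances.

    The resampling null redraws the set's n_i change values iid from the
    array's empirical score distribution and recomputes the set-vs-array
    mean difference; the parametric comparator is 2(1 − Φ(|z|)).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        values = rng.normal(size=n_a)
        pos = rng.choice(n_a, size=n_i, replace=False)
        diff_obs = values[pos].mean() - values.mean()
        z = np.sqrt(n_i) * diff_obs / values.std(ddof=1)
        p_param = 2.0 * norm.sf(abs(z))
        resampled = rng.choice(values, size=(draws, n_i), replace=True)
        diff_null = resampled.mean(axis=1) - values.mean()
        p_resamp = float(np.mean(np.abs(diff_null) >= abs(diff_obs)))
        worst = max(worst, abs(p_param - p_resamp))
    return worst


def gsa_power_curve(deltas=(0.0, 0.25, 0.5, 1.0), n_a: int = 2000,
                    n_i: int = 20, reps: int = 200, alpha: float = 0.05,
                    seed: int = 0) -> dict[float, float]:
    """Rejection rate of the reported p at each planted shift (sigma = 1)."""
    out: dict[float, float] = {}
    for d, delta in enumerate(deltas):
        rng = np.random.default_rng(seed + d)
        hits = 0
        for _ in range(reps):
            values = rng.normal(size=n_a)
            values[:n_i] += delta
            diff = values[:n_i].mean() - values.mean()
            p = empirical_p(diff, values[:n_i].std(ddof=1), n_i,
                            values.std(ddof=1), n_a)
            hits += p < alpha
        out[float(delta)] = hits / reps
    return out


def gsa_planted_sensitivity(n_seeds: int = 10, delta: float = 1.0,
                            q_threshold: float = 0.05,
                            seed: int = 0) -> float:
    """End-to-end sensitivity: generate expression with planted set shifts,
    run Z-normalization, Z-ratio, and PAGE, and report the fraction of
    planted sets recovered at the FDR threshold."""
    found = planted = 0
    for k in range(n_seeds):
        coll, _ = simulate_collection(PlantedCollectionSpec(
            n_phenotypes=30, gene_pool_size=1500, set_size_range=(20, 30),
            seed=seed + k))
        targets = coll.terms()[:3]
        espec = PlantedExpressionSpec(
            n_genes=3000,
            target_sets={t: {"A": delta} for t in targets},
            seed=seed + k)
        expr, ledger = simulate_expression(espec, coll)
        scores = z_ratio(zscore_normalize(expr),
                         ledger["groups"]["A"], ledger["groups"]["B"])
        table = run_gsa(coll, scores, min_genes=3, max_genes=500)
        sig = set(table.index[table["q"] <= q_threshold])
        planted += len(targets)
        found += len(sig & set(targets))
    return found / planted


def pca_separation_rate(n_seeds: int = 20, n_sets: int = 50,
                        shifted_fraction: float = 0.2, delta: float = 2.0,
                        per_group: int = 6, seed: int = 0) -> float:
    """Fraction of seeds where PC1 of the gene-set Z matrix separates the
    two sample groups with zero overlap."""
    n_shift = int(round(shifted_fraction * n_sets))
    hits = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        X = rng.normal(size=(n_sets, 2 * per_group))
        X[:n_shift, per_group:] += delta
        zmat = pd.DataFrame(
            X, index=[f"set{i}" for i in range(n_sets)],
            columns=[f"A_{j}" for j in range(per_group)]
            + [f"B_{j}" for j in range(per_group)])
        pc1 = project_samples(zmat, components=1).coordinates["PC1"]
        a = pc1.iloc[:per_group].to_numpy()
        b = pc1.iloc[per_group:].to_numpy()
        hits += int(a.max() < b.min() or b.max() < a.min())
    return hits / n_seeds
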