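"""Synthetic association tables and expression matrices with planted truth.

Every generator takes an explicit seed and returns, next to its output, a
*ledger*: the exact planted structure (pair list, block memberships, shifted
genes) so downstream stages can be tested against known ground truth without
any external downloads.

``simulate_association_table`` emulates the gene-sharing structure of
curated phenotype annotations: phenotype terms fall into blocks, and sets in
the same block draw most of their genes from a small shared pool, so
within-block overlap distances are small and between-block distances large.
``simulate_expression`` emulates a grouped expression experiment with
selected gene sets shifted by a group-specific effect over iid Gaussian
noise.

Gene identifiers are formatted like worm locus tags (``SYN12.3``), a third
of them carrying a parenthesized symbol in the emitted table, so the
generated files exercise the same label-normalization path as real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SpecError
from .genesets import (
    GeneSetCollection,
    build_collection,
    parse_association_table,
)

__all__ = [
    "PlantedCollectionSpec",
    "PlantedExpressionSpec",
    "simulate_association_table",
    "simulate_collection",
    "simulate_expression",
]


@dataclass(frozen=True)
class PlantedCollectionSpec:
    """Planted block structure for a synthetic gene-set collection."""

    n_phenotypes: int = 12
    gene_pool_size: int = 240
    set_size_range: tuple[int, int] = (6, 12)
    n_blocks: int = 2
    within_block_sharing: float = 0.8
    between_block_sharing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        smin, smax = self.set_size_range
        if self.n_phenotypes < 1 or self.gene_pool_size < 1:
            raise SpecError("sizes must be positive")
        if not 1 <= smin <= smax:
            raise SpecError("invalid set_size_range")
        if self.n_blocks < 1 or self.n_blocks > self.n_phenotypes:
            raise SpecError("n_blocks must be in [1, n_phenotypes]")
        if not (0.0 <= self.between_block_sharing
                <= self.within_block_sharing <= 1.0):
            raise SpecError(
                "need 0 <= between_block_sharing <= within_block_sharing <= 1")


def _gene_labels(n: int) -> tuple[list[str], list[str]]:
    """Canonical ids and printed labels (every third gene gets a symbol)."""
    ids, printed = [], []
    for i in range(n):
        gid = f"SYN{i // 8 + 1}.{i % 8 + 1}"
        ids.append(gid)
        printed.append(f"{gid}(sgn-{i + 1})" if i % 3 == 0 else gid)
    return ids, printed


def simulate_association_table(
        spec: PlantedCollectionSpec) -> tuple[str, dict]:
    """Generate a worm-dialect association table plus its ledger.

    Phenotype terms are partitioned evenly into blocks. Each gene of a set
    is drawn from the set's own block pool with probability
    ``within_block_sharing``, from another block's pool with probability
    ``between_block_sharing`` (zero when there is a single block), and from
    a background pool otherwise. Deterministic given the seed.
    """
    smin, smax = spec.set_size_range
    shared_size = max(smax, spec.gene_pool_size // (4 * spec.n_blocks))
    n_shared = shared_size * spec.n_blocks
    n_background = spec.gene_pool_size - n_shared
    if n_background < smax:
        raise SpecError(
            f"gene_pool_size={spec.gene_pool_size} too small for "
            f"{spec.n_blocks} block pools of {shared_size} plus a "
            f"background of >= {smax}")
    ids, printed = _gene_labels(spec.gene_pool_size)
    block_pools = [np.arange(b * shared_size, (b + 1) * shared_size)
                   for b in range(spec.n_blocks)]
    background = np.arange(n_shared, spec.gene_pool_size)

    rng = np.random.default_rng(spec.seed)
    p_within = spec.within_block_sharing
    p_between = spec.between_block_sharing if spec.n_blocks > 1 else 0.0

    lines: list[str] = []
    pairs: list[list[str]] = []
    blocks: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for k in range(spec.n_phenotypes):
        block = k % spec.n_blocks
        term_raw = f"planted phenotype {k:03d}"
        term = "_".join(term_raw.split())
        blocks[term] = block
        size = int(rng.integers(smin, smax + 1))
        chosen: list[int] = []
        seen: set[int] = set()
        while len(chosen) < size:
            u = rng.random()
            if u < p_within:
                pool = block_pools[block]
            elif u < p_within + p_between:
                others = [b for b in range(spec.n_blocks) if b != block]
                pool = block_pools[others[int(rng.integers(len(others)))]]
            else:
                pool = background
            g = int(pool[int(rng.integers(len(pool)))])
            if g not in seen:
                seen.add(g)
                chosen.append(g)
        members[term] = sorted(ids[g] for g in chosen)
        for g in chosen:
            lines.append(f"{printed[g]}\t{term_raw}")
            pairs.append([ids[g], term])

    ledger = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "pairs": pairs,
        "blocks": blocks,
        "members": members,
        "gene_block": {ids[g]: b for b, pool in enumerate(block_pools)
                       for g in pool},
    }
    return "\n".join(lines) + "\n", ledger


def simulate_collection(spec: PlantedCollectionSpec,
                        label: str = "synthetic"
                        ) -> tuple[GeneSetCollection, dict]:
    """Generate a table and run it through the real parsing path."""
    import io

    table, ledger = simulate_association_table(spec)
    pairs = parse_association_table(io.StringIO(table), "worm_pairs")
    coll = build_collection(pairs, label,
                            provenance=f"simulated, seed={spec.seed}")
    return coll, ledger


@dataclass(frozen=True)
class PlantedExpressionSpec:
    """Planted group shifts for a synthetic expression matrix."""

    n_genes: int = 2000
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"A": 4, "B": 4})
    # set name -> {group label -> shift delta}
    target_sets: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        if not self.groups or any(n < 2 for n in self.groups.values()):
            raise SpecError("every group needs >= 2 samples")
        if self.n_genes < 2:
            raise SpecError("n_genes must be >= 2")


def simulate_expression(spec: PlantedExpressionSpec,
                        coll: GeneSetCollection
                        ) -> tuple[pd.DataFrame, dict]:
    """Gaussian expression matrix with planted per-group set shifts.

    Genes are the collection's genes padded with filler genes up to
    ``n_genes``; baseline values are iid normal(0, noise_sd); for each
    target set and group, that set's genes are shifted by the group's delta
    in that group's samples. Returns (genes x samples DataFrame, ledger).
    """
    for name, shifts in spec.target_sets.items():
        if name not in coll:
            raise SpecError(f"unknown target set {name!r}")
        for g in shifts:
            if g not in spec.groups:
                raise SpecError(f"unknown group {g!r} for set {name!r}")

    coll_genes = sorted({g for t in coll.terms() for g in coll[t].genes})
    if len(coll_genes) > spec.n_genes:
        raise SpecError(
            f"collection has {len(coll_genes)} genes > n_genes={spec.n_genes}")
    filler = [f"FIL{i + 1}.1" for i in range(spec.n_genes - len(coll_genes))]
    genes = coll_genes + filler
    samples: list[str] = []
    group_cols: dict[str, list[int]] = {}
    for gname, n in spec.groups.items():
        group_cols[gname] = list(range(len(samples), len(samples) + n))
        samples.extend(f"{gname}_{k + 1}" for k in range(n))

    rng = np.random.default_rng(spec.seed)
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    gene_row = {g.casefold(): i for i, g in enumerate(genes)}
    shifted: dict[str, dict] = {}
    for name, shifts in spec.target_sets.items():
        rows = sorted(gene_row[k] for k in coll[name].gene_keys)
        shifted[name] = {"genes": [genes[r] for r in rows],
                         "shifts": dict(shifts)}
        for gname, delta in shifts.items():
            values[np.ix_(rows, group_cols[gname])] += delta

    expr = pd.DataFrame(values, index=genes, columns=samples)
    ledger = {
        "seed": spec.seed,
        "groups": {g: [samples[c] for c in cols]
                   for g, cols in group_cols.items()},
        "shifted": shifted,
        "noise_sd": spec.noise_sd,
    }
    return expr, ledger


def write_ledger(ledger: dict, target) -> None:
    """Write a generator ledger as JSON next to its output file."""
    import os

    if hasattr(target, "write"):
        json.dump(ledger, target, indent=1, sort_keys=True)
    else:
        with open(os.fspath(target), "w", encoding="utf-8") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)
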