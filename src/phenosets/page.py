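"""Parametric gene-set analysis (PAGE) of expression contrasts.

Given per-gene expression-change values (log ratios or Z-ratios) for one
contrast, each gene set is scored with the parametric PAGE statistic

    Z_i = sqrt(n_i) * diff_i / sigma_a,    diff_i = mean(GC_i) - mean(GC_a),

where GC_a are the change values over the whole array (n_a genes, standard
deviation sigma_a) and GC_i those of the set's n_i matched genes. A normal-
theory p-value for the difference of means uses

    sigma(diff_i) = sqrt(sigma_i^2/n_i + sigma_a^2/n_a),
    p_i = 2 * (1 - Phi(|diff_i| / sigma(diff_i))),

and false-discovery control across the surviving sets is Benjamini–Hochberg.

Preprocessing helpers: per-sample Z-score normalization of an expression
matrix, and the Z-ratio contrast (difference of group-mean Z values per
gene, scaled by the standard deviation of those differences across genes).

Containers are the field's usual ones: an expression matrix is a pandas
DataFrame (genes x samples, unique labels both ways), a contrast is a pandas
Series indexed by gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConfigurationError,
    DegenerateContrastError,
    EmptyResultError,
    NormalizationError,
)
from .genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PageScore",
    "zscore_normalize",
    "z_ratio",
    "page_z",
    "empirical_p",
    "run_gsa",
    "gsa_matrix",
    "read_expression_tsv",
]


def _validate_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise ConfigurationError("duplicate gene identifiers in matrix")
    if expr.columns.has_duplicates:
        raise ConfigurationError("duplicate sample labels in matrix")


def zscore_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each sample column: subtract its mean, divide by its SD (n-1).

    Missing values are ignored in the column statistics and stay missing.
    """
    _validate_matrix(expr)
    if (expr.notna().sum(axis=0) < 2).any():
        raise NormalizationError("every sample needs >= 2 finite values")
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=1)
    bad = sd[(sd == 0) | sd.isna()]
    if len(bad):
        raise NormalizationError(
            f"zero-variance sample(s): {list(bad.index)}")
    return (expr - mu) / sd


def z_ratio(expr_z: pd.DataFrame, group_a: Sequence[str],
            group_b: Sequence[str]) -> pd.Series:
    """Per-gene Z-ratio contrast between two sample groups.

    For each gene: (mean Z over group_a) - (mean Z over group_b), divided by
    the standard deviation of those per-gene differences across genes, so
    the returned scores have unit spread. Genes with any missing value in
    either group are dropped.
    """
    _validate_matrix(expr_z)
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ConfigurationError("both groups must be non-empty")
    if set(a) & set(b):
        raise ConfigurationError("groups must be disjoint")
    unknown = (set(a) | set(b)) - set(expr_z.columns)
    if unknown:
        raise ConfigurationError(f"unknown sample label(s): {sorted(unknown)}")
    sub = expr_z[a + b].dropna(axis=0, how="any")
    if len(sub) < 2:
        raise DegenerateContrastError("fewer than 2 genes with complete data")
    diff = sub[a].mean(axis=1) - sub[b].mean(axis=1)
    s = float(diff.std(ddof=1))
    if s == 0:
        raise DegenerateContrastError(
            "per-gene group differences have zero spread")
    return diff / s


@dataclass(frozen=True)
class PageScore:
    """PAGE statistic for one gene set against one contrast."""

    set_name: str
    n_set: int          # n_i: set genes matched in the contrast
    n_all: int          # n_a: genes in the whole contrast
    diff: float         # set mean minus array mean
    sigma_set: float    # SD of matched set scores (nan when n_set < 2)
    sigma_all: float    # SD of all scores
    z: float


def _match_positions(scores: pd.Series, geneset: GeneSet) -> np.ndarray:
    keys = pd.Index([str(g).casefold() for g in scores.index])
    return np.flatnonzero(keys.isin(geneset.gene_keys))


def page_z(scores: pd.Series, geneset: GeneSet,
           statistic: str = "sqrt_n") -> PageScore:
    """Score one gene set against per-gene change values.

    ``statistic='sqrt_n'`` is the PAGE statistic sqrt(n_i)*diff/sigma_a;
    ``statistic='n_minus_1'`` is the alternative literal reading
    (n_i - 1)*diff/sigma_a (off by default).
    Gene matching is case-insensitive on canonical identifiers.
    """
    if statistic not in ("sqrt_n", "n_minus_1"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    values = scores.to_numpy(dtype=float)
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise DegenerateContrastError("scores must be >= 2 finite values")
    pos = _match_positions(scores, geneset)
    n_i = int(pos.size)
    if n_i == 0:
        raise EmptyResultError(f"no genes of {geneset.name!r} in contrast")
    sigma_a = float(np.std(values, ddof=1))
    if sigma_a == 0:
        raise DegenerateContrastError("zero spread in change values")
    sub = values[pos]
    diff = float(sub.mean() - values.mean())
    sigma_i = float(np.std(sub, ddof=1)) if n_i >= 2 else float("nan")
    factor = np.sqrt(n_i) if statistic == "sqrt_n" else (n_i - 1)
    z = float(factor * diff / sigma_a)
    return PageScore(geneset.name, n_i, values.size, diff, sigma_i,
                     sigma_a, z)


def empirical_p(diff_i: float, sigma_i: float, n_i: int,
                sigma_a: float, n_a: int) -> float:
    """Two-sided normal p for diff_i with sd sqrt(s_i^2/n_i + s_a^2/n_a)."""
    if n_i < 2 or n_a < 2:
        raise ConfigurationError("empirical_p requires n_i >= 2 and n_a >= 2")
    sd = float(np.sqrt(sigma_i ** 2 / n_i + sigma_a ** 2 / n_a))
    if sd == 0:
        logger.warning("sigma(diff)=0; limit convention p=%d",
                       1 if diff_i == 0 else 0)
        return 1.0 if diff_i == 0 else 0.0
    return float(2.0 * norm.sf(abs(diff_i) / sd))


def run_gsa(coll: GeneSetCollection, scores: pd.Series,
            min_genes: int = 3, max_genes: int | None = 500,
            statistic: str = "sqrt_n",
            fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Score every gene set of a collection against one contrast.

    The size filter counts genes matched in the contrast (the statistic's
    n_i), not nominal set size. Returns a DataFrame indexed by set name with
    columns n, diff, sigma_set, z, p, q, sorted by |z| descending. ``q`` is
    Benjamini–Hochberg across the surviving sets.
    """
    rows = []
    skipped = 0
    for s in coll:
        try:
            sc = page_z(scores, s, statistic=statistic)
        except EmptyResultError:
            skipped += 1
            continue
        if sc.n_set < min_genes or (max_genes is not None
                                    and sc.n_set > max_genes):
            continue
        p = empirical_p(sc.diff, sc.sigma_set, sc.n_set,
                        sc.sigma_all, sc.n_all)
        rows.append((sc.set_name, sc.n_set, sc.diff, sc.sigma_set, sc.z, p))
    if skipped:
        logger.info("run_gsa: %d sets had no matched genes", skipped)
    if not rows:
        raise EmptyResultError("no gene set survived matching and size filter")
    df = pd.DataFrame(rows, columns=["set", "n", "diff", "sigma_set",
                                     "z", "p"]).set_index("set")
    df["q"] = multipletests(df["p"].to_numpy(), method=fdr_method)[1]
    return df.reindex(df["z"].abs().sort_values(ascending=False,
                                                kind="stable").index)


def gsa_matrix(coll: GeneSetCollection,
               contrasts: Mapping[str, pd.Series],
               min_genes: int = 3, max_genes: int | None = 500,
               statistic: str = "sqrt_n",
               q_threshold: float | None = None) -> pd.DataFrame:
    """Z-score matrix (set x contrast) over labeled contrasts.

    Rows are the sets surviving the size filter in every contrast; with
    ``q_threshold`` set, rows are restricted to sets significant (q below
    the threshold) in at least one contrast.
    """
    if not contrasts:
        raise ConfigurationError("at least one contrast is required")
    tables = {lab: run_gsa(coll, sc, min_genes=min_genes,
                           max_genes=max_genes, statistic=statistic)
              for lab, sc in contrasts.items()}
    common: set[str] | None = None
    for df in tables.values():
        common = set(df.index) if common is None else common & set(df.index)
    if not common:
        raise EmptyResultError("no gene set survived in every contrast")
    index = sorted(common)
    zmat = pd.DataFrame({lab: df.loc[index, "z"]
                         for lab, df in tables.items()}, index=index)
    if q_threshold is not None:
        qmat = pd.DataFrame({lab: df.loc[index, "q"]
                             for lab, df in tables.items()}, index=index)
        keep = (qmat <= q_threshold).any(axis=1)
        if not keep.any():
            raise EmptyResultError(
                f"no gene set significant at q <= {q_threshold}")
        zmat = zmat.loc[keep]
    return zmat


def read_expression_tsv(source) -> pd.DataFrame:
    """Read an expression TSV: first column gene id, header sample labels."""
    df = pd.read_csv(source, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    _validate_matrix(df)
    return df
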