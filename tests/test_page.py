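import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from phenosets.errors import (
    ConfigurationError,
    DegenerateContrastError,
    EmptyResultError,
    NormalizationError,
)
from phenosets.genesets import GeneSet, GeneSetCollection
from phenosets.page import (
    empirical_p,
    gsa_matrix,
    page_z,
    run_gsa,
    z_ratio,
    zscore_normalize,
)

from conftest import make_collection


def reference_bh(pvals):
    """Independent Benjamini–Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# normalization and contrasts

def test_zscore_column_example():
    expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 0.0, 2.0]},
                        index=["g1", "g2", "g3"])
    z = zscore_normalize(expr)
    assert np.allclose(z["s1"], [-1, 0, 1])
    assert z.mean().abs().max() < 1e-12
    assert np.allclose(z.std(ddof=1), 1.0)


def test_zscore_is_idempotent():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(50, 4)),
                        index=[f"g{i}" for i in range(50)],
                        columns=list("abcd"))
    z1 = zscore_normalize(expr)
    z2 = zscore_normalize(z1)
    assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)
    assert z1.mean().abs().max() < 1e-12
    assert np.allclose(z1.std(ddof=1), 1.0, atol=1e-12)


def test_zscore_zero_variance_column_names_sample():
    expr = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
    with pytest.raises(NormalizationError, match="flat"):
        zscore_normalize(expr)


def test_z_ratio_has_unit_spread_and_checks_groups():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.normal(size=(100, 6)),
                        index=[f"g{i}" for i in range(100)],
                        columns=["a1", "a2", "a3", "b1", "b2", "b3"])
    z = zscore_normalize(expr)
    scores = z_ratio(z, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    assert scores.std(ddof=1) == pytest.approx(1.0)
    with pytest.raises(ConfigurationError):
        z_ratio(z, ["a1"], ["a1", "b1"])
    with pytest.raises(ConfigurationError):
        z_ratio(z, [], ["b1"])
    with pytest.raises(ConfigurationError):
        z_ratio(z, ["nope"], ["b1"])


def test_z_ratio_degenerate_when_groups_identical():
    expr = pd.DataFrame({"a1": [1.0, 2.0, 3.0], "b1": [1.0, 2.0, 3.0]},
                        index=["g1", "g2", "g3"])
    with pytest.raises(DegenerateContrastError):
        z_ratio(expr, ["a1"], ["b1"])


def test_z_ratio_drops_genes_with_missing_values():
    expr = pd.DataFrame({"a1": [1.0, np.nan, 3.0, 0.0],
                         "b1": [0.0, 1.0, 1.0, 2.0]},
                        index=["g1", "g2", "g3", "g4"])
    scores = z_ratio(expr, ["a1"], ["b1"])
    assert "g2" not in scores.index and len(scores) == 3


# ---------------------------------------------------------------------------
# PAGE statistic

def test_page_z_direct_evaluation():
    scores = pd.Series([1.0, 2, 3, 4, 5, 6],
                       index=[f"g{i}" for i in range(1, 7)])
    geneset = GeneSet("top", ["g5", "g6"])
    sc = page_z(scores, geneset)
    sigma_a = np.std([1, 2, 3, 4, 5, 6], ddof=1)
    assert sc.diff == pytest.approx(2.0)
    assert sc.z == pytest.approx(np.sqrt(2) * 2 / sigma_a)
    assert sc.n_set == 2 and sc.n_all == 6


def test_page_z_whole_array_set_is_zero(null_scores):
    geneset = GeneSet("all", list(null_scores.index))
    sc = page_z(null_scores, geneset)
    assert sc.diff == pytest.approx(0.0, abs=1e-12)
    assert sc.z == pytest.approx(0.0, abs=1e-12)


def test_page_z_sign_antisymmetry(null_scores):
    geneset = GeneSet("s", list(null_scores.index[:20]))
    sc = page_z(null_scores, geneset)
    neg = page_z(-null_scores, geneset)
    assert neg.z == pytest.approx(-sc.z)
    assert np.sign(sc.z) == np.sign(sc.diff)


def test_page_z_location_scale_invariance(null_scores):
    geneset = GeneSet("s", list(null_scores.index[:30]))
    base = page_z(null_scores, geneset).z
    shifted = page_z(null_scores + 5.0, geneset).z
    scaled = page_z(null_scores * 3.0, geneset).z
    assert shifted == pytest.approx(base, rel=1e-9)
    assert scaled == pytest.approx(base, rel=1e-9)


def test_page_z_matching_is_case_insensitive(null_scores):
    upper = GeneSet("s", [g.upper() for g in null_scores.index[:10]])
    assert page_z(null_scores, upper).n_set == 10


def test_page_z_literal_variant():
    scores = pd.Series([1.0, 2, 3, 4, 5, 6],
                       index=[f"g{i}" for i in range(1, 7)])
    geneset = GeneSet("top", ["g5", "g6"])
    sc = page_z(scores, geneset, statistic="n_minus_1")
    sigma_a = np.std([1, 2, 3, 4, 5, 6], ddof=1)
    assert sc.z == pytest.approx(1 * 2 / sigma_a)


def test_page_normal_p_matches_resampling_null():
    """Normal-theory p of Z tracks a gene-resampling null distribution."""
    rng = np.random.default_rng(42)
    n_a, n_i, draws = 200, 20, 20_000
    for _ in range(5):
        values = rng.normal(size=n_a)
        pos = rng.choice(n_a, size=n_i, replace=False)
        diff_obs = values[pos].mean() - values.mean()
        sigma_a = values.std(ddof=1)
        z = np.sqrt(n_i) * diff_obs / sigma_a
        p_param = 2 * norm.sf(abs(z))
        resampled = rng.choice(values, size=(draws, n_i), replace=True)
        diff_null = resampled.mean(axis=1) - values.mean()
        p_perm = np.mean(np.abs(diff_null) >= abs(diff_obs))
        assert abs(p_param - p_perm) < 0.02


# ---------------------------------------------------------------------------
# empirical p

def test_empirical_p_zero_diff_is_one():
    assert empirical_p(0.0, 1.0, 10, 1.0, 100) == pytest.approx(1.0)


def test_empirical_p_hits_five_percent_at_quantile():
    # choose diff so that diff / sigma(diff) = 1.959964
    sd = np.sqrt(1.0 / 10 + 1.0 / 100)
    p = empirical_p(1.959964 * sd, 1.0, 10, 1.0, 100)
    assert p == pytest.approx(0.05, abs=1e-6)


def test_empirical_p_monotone_in_diff():
    sd_args = (1.0, 10, 1.0, 100)
    ps = [empirical_p(d, *sd_args) for d in (0.0, 0.1, 0.5, 1.0, 2.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_empirical_p_degenerate_sd_limit():
    assert empirical_p(0.0, 0.0, 5, 0.0, 50) == 1.0
    assert empirical_p(0.5, 0.0, 5, 0.0, 50) == 0.0


# ---------------------------------------------------------------------------
# run_gsa / gsa_matrix

def _scores_for(genes, rng):
    return pd.Series(rng.normal(size=len(genes)), index=genes)


def test_run_gsa_size_filter_on_matched_genes(null_scores):
    genes = list(null_scores.index)
    coll = GeneSetCollection("f", [
        GeneSet("too_small", genes[:2]),
        GeneSet("lower_edge", genes[:3]),
        GeneSet("upper_edge", genes[:500] if len(genes) >= 500 else genes),
    ])
    table = run_gsa(coll, null_scores, min_genes=3, max_genes=500)
    assert set(table.index) == {"lower_edge", "upper_edge"}


def test_run_gsa_counts_matched_not_nominal(null_scores):
    genes = list(null_scores.index)
    # 3 matched + 2 absent genes: nominal 5, matched 3
    s = GeneSet("mixed", genes[:3] + ["ABSENT.1", "ABSENT.2"])
    table = run_gsa(GeneSetCollection("f", [s]), null_scores, min_genes=3)
    assert table.loc["mixed", "n"] == 3


def test_run_gsa_empty_result_error(null_scores):
    coll = GeneSetCollection("f", [GeneSet("missing", ["NOPE.1"])])
    with pytest.raises(EmptyResultError):
        run_gsa(coll, null_scores)


def test_run_gsa_q_matches_reference_bh(null_scores):
    rng = np.random.default_rng(3)
    genes = list(null_scores.index)
    sets = [GeneSet(f"s{i:02d}", list(rng.choice(genes, size=20,
                                                 replace=False)))
            for i in range(40)]
    table = run_gsa(GeneSetCollection("f", sets), null_scores)
    assert np.allclose(table["q"].to_numpy(),
                       reference_bh(table["p"].to_numpy()), atol=1e-12)


def test_null_z_distribution_is_standard_normal_like():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(2000)]
    scores = pd.Series(rng.normal(size=2000), index=genes)
    draws = np.array([rng.choice(2000, size=25, replace=False)
                      for _ in range(2000)])
    values = scores.to_numpy()
    zs = (np.sqrt(25) * (values[draws].mean(axis=1) - values.mean())
          / values.std(ddof=1))
    # spot-check the vectorized null against page_z on a few sets
    for row in draws[:5]:
        sc = page_z(scores, GeneSet("s", [genes[i] for i in row]))
        assert sc.z == pytest.approx(
            np.sqrt(25) * (values[row].mean() - values.mean())
            / values.std(ddof=1))
    assert abs(zs.mean()) < 0.1
    assert 0.85 < zs.std() < 1.15


def test_power_nondecreasing_in_planted_shift():
    rng = np.random.default_rng(5)
    n_a, n_i, reps = 2000, 20, 120
    power = []
    for delta in (0.0, 0.25, 0.5, 1.0):
        hits = 0
        for _ in range(reps):
            values = rng.normal(size=n_a)
            values[:n_i] += delta
            sigma_i = values[:n_i].std(ddof=1)
            diff = values[:n_i].mean() - values.mean()
            p = empirical_p(diff, sigma_i, n_i, values.std(ddof=1), n_a)
            hits += p < 0.05
        power.append(hits / reps)
    assert all(b >= a - 0.05 for a, b in zip(power, power[1:]))
    assert power[-1] > 0.9


def test_gsa_matrix_single_and_duplicate_contrast(null_scores):
    rng = np.random.default_rng(11)
    genes = list(null_scores.index)
    sets = [GeneSet(f"s{i}", list(rng.choice(genes, 15, replace=False)))
            for i in range(10)]
    coll = GeneSetCollection("f", sets)
    single = gsa_matrix(coll, {"c1": null_scores})
    table = run_gsa(coll, null_scores)
    assert np.allclose(single["c1"].sort_index(),
                       table["z"].sort_index())
    double = gsa_matrix(coll, {"c1": null_scores, "c2": null_scores})
    assert np.allclose(double["c1"], double["c2"])


def test_gsa_matrix_tracks_growing_planted_shift():
    rng = np.random.default_rng(13)
    genes = [f"g{i}" for i in range(800)]
    target = genes[:25]
    coll = GeneSetCollection("f", [
        GeneSet("target", target),
        GeneSet("decoy", genes[100:130]),
    ])
    contrasts = {}
    base = rng.normal(size=800)
    for k, delta in enumerate((0.0, 0.5, 1.0, 2.0)):
        v = base + rng.normal(0, 0.1, 800)
        v[:25] += delta
        contrasts[f"t{k}"] = pd.Series(v, index=genes)
    zmat = gsa_matrix(coll, contrasts, min_genes=3)
    target_z = zmat.loc["target"].to_numpy()
    assert np.all(np.diff(target_z) > 0)
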