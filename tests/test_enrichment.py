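"""Enrichment statistics: chi-square deviation, Fisher, logistic, overlaps.

Oracles: exhaustive hypergeometric enumeration for Fisher, hand-written
IRLS for logistic coefficients, quadratic all-pairs scan for interval
overlap, and the Benjamini-Hochberg definition for FDR.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from epilineage.enrichment import (MarkerSet, fisher_enrichment_batch,
                                   fisher_marker_enrichment, interval_overlap,
                                   logistic_enrichment,
                                   marker_substitution_deviation)
from epilineage.phylo import BRANCH_MY, LINEAGES


# -- Fisher vs hypergeometric enumeration ----------------------------------


def oracle_fisher_two_sided(a, b, c, d):
    """Point-probability two-sided Fisher: sum of all table probabilities
    (fixed margins) not exceeding the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)

    def prob(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def test_fisher_matches_enumeration_for_all_small_tables():
    """Every 2x2 table with total <= 30."""
    checked = 0
    for n in range(1, 31):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            p_oracle = oracle_fisher_two_sided(a, b, c, d)
            assert abs(p_scipy - p_oracle) < 1e-9, (a, b, c, d)
            checked += 1
    assert checked > 1000


def test_fisher_marker_enrichment_independence_and_tables():
    universe = {f"g{i}" for i in range(100)}
    markers = {f"g{i}" for i in range(0, 100, 2)}   # half
    class_set = {f"g{i}" for i in range(0, 100, 4)}  # markers only... no:
    class_set = {f"g{i}" for i in range(0, 40)}
    res = fisher_marker_enrichment(markers, class_set, universe)
    assert res["a"] + res["b"] + res["c"] + res["d"] == 100
    # equal marker frequency inside and outside the class
    res2 = fisher_marker_enrichment(markers, class_set, universe)
    assert res2["p"] == pytest.approx(1.0, abs=0.05)


def test_fisher_degenerate_class_flagged():
    universe = {"a", "b", "c"}
    res = fisher_marker_enrichment({"a"}, universe, universe)
    assert res["degenerate"]


def test_fisher_batch_labels():
    universe = {f"g{i}" for i in range(200)}
    enriched_class = {f"g{i}" for i in range(40)}
    markers = {"ct": {f"g{i}" for i in range(30)} |
                     {f"g{i}" for i in range(150, 160)}}
    out = fisher_enrichment_batch(markers, {"cls": enriched_class}, universe)
    row = out.iloc[0]
    assert row["odds_ratio"] > 1
    assert row["label"] == "enriched"


# -- chi-square deviation ---------------------------------------------------


def _uniform_counts(cts, n_per_ct, rate_per_bp, length, lineage_share):
    rows = {}
    gre_ids = []
    markers = {}
    for ct in cts:
        ids = [f"{ct}_{i}" for i in range(n_per_ct)]
        markers[ct] = set(ids)
        gre_ids += ids
    counts = pd.DataFrame(0, index=gre_ids, columns=list(LINEAGES))
    for ct in cts:
        for g in markers[ct]:
            for lin in LINEAGES:
                counts.loc[g, lin] = rate_per_bp[ct] * length * lineage_share[lin]
    lengths = {ct: float(n_per_ct * length) for ct in cts}
    return counts, MarkerSet(markers, lengths)


def test_deviation_null_all_ratios_one():
    cts = ["A", "B", "C"]
    share = {l: 1 for l in LINEAGES}
    counts, mset = _uniform_counts(cts, 10, {c: 2 for c in cts}, 100, share)
    out = marker_substitution_deviation(counts, mset, BRANCH_MY)
    assert np.allclose(out["deviation_ratio"], 1.0)
    assert (out["label"] == "ns").all()


def test_deviation_ratios_average_to_one_per_lineage():
    rng = np.random.default_rng(0)
    cts = ["A", "B", "C", "D"]
    markers = {ct: {f"{ct}_{i}" for i in range(20)} for ct in cts}
    ids = [g for s in markers.values() for g in s]
    counts = pd.DataFrame(rng.poisson(5, size=(len(ids), 5)), index=ids,
                          columns=list(LINEAGES))
    mset = MarkerSet(markers, {ct: 20 * 400.0 for ct in cts})
    out = marker_substitution_deviation(counts, mset, BRANCH_MY)
    for lin in LINEAGES:
        assert out[out.lineage == lin]["deviation_ratio"].mean() == \
            pytest.approx(1.0)


def test_deviation_flags_planted_excess():
    """3x microglia substitution rate stands out at FDR < 1e-5."""
    rng = np.random.default_rng(1)
    cts = ["Microglia", "Neuron", "Astro"]
    markers = {ct: {f"{ct}_{i}" for i in range(300)} for ct in cts}
    ids = [g for s in markers.values() for g in s]
    counts = pd.DataFrame(rng.poisson(5, size=(len(ids), 5)), index=ids,
                          columns=list(LINEAGES))
    mg = sorted(markers["Microglia"])
    counts.loc[mg] = rng.poisson(15, size=(len(mg), 5))
    mset = MarkerSet(markers, {ct: 300 * 400.0 for ct in cts})
    out = marker_substitution_deviation(counts, mset, BRANCH_MY)
    mg_rows = out[out.cell_type == "Microglia"]
    assert (mg_rows["deviation_ratio"] > 1).all()
    assert (mg_rows["label"] == "enriched").all()
    assert (out[out.cell_type != "Microglia"]["label"] == "ns").all()


def test_deviation_chi2_closed_form():
    cts = ["A", "B"]
    markers = {ct: {f"{ct}_{i}" for i in range(10)} for ct in cts}
    ids = [g for s in markers.values() for g in s]
    counts = pd.DataFrame(0, index=ids, columns=list(LINEAGES))
    counts.loc[sorted(markers["A"]), "Human"] = 3   # 30 vs 10
    counts.loc[sorted(markers["B"]), "Human"] = 1
    mset = MarkerSet(markers, {"A": 1000.0, "B": 1000.0})
    out = marker_substitution_deviation(counts, mset, BRANCH_MY)
    row = out[(out.cell_type == "A") & (out.lineage == "Human")].iloc[0]
    # O=(30,10), E=(20,20): chi2 = 100/20 + 100/20 = 10
    assert row["chi2"] == pytest.approx(10.0)
    assert row["p"] == pytest.approx(stats.chi2.sf(10.0, 1))
    row_b = out[(out.cell_type == "B") & (out.lineage == "Human")].iloc[0]
    assert row_b["p"] == 1.0  # deficit: one-sided reports excess only


# -- logistic ---------------------------------------------------------------


def oracle_irls_logit(X, y, n_iter=100, tol=1e-12):
    """Plain iteratively reweighted least squares for logit."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(W, 1e-12)
        WX = X * W[:, None]
        new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def test_logistic_matches_irls_oracle():
    rng = np.random.default_rng(2)
    n = 800
    length = rng.normal(500, 100, n)
    pred = (rng.random(n) < 0.3).astype(float)
    logit = -1.0 + 0.002 * length + 0.8 * pred
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    res = logistic_enrichment(y, length, pred)
    X = np.column_stack([np.ones(n), length, pred])
    beta = oracle_irls_logit(X, y)
    assert abs(res["beta"] - beta[2]) < 1e-6


def test_logistic_null_not_significant():
    rng = np.random.default_rng(3)
    n = 5000
    length = rng.normal(500, 100, n)
    pred = (rng.random(n) < 0.3).astype(float)
    y = (rng.random(n) < 0.2).astype(float)
    res = logistic_enrichment(y, length, pred)
    assert abs(res["beta"]) < 0.3
    assert res["p"] > 0.01


def test_logistic_removes_length_confound():
    """Length drives both response and a length-biased predictor; the
    adjusted coefficient stays near zero while naive Fisher fires."""
    rng = np.random.default_rng(4)
    n = 5000
    length = rng.normal(500, 120, n)
    # predictor and response both length-driven, otherwise independent
    pred = (rng.random(n) < 1 / (1 + np.exp(-(length - 500) / 60))).astype(float)
    y = (rng.random(n) < 1 / (1 + np.exp(-(length - 500) / 60))).astype(float)
    res = logistic_enrichment(y, length, pred)
    assert res["p"] > 0.001  # no adjusted association
    a = int(((pred == 1) & (y == 1)).sum())
    b = int(((pred == 1) & (y == 0)).sum())
    c = int(((pred == 0) & (y == 1)).sum())
    d = int(((pred == 0) & (y == 0)).sum())
    _, p_naive = stats.fisher_exact([[a, b], [c, d]])
    assert p_naive < 1e-10  # the confound fools the unadjusted test


def test_logistic_wald_p_uniform_under_null():
    """Calibration: Wald p over 200 seeded null fits is ~uniform."""
    pvals = []
    for s in range(200):
        rng = np.random.default_rng(1000 + s)
        n = 400
        length = rng.normal(500, 100, n)
        pred = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        res = logistic_enrichment(y, length, pred)
        if not res["separation"]:
            pvals.append(res["p"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_logistic_perfect_separation_flagged():
    y = np.array([0.0] * 50 + [1.0] * 50)
    pred = y.copy()
    length = np.linspace(400, 600, 100)
    res = logistic_enrichment(y, length, pred)
    assert res["separation"]


# -- BH FDR oracle ----------------------------------------------------------


def oracle_bh(p):
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


def test_bh_fdr_matches_definition_on_random_vectors():
    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.random(rng.integers(3, 50))
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, oracle_bh(p), atol=1e-12)
    # monotone in raw p
    p = rng.random(100)
    adj = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- interval overlap -------------------------------------------------------


def _bed(rows, idc="id"):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", idc])


def test_interval_overlap_half_open_boundary():
    a = _bed([("c", 0, 10, "a0")])
    touching = _bed([("c", 10, 20, "b0")], "idb")
    overlapping = _bed([("c", 9, 20, "b0")], "idb")
    pairs, counts = interval_overlap(a, touching)
    assert pairs.empty and counts["a0"] == 0
    pairs, counts = interval_overlap(a, overlapping)
    assert len(pairs) == 1 and counts["a0"] == 1


def test_interval_overlap_matches_quadratic_scan():
    rng = np.random.default_rng(6)
    a_rows = [("c%d" % rng.integers(2), int(s), int(s + rng.integers(1, 50)),
               f"a{i}") for i, s in enumerate(rng.integers(0, 500, 60))]
    b_rows = [("c%d" % rng.integers(2), int(s), int(s + rng.integers(1, 50)),
               f"b{i}") for i, s in enumerate(rng.integers(0, 500, 60))]
    a, b = _bed(a_rows), _bed(b_rows, "idb")
    pairs, counts = interval_overlap(a, b)
    got = set(map(tuple, pairs.values))
    expected = set()
    for ar in a_rows:
        for br in b_rows:
            if ar[0] == br[0] and ar[1] < br[2] and br[1] < ar[2]:
                expected.add((ar[3], br[3]))
    assert got == expected
    for ar in a_rows:
        assert counts[ar[3]] == sum(1 for x in expected if x[0] == ar[3])


def test_interval_overlap_rejects_invalid():
    with pytest.raises(ValueError):
        interval_overlap(_bed([("c", 10, 10, "a")]), _bed([("c", 0, 5, "b")]))
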