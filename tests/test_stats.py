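"""Rank statistics and trait associations against definition-level oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ileotype.abundance import AbundanceTable, to_relative
from ileotype.simulate import simulate_correlated_pair, spearman_to_pearson
from ileotype.stats import (correlation_network, genus_trait_correlations,
                            kruskal_wallis, pairwise_trait_tests,
                            significance_tier, spearman, welch_t,
                            wilcoxon_rank_sum)


def midrank(v):
    """Explicit mid-rank computation (ties -> average rank)."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = midrank(x), midrank(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return rho, 2 * sps.t.sf(abs(t), n - 2)


def kw_oracle(groups):
    pooled = np.concatenate(groups)
    ranks = midrank(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx:idx + len(g)]
        idx += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    h /= tie
    return h, sps.chi2.sf(h, len(groups) - 1)


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, 2 * sps.t.sf(abs(t), df)


# -- spearman -------------------------------------------------------------

def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 7, 9], [2, 4, 9, 20, 21]) == (1.0, 0.0)
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == (-1.0, 0.0)


def test_spearman_tied_fixture_matches_oracle():
    x, y = [1, 1, 2, 3], [2, 3, 1, 4]
    rho, p = spearman(x, y)
    orho, op = spearman_oracle(x, y)
    assert rho == pytest.approx(orho, abs=1e-12)
    assert p == pytest.approx(op, abs=1e-12)


def test_spearman_random_matches_oracle(rng):
    for _ in range(20):
        x = rng.integers(0, 8, size=25).astype(float)  # plenty of ties
        y = rng.integers(0, 8, size=25).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = spearman(x, y)
        orho, op = spearman_oracle(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-10)


def test_spearman_monotone_transform_invariant(rng):
    x = rng.standard_normal(40)
    y = rng.standard_normal(40)
    rho, _ = spearman(x, y)
    rho2, _ = spearman(np.exp(x), y ** 3)
    assert rho2 == pytest.approx(rho, abs=1e-12)


def test_spearman_rejects_constant_and_short():
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2, 3])


# -- Kruskal-Wallis -------------------------------------------------------

def test_kw_identical_groups_zero():
    assert kruskal_wallis([[2, 2], [2, 2], [2, 2]]) == (0.0, 1.0)


def test_kw_hand_fixture():
    groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
    h, p = kruskal_wallis(groups)
    oh, op = kw_oracle([np.array(g, float) for g in groups])
    assert h == pytest.approx(7.2, abs=1e-12)
    assert h == pytest.approx(oh, abs=1e-12)
    assert p == pytest.approx(op, abs=1e-12)


def test_kw_matches_oracle_with_ties(rng):
    for _ in range(20):
        groups = [rng.integers(0, 6, size=rng.integers(5, 12)).astype(float)
                  for _ in range(3)]
        if np.ptp(np.concatenate(groups)) == 0:
            continue
        h, p = kruskal_wallis(groups)
        oh, op = kw_oracle(groups)
        assert h == pytest.approx(oh, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)


def test_kw_two_groups_monotone_in_ranksum(rng):
    """With g=2 and no ties, H is a monotone function of the centred
    rank-sum statistic, so their orderings across instances agree."""
    hs, ws = [], []
    na, nb = 8, 9
    for _ in range(20):
        a = rng.standard_normal(na)
        b = rng.standard_normal(nb) + rng.uniform(-1, 1)
        h, _ = kruskal_wallis([a, b])
        w, _ = wilcoxon_rank_sum(a, b)
        hs.append(h)
        ws.append(abs(w - na * (na + nb + 1) / 2))
    for i in range(len(hs)):
        for j in range(len(hs)):
            if ws[i] < ws[j] - 1e-9:
                assert hs[i] < hs[j] + 1e-9


# -- Wilcoxon rank-sum ----------------------------------------------------

def test_wilcoxon_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0]
    _, p = wilcoxon_rank_sum(a, a)
    assert p > 0.9


def test_wilcoxon_exact_small_sample():
    w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert w == 6.0  # ranks 1+2+3
    assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3) enumerated


def test_wilcoxon_exact_matches_enumeration(rng):
    """Exact path agrees with full enumeration of rank assignments."""
    from itertools import combinations
    a = rng.standard_normal(4)
    b = rng.standard_normal(5)
    w, p = wilcoxon_rank_sum(a, b)
    pooled = np.concatenate([a, b])
    ranks = midrank(pooled)
    wa = ranks[:4].sum()
    n = len(pooled)
    all_w = [sum(c) for c in combinations(range(1, n + 1), 4)]
    mean_w = 4 * (n + 1) / 2
    extreme = sum(abs(x - mean_w) >= abs(wa - mean_w) - 1e-12 for x in all_w)
    assert w == pytest.approx(wa)
    assert p == pytest.approx(extreme / len(all_w), abs=1e-12)


def test_wilcoxon_large_shift():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(50)
    b = rng.standard_normal(50) + 10
    _, p = wilcoxon_rank_sum(a, b)
    assert p < 1e-6


# -- Welch ----------------------------------------------------------------

def test_welch_fixture_matches_hand_formula():
    a = [19.8, 21.2, 20.5, 22.1, 18.9, 20.0]
    b = [24.1, 23.8, 25.2, 24.9]
    t, p = welch_t(a, b)
    ot, op = welch_oracle(a, b)
    assert t == pytest.approx(ot, abs=1e-10)
    assert p == pytest.approx(op, abs=1e-10)


# -- trait tests ----------------------------------------------------------

def _pheno_frame(values, labels, index=None):
    from ileotype.abundance import derive_carcass_traits
    n = len(labels)
    df = pd.DataFrame({
        "body_weight": 2400 + values, "dressed_weight": 2100 + values,
        "eviscerated_weight": 1800 + values, "breast_muscle_weight": 270 + values / 10,
        "leg_muscle_weight": 180 + values / 10,
    }, index=index if index is not None else [f"d{i}" for i in range(n)])
    return derive_carcass_traits(df)


def test_trait_tests_identical_groups_p_one(rng):
    v = rng.standard_normal(30) * 10
    values = np.concatenate([v, v, v])
    labels = np.repeat([1, 2, 3], 30)
    tt = pairwise_trait_tests(_pheno_frame(values, labels), labels)
    assert (tt["p"] > 0.999).all()
    assert (tt["significance"] == "").all()


def test_trait_tests_detect_leg_shift_only(default_cohort):
    co = default_cohort
    tt = pairwise_trait_tests(co.phenotypes, co.true_labels)
    leg = tt[tt["trait"] == "leg_muscle_weight"].set_index(["et_a", "et_b"])
    assert leg.loc[(1, 3), "p"] < 0.01 and leg.loc[(2, 3), "p"] < 0.01
    body = tt[tt["trait"] == "body_weight"]
    assert (body["p"] > 0.05).all()
    legpct = tt[tt["trait"] == "leg_muscle_percentage"].set_index(["et_a", "et_b"])
    assert legpct.loc[(1, 3), "p"] < 0.01
    assert tt.attrs["corrected"] is False


def test_trait_tests_zero_variance_named():
    labels = np.repeat([1, 2], 5)
    values = np.concatenate([np.zeros(5), np.arange(5.0)])
    with pytest.raises(ValueError, match="body_weight"):
        pairwise_trait_tests(_pheno_frame(values, labels), labels,
                             traits=["body_weight"])


def test_significance_tiers():
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.2) == ""


# -- correlation network --------------------------------------------------

def _random_rel_table(rng, n_taxa=15, n=200, planted_rho=None, seed=0):
    vals = np.exp(rng.standard_normal((n_taxa, n)))
    if planted_rho is not None:
        x, y = simulate_correlated_pair(n, planted_rho, seed=seed)
        vals[0] = np.exp(x)
        vals[1] = np.exp(y)
    vals = vals / vals.sum(axis=0)
    return AbundanceTable(vals, [f"g{i}" for i in range(n_taxa)],
                          [f"s{i}" for i in range(n)], mode="relative")


def test_network_no_thresholds_gives_complete_graph(rng):
    t = _random_rel_table(rng, n_taxa=6)
    net = correlation_network(t, rho_min=0.0, p_max=1.0, top_n=6)
    assert len(net.edges) == 15  # C(6,2); |rho|>0 almost surely
    assert len(net.nodes) == 6


def test_network_recovers_planted_edge_across_seeds():
    hits = only = 0
    for s in range(100):
        rng = np.random.default_rng(1000 + s)
        t = _random_rel_table(rng, planted_rho=0.9, seed=s)
        net = correlation_network(t, rho_min=0.6, p_max=0.01, top_n=15)
        pairs = set(map(tuple, net.edges[["genus_a", "genus_b"]].to_numpy()))
        if ("g0", "g1") in pairs or ("g1", "g0") in pairs:
            hits += 1
            only += len(pairs) == 1
    assert hits >= 95
    assert only >= 95


def test_network_null_is_nearly_empty():
    total = 0
    for s in range(50):
        rng = np.random.default_rng(2000 + s)
        t = _random_rel_table(rng)
        total += len(correlation_network(t, 0.6, 0.01, 15).edges)
    assert total / 50 < 1.0


def test_network_edges_respect_thresholds(fitted):
    rel = fitted.model.table
    net = correlation_network(rel, 0.6, 0.01, 15)
    if len(net.edges):
        assert (net.edges["rho"].abs() > 0.6).all()
        assert (net.edges["p"] < 0.01).all()
    assert len(net.nodes) == 15


def test_network_graphml_roundtrip(tmp_path, rng):
    import xml.etree.ElementTree as ET
    t = _random_rel_table(rng, n_taxa=6)
    net = correlation_network(t, 0.0, 1.0, 6)
    p = tmp_path / "net.graphml"
    net.to_graphml(p)
    tree = ET.parse(p)
    ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
    assert len(tree.findall(".//g:node", ns)) == 6
    assert len(tree.findall(".//g:edge", ns)) == len(net.edges)


# -- genus-trait correlations ---------------------------------------------

def test_genus_trait_rank_transform_gives_unity(default_cohort):
    co = default_cohort
    rel = to_relative(co.abundance)
    row = rel.taxon_ids.index("Streptococcus")
    pheno = co.phenotypes
    hacked = pheno.data.copy()
    ranks = pd.Series(rel.values[row]).rank().to_numpy()
    # strictly monotone in the genus, and large enough to stay above the
    # dressed weight so the table remains physically valid
    hacked["body_weight"] = 3000.0 + ranks * 10
    from ileotype.abundance import PhenotypeTable
    gc = genus_trait_correlations(rel, PhenotypeTable(hacked),
                                  genus_set=["Streptococcus"],
                                  traits=["body_weight"])
    assert gc["rho"].iloc[0] == pytest.approx(1.0)


def test_genus_trait_misalignment_rejected(default_cohort):
    co = default_cohort
    rel = to_relative(co.abundance)
    sub = rel.select_samples(rel.sample_ids[:100])
    with pytest.raises(ValueError):
        genus_trait_correlations(sub, co.phenotypes)


def test_genus_trait_planted_couplings_recovered(default_cohort):
    """Lactococcus must correlate positively and significantly with leg
    muscle weight across nearly all phenotype seeds."""
    from ileotype.simulate import simulate_phenotypes
    co = default_cohort
    rel = to_relative(co.abundance)
    row_l = rel.taxon_ids.index("Lactococcus")
    row_b = rel.taxon_ids.index("Bradyrhizobium")
    hits_l = hits_b = 0
    for s in range(100):
        p = simulate_phenotypes(co.true_labels, co.abundance, seed=s)
        rho, pv = spearman(rel.values[row_l], p.trait("leg_muscle_weight"))
        hits_l += (rho > 0) and (pv < 0.05)
        rho, pv = spearman(rel.values[row_b],
                           p.trait("eviscerated_yield_percentage"))
        hits_b += (rho > 0) and (pv < 0.01)
    assert hits_l >= 95
    assert hits_b >= 95


def test_genus_trait_null_calibration():
    """Under independence ~5% of genus-trait pairs are significant at
    p<0.05 (Monte-Carlo, 2% tolerance)."""
    count = total = 0
    for s in range(40):
        rng = np.random.default_rng(3000 + s)
        t = _random_rel_table(rng, n_taxa=10, n=60)
        from ileotype.abundance import derive_carcass_traits
        vals = rng.standard_normal(60) * 20
        ph = _pheno_frame(vals, np.ones(60), index=t.sample_ids)
        gc = genus_trait_correlations(t, ph, genus_set=t.taxon_ids,
                                      traits=["body_weight"])
        count += int((gc["p"] < 0.05).sum())
        total += len(gc)
    assert abs(count / total - 0.05) < 0.02


def test_genus_trait_sorted_by_effect(default_cohort):
    co = default_cohort
    rel = to_relative(co.abundance)
    gc = genus_trait_correlations(rel, co.phenotypes)
    for _, grp in gc.groupby("trait"):
        assert (grp["rho"].abs().diff().dropna() <= 1e-12).all()
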