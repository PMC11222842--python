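"""Rank statistics and enterotype-trait association tests.

Spearman correlation (pairwise, genus co-occurrence networks, and
genus-trait matrices), Kruskal-Wallis, Wilcoxon rank-sum and Welch
t-tests.  The numerical engines are scipy's; this module pins the exact
conventions used throughout the pipeline (mid-rank ties, t-approximation
p-values for Spearman, exact rank-sum enumeration for small untied
samples, continuity-corrected normal approximation otherwise) and the
filtering thresholds of the co-occurrence network (|rho| > 0.6, p < 0.01
among the most abundant genera).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable, PhenotypeTable

__all__ = [
    "spearman",
    "correlation_network",
    "CorrelationNetwork",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "pairwise_trait_tests",
    "genus_trait_correlations",
    "significance_tier",
]

#: Sample-size bound below which the untied rank-sum test enumerates exactly.
EXACT_RANKSUM_MAX_N = 12


def significance_tier(p: float) -> str:
    """Star notation used in trait figures: ``**`` p<0.01, ``*`` p<0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks; p comes from
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df, the standard approximation at
    cohort scale.  Perfect monotone inputs return p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    return rho, float(p)


@dataclass
class CorrelationNetwork:
    """Genus co-occurrence network.

    ``nodes`` maps genus -> mean relative abundance (the node-size
    semantic of abundance-scaled network plots); ``edges`` is a DataFrame
    with columns genus_a / genus_b / rho / p, one row per unordered pair
    passing the thresholds.
    """

    nodes: dict[str, float]
    edges: pd.DataFrame
    rho_min: float
    p_max: float

    def to_edge_list(self, path) -> None:
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            self.edges.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    def to_graphml(self, path) -> None:
        """Minimal GraphML export (node mean abundance, edge rho/p)."""
        import xml.etree.ElementTree as ET

        ns = "http://graphml.graphdrawing.org/xmlns"
        ET.register_namespace("", ns)
        root = ET.Element(f"{{{ns}}}graphml")
        for kid, dom, name, typ in (("d0", "node", "mean_abundance", "double"),
                                    ("d1", "edge", "rho", "double"),
                                    ("d2", "edge", "p", "double")):
            ET.SubElement(root, f"{{{ns}}}key", id=kid, attrib={
                "for": dom, "attr.name": name, "attr.type": typ})
        g = ET.SubElement(root, f"{{{ns}}}graph", id="coabundance",
                          edgedefault="undirected")
        for genus, ab in self.nodes.items():
            node = ET.SubElement(g, f"{{{ns}}}node", id=genus)
            d = ET.SubElement(node, f"{{{ns}}}data", key="d0")
            d.text = f"{ab:.10g}"
        for _, row in self.edges.iterrows():
            e = ET.SubElement(g, f"{{{ns}}}edge",
                              source=row["genus_a"], target=row["genus_b"])
            for kid, val in (("d1", row["rho"]), ("d2", row["p"])):
                d = ET.SubElement(e, f"{{{ns}}}data", key=kid)
                d.text = f"{val:.10g}"
        ET.indent(root)
        ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def correlation_network(table: AbundanceTable, rho_min: float = 0.6,
                        p_max: float = 0.01, top_n: int = 15) -> CorrelationNetwork:
    """Spearman co-occurrence network among the ``top_n`` most abundant genera.

    Keeps undirected edges with |rho| > rho_min and p < p_max.
    """
    if table.mode != "relative":
        raise ValueError("correlation_network requires relative abundances")
    mean_ab = table.values.mean(axis=1)
    order = np.argsort(-mean_ab, kind="stable")[:top_n]
    if len(order) < 2:
        raise ValueError("need at least 2 genera after top-n restriction")
    names = [table.taxon_ids[i] for i in order]
    nodes = {table.taxon_ids[i]: float(mean_ab[i]) for i in order}
    rows = []
    for a in range(len(order)):
        xa = table.values[order[a]]
        for b in range(a + 1, len(order)):
            xb = table.values[order[b]]
            try:
                rho, p = spearman(xa, xb)
            except ValueError:
                continue  # constant genus: no defined correlation
            if abs(rho) > rho_min and p < p_max:
                rows.append((names[a], names[b], rho, p))
    edges = pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p"])
    return CorrelationNetwork(nodes, edges, rho_min, p_max)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on g-1 df.

    All-identical observations return (0, 1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample with
    mid-ranks.  Exact enumeration when n_a + n_b <= 12 with no ties,
    otherwise the tie-corrected normal approximation with 0.5 continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_RANKSUM_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    w = float(res.statistic) + len(a) * (len(a) + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pairwise_trait_tests(phenotypes: PhenotypeTable, labels,
                         traits: list[str] | None = None) -> pd.DataFrame:
    """Welch t-tests for every trait and every enterotype pair.

    ``labels`` is a per-sample cluster vector aligned with the phenotype
    table.  No multiple-testing correction is applied; the returned frame
    carries ``corrected=False`` in ``attrs`` to flag that.
    """
    labels = np.asarray(labels)
    if len(labels) != len(phenotypes.sample_ids):
        raise ValueError("labels are not aligned with the phenotype table")
    traits = traits or phenotypes.traits
    ets = sorted(np.unique(labels).tolist())
    for et in ets:
        if (labels == et).sum() < 2:
            raise ValueError(f"enterotype {et} has fewer than 2 samples")
    rows = []
    for trait in traits:
        v = phenotypes.trait(trait)
        for i in range(len(ets)):
            for j in range(i + 1, len(ets)):
                a, b = v[labels == ets[i]], v[labels == ets[j]]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    raise ValueError(
                        f"zero variance for trait {trait!r} in enterotype "
                        f"{ets[i] if np.ptp(a) == 0 else ets[j]}")
                t, p = welch_t(a, b)
                rows.append({
                    "trait": trait, "et_a": ets[i], "et_b": ets[j],
                    "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                    "t": t, "p": p, "significance": significance_tier(p),
                })
    out = pd.DataFrame(rows)
    out.attrs["corrected"] = False
    return out


def genus_trait_correlations(table: AbundanceTable, phenotypes: PhenotypeTable,
                             genus_set: list[str] | None = None,
                             traits: list[str] | None = None) -> pd.DataFrame:
    """Spearman rho and p for every genus x trait pair.

    Rows are sorted by |rho| descending within each trait.  Genus
    abundances must be relative and sample-aligned with the phenotypes.
    """
    if table.mode != "relative":
        raise ValueError("genus_trait_correlations requires relative abundances")
    if list(table.sample_ids) != phenotypes.sample_ids:
        raise ValueError("abundance and phenotype tables have misaligned samples")
    if genus_set is None:
        order = np.argsort(-table.values.mean(axis=1), kind="stable")[:15]
        genus_set = [table.taxon_ids[i] for i in order]
    traits = traits or phenotypes.traits
    rows = []
    for trait in traits:
        y = phenotypes.trait(trait)
        for g in genus_set:
            x = table.values[table.taxon_ids.index(g)]
            try:
                rho, p = spearman(x, y)
            except ValueError:
                continue
            rows.append({"trait": trait, "genus": g, "rho": rho, "p": p,
                         "significance": significance_tier(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out = (out.assign(_a=out["rho"].abs())
                  .sort_values(["trait", "_a"], ascending=[True, False], kind="stable")
                  .drop(columns="_a").reset_index(drop=True))
    return out
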